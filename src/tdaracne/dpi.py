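"""Data Processing Inequality pruning of weighted directed networks.

If genes g1 and g3 interact only through g2, information theory bounds the
indirect dependence: I(g1, g3) <= min(I(g1, g2), I(g2, g3)).  The weakest
edge of any fully connected triple can therefore be explained as an
indirect interaction and is pruned, unless its weight is within a relative
tolerance of the next-weakest edge (which keeps genuine three-gene loops).
"""

from __future__ import annotations

import logging
from itertools import combinations

import networkx as nx

logger = logging.getLogger(__name__)

DEFAULT_DPI_TOLERANCE = 0.15


def apply_dpi(network: nx.DiGraph, tolerance: float = DEFAULT_DPI_TOLERANCE) -> nx.DiGraph:
    """Prune the minimum-weight edge of every triangle, with tolerance.

    Triangles are detected on the undirected skeleton: an unordered gene
    pair counts as connected if either directed edge is present, and its
    weight is the larger of the two directed weights.  For each triangle
    the minimum-weight pair is marked for removal unless
    ``(min_other - w_min) / min_other < tolerance`` (relative difference),
    in which case the loop is kept.  Marks are collected against the input
    graph and swept at the end, which makes the operation idempotent;
    removal deletes both directed edges of the marked pair.

    Returns a pruned copy; the edge set is always a subset of the input's.
    """
    if not 0.0 <= tolerance < 1.0:
        raise ValueError(f"tolerance must lie in [0, 1), got {tolerance}")
    pruned = network.copy()
    pair_weight: dict[frozenset, float] = {}
    for u, v, data in network.edges(data=True):
        key = frozenset((u, v))
        w = float(data["weight"])
        pair_weight[key] = max(w, pair_weight.get(key, -float("inf")))

    skeleton = nx.Graph(tuple(key) for key in pair_weight)
    to_remove: set[frozenset] = set()
    for a, b, c in combinations(skeleton.nodes, 3):
        if not (skeleton.has_edge(a, b) and skeleton.has_edge(b, c) and skeleton.has_edge(a, c)):
            continue
        triple = sorted(
            (frozenset((a, b)), frozenset((b, c)), frozenset((a, c))),
            key=pair_weight.__getitem__,
        )
        w_min = pair_weight[triple[0]]
        min_other = pair_weight[triple[1]]
        if min_other > 0 and (min_other - w_min) / min_other >= tolerance:
            to_remove.add(triple[0])

    for key in to_remove:
        u, v = tuple(key)
        for edge in ((u, v), (v, u)):
            if pruned.has_edge(*edge):
                pruned.remove_edge(*edge)
    if to_remove:
        logger.info("DPI: pruned %d unordered pairs from %d triangles-checked graph",
                    len(to_remove), network.number_of_edges())
    return pruned
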