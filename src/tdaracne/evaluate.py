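"""Scoring of inferred directed networks against a gold standard.

An inferred edge is a true positive only if the gold standard contains the
same edge with the same direction (directed matching, the default).  An
edge recovered with the wrong direction therefore costs one false positive
and one false negative.  Undirected matching is available for comparisons
against simplified (orientation-free) reference networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx


def f_score(ppv: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if ppv + recall == 0:
        return 0.0
    return 2.0 * ppv * recall / (ppv + recall)


@dataclass(frozen=True)
class EvaluationResult:
    """Directed-edge confusion counts and the derived p / r / F metrics."""

    tp: int
    fp: int
    fn: int

    @property
    def ppv(self) -> float:
        """Positive predictive value: fraction of inferred edges that are true."""
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        """Fraction of true edges that were inferred."""
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f_score(self) -> float:
        return f_score(self.ppv, self.recall)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "ppv": self.ppv,
            "recall": self.recall,
            "f_score": self.f_score,
        }

    def to_json(self, path=None):
        if path is None:
            return json.dumps(self.to_dict(), indent=2)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        return None

    def to_row(self) -> str:
        """One tab-separated line for benchmark tables."""
        return "\t".join(
            [str(self.tp), str(self.fp), str(self.fn),
             f"{self.ppv:.4f}", f"{self.recall:.4f}", f"{self.f_score:.4f}"]
        )


def _edge_set(obj, directed: bool) -> set:
    edges = obj.edges() if isinstance(obj, nx.DiGraph) else obj
    if directed:
        return {(a, b) for a, b in edges}
    return {frozenset((a, b)) for a, b in edges}


def evaluate(inferred, truth, directed: bool = True, universe=None) -> EvaluationResult:
    """Score an inferred network against a gold-standard directed edge set.

    Parameters
    ----------
    inferred : DiGraph or iterable of (source, target) pairs
    truth : iterable of (source, target) pairs
        The gold-standard regulator -> regulated relations.
    directed : bool
        If True (default), (a, b) matches only (a, b); if False either
        orientation matches.
    universe : iterable of gene ids, optional
        When given, inferred edges touching genes outside it raise an
        error naming the offenders.
    """
    truth_edges = list(truth)
    inferred_edges = list(
        inferred.edges() if isinstance(inferred, nx.DiGraph) else inferred
    )
    if universe is not None:
        known = set(universe)
        unknown = sorted(
            {g for e in inferred_edges for g in e if g not in known}
        )
        if unknown:
            raise ValueError(f"inferred network contains genes outside the truth universe: {unknown}")

    pred = _edge_set(inferred_edges, directed)
    gold = _edge_set(truth_edges, directed)
    tp = len(pred & gold)
    return EvaluationResult(tp=tp, fp=len(pred - gold), fn=len(gold - pred))
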