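"""Profile preprocessing: copula transform, initial change of expression.

The copula (rank) transform maps each profile to uniform marginals on
(0, 1), making downstream MI estimates invariant to any monotone
reparameterisation of the raw measurements.  The initial change of
expression (IcE) flags, for each gene, the first time point at which the
profile has moved by more than a fold-change threshold relative to its
starting value; a gene can only regulate genes whose IcE is not earlier
than its own, which prunes the ordered pairs the estimator must visit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: Sentinel IcE value for genes that never cross either fold-change threshold.
NO_CHANGE = -1


def copula_transform(profile) -> np.ndarray:
    """Rank-based empirical copula: value -> (rank - 0.5) / n.

    Ties receive average ranks.  The fractional-rank convention keeps the
    transformed values strictly inside (0, 1), away from the grid borders
    where kernel density estimates are least stable.  A constant profile
    maps to the midpoint 0.5 everywhere (flagged, not fatal).
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a 1-D sequence of length >= 2")
    if np.ptp(x) == 0:
        logger.warning("copula_transform: constant profile; mapping to midpoint 0.5")
    return (rankdata(x) - 0.5) / x.size


def copula_transform_matrix(values: np.ndarray) -> np.ndarray:
    """Row-wise copula transform of a genes x time matrix."""
    values = np.asarray(values, dtype=float)
    return (rankdata(values, axis=1) - 0.5) / values.shape[1]


def compute_ice(matrix: pd.DataFrame, tau_up: float = 1.2, tau_down: float | None = None) -> pd.Series:
    """Initial change of expression for every gene.

    For profile x, IcE is the smallest 1-based index t >= 2 with
    ``x_t / x_1 >= tau_up`` or ``x_t / x_1 <= tau_down``; genes that never
    cross either threshold get :data:`NO_CHANGE`.  By default
    ``tau_down = 1 / tau_up`` (tau_up = 1.2 gives tau_down = 0.83), the
    reciprocal relation under which up- and down-regulation are treated
    symmetrically on the ratio scale.

    A zero first observation would make the ratio undefined; the whole
    profile is shifted by a machine-scale epsilon in that case (logged).
    """
    if tau_up <= 1.0:
        raise ValueError(f"tau_up must exceed 1, got {tau_up}")
    if tau_down is None:
        tau_down = 1.0 / tau_up
    elif not 0 < tau_down < 1:
        raise ValueError(f"tau_down must lie in (0, 1), got {tau_down}")

    out = {}
    for gene, row in matrix.iterrows():
        x = row.to_numpy(dtype=float)
        base = x[0]
        if base == 0.0:
            eps = np.finfo(float).eps * max(1.0, float(np.abs(x).max()))
            logger.warning("compute_ice: gene %s starts at 0; shifting profile by %.3g", gene, eps)
            x = x + eps
            base = x[0]
        ratios = x[1:] / base
        hits = (ratios >= tau_up) | (ratios <= tau_down)
        out[gene] = int(np.argmax(hits)) + 2 if hits.any() else NO_CHANGE
    return pd.Series(out, name="ice")


def admissible_pairs(ice: pd.Series) -> set[tuple]:
    """Ordered gene pairs (a, b) with IcE(a) <= IcE(b).

    A gene whose expression never changes (:data:`NO_CHANGE`) compares as
    +infinity: it may be regulated by anyone but can only regulate other
    no-change genes.  If every gene is flagged no-change the filter carries
    no information and all ordered pairs are admissible (warned), so the
    pipeline degrades gracefully on flat data.
    """
    key = {g: (np.inf if v == NO_CHANGE else v) for g, v in ice.items()}
    if all(np.isinf(k) for k in key.values()):
        logger.warning("admissible_pairs: no gene crossed the IcE thresholds; filter disabled")
    return {
        (a, b)
        for a in ice.index
        for b in ice.index
        if a != b and key[a] <= key[b]
    }
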