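"""Time-delayed mutual information on a fixed kernel-density grid.

Pairwise dependence between two expression profiles is measured as the
mutual information (MI, in nats) of their copula-transformed values,
estimated with a bivariate Gaussian product-kernel density evaluated on a
fixed ``grid_size x grid_size`` lattice over the unit square.  A directed,
time-aware variant shifts the putative target ``kappa`` steps forward in
time before estimation; the *influence* of gene *a* on gene *b* is the
maximum of these delayed MIs over ``kappa = 1..K``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy


class DegenerateProfileError(ValueError):
    """A profile has zero variance, so no kernel bandwidth exists.

    Callers enumerating gene pairs should catch this and skip the pair.
    """


@dataclass(frozen=True)
class MIParams:
    """Settings for grid-based MI estimation.

    Parameters
    ----------
    grid_size : int
        Number of density cells per axis (default 100, i.e. a 100x100 grid).
    max_delay : int
        Largest time shift ``K`` considered when maximising delayed MI.
        Small values favour direct interactions; K must satisfy
        ``T - K >= 4`` for the series length T at hand.
    bandwidth_method : str
        Automatic bandwidth selector.  The calibrated rule
        ``h_j = C * sigma_j * n**(-1/2)`` is provided (see BANDWIDTH_C for
        how C was fixed against closed-form oracles).
    """

    grid_size: int = 100
    max_delay: int = 3
    bandwidth_method: str = "calibrated"

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ValueError(f"grid_size must be >= 16, got {self.grid_size}")
        if self.max_delay < 1:
            raise ValueError(f"max_delay must be >= 1, got {self.max_delay}")
        if self.bandwidth_method != "calibrated":
            raise ValueError(f"unknown bandwidth_method {self.bandwidth_method!r}")


#: Scale constant of the bandwidth rule h = C * sigma * n**(-1/2).
#: Density-MISE-optimal (Silverman-type, n**(-1/6)) bandwidths
#: systematically oversmooth plug-in entropy functionals at large n while
#: a uniformly shrunk version leaves a large additive independence bias
#: (~0.45 nats) at short series lengths.  The n**(-1/2) decay with
#: C = 3.15 is calibrated against two estimator-quality targets: it
#: matches the closed-form bivariate-Gaussian MI (-0.5*ln(1 - rho^2))
#: within ~0.08 nats over rho in [0, 0.9] at n = 2000 (with the
#: independence estimate below 0.05 nats), and it keeps the independence
#: bias near 0.03 nats at the 50-point series lengths typical of
#: expression time courses, so relative comparisons between edge weights
#: (the DPI step) are not compressed by a bias floor.
BANDWIDTH_C = 3.15


def _bandwidth(values: np.ndarray) -> float:
    """Calibrated bandwidth for one margin of a bivariate KDE on copula data."""
    d = values - values.mean()
    sd = float(np.sqrt((d @ d) / (values.size - 1)))
    if sd == 0.0:
        raise DegenerateProfileError("constant profile: cannot select a bandwidth; skip this pair")
    return BANDWIDTH_C * sd * values.size ** -0.5


def _grid_centers(grid_size: int) -> np.ndarray:
    return (np.arange(grid_size) + 0.5) / grid_size


def _kernel_matrix(values: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    """Unnormalised Gaussian kernel evaluations, shape (grid, n)."""
    z = (grid[:, None] - values[None, :]) / h
    return np.exp(-0.5 * z * z)


def _joint_masses(ax: np.ndarray, ay: np.ndarray) -> np.ndarray:
    joint = ax @ ay.T
    total = joint.sum()
    if total <= 0.0 or not np.isfinite(total):
        raise DegenerateProfileError("kernel density vanished on the grid")
    return joint / total


def _plogp(t: np.ndarray) -> float:
    # sum t*log(t) with 0*log(0) = 0; the floor only touches exact zeros
    # (underflowed kernel cells), whose contribution is zero anyway.
    return float(t @ np.log(np.maximum(t, 1e-300)))


def _mi_from_raw_joint(raw: np.ndarray) -> float:
    """MI of an *unnormalised* non-negative joint grid, in nats.

    Uses MI = sum J log J - sum px log px - sum py log py on the
    normalised grid J = raw/s, algebraically rearranged to avoid
    materialising J:  (A - B - C)/s + log s.
    """
    s = float(raw.sum())
    if s <= 0.0 or not np.isfinite(s):
        raise DegenerateProfileError("kernel density vanished on the grid")
    px = raw.sum(axis=1)
    py = raw.sum(axis=0)
    mi = (_plogp(raw.ravel()) - _plogp(px) - _plogp(py)) / s + np.log(s)
    return max(mi, 0.0)


def _mi_from_joint(joint: np.ndarray) -> float:
    # MI = sum J log J - sum px log px - sum py log py; xlogy treats
    # zero-mass cells as contributing nothing (0 * log 0 = 0).
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = float(xlogy(joint, joint).sum() - xlogy(px, px).sum() - xlogy(py, py).sum())
    return max(mi, 0.0)


def kde2d(x, y, params: MIParams = MIParams()) -> tuple[np.ndarray, dict]:
    """Joint density cell masses of (x, y) on the fixed grid.

    Parameters
    ----------
    x, y : sequences of equal length >= 4, expected on the copula scale (0, 1).

    Returns
    -------
    joint : ndarray of shape (grid_size, grid_size)
        Non-negative cell masses summing to 1.
    meta : dict
        The automatically selected bandwidths ``hx`` and ``hy``, recorded
        for reproducibility.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("x and y must be 1-D sequences of equal length")
    if len(x) < 4:
        raise ValueError(f"need at least 4 samples, got {len(x)}")
    hx = _bandwidth(x)
    hy = _bandwidth(y)
    grid = _grid_centers(params.grid_size)
    joint = _joint_masses(_kernel_matrix(x, grid, hx), _kernel_matrix(y, grid, hy))
    return joint, {"hx": hx, "hy": hy}


def mutual_information(x, y, params: MIParams = MIParams()) -> float:
    """Grid-KDE mutual information in nats; symmetric, clipped at zero.

    Marginals are obtained by summing the joint grid along each axis;
    zero-mass cells contribute nothing (0*log 0 = 0).
    """
    joint, _ = kde2d(x, y, params)
    return _mi_from_joint(joint)


def delayed_mi(a, b, kappa: int, params: MIParams = MIParams()) -> float:
    """MI between ``a[t]`` and ``b[t + kappa]`` (b shifted forward in time).

    At ``kappa = 0`` this reduces to the ordinary symmetric MI (the
    steady-state compatibility mode).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("profiles must have equal length")
    if not 0 <= kappa <= params.max_delay:
        raise ValueError(f"kappa must be in [0, {params.max_delay}], got {kappa}")
    n = len(a) - kappa
    if n < 4:
        raise ValueError(f"overlap of length {n} after shifting by {kappa} is too short")
    if kappa == 0:
        return mutual_information(a, b, params)
    return mutual_information(a[:n], b[kappa:], params)


def influence(a, b, params: MIParams = MIParams()) -> tuple[float, int, np.ndarray]:
    """Influence of *a* on *b*: the maximum delayed MI over kappa = 1..K.

    Returns ``(influence, best_delay, per_delay)``.  Ties are broken toward
    the smallest delay, which biases the recovered edge toward a direct
    interaction.  The measure is asymmetric: ``influence(a, b)`` need not
    equal ``influence(b, a)``.
    """
    per_delay = np.array([delayed_mi(a, b, k, params) for k in range(1, params.max_delay + 1)])
    best = int(np.argmax(per_delay))  # argmax returns the first (smallest) maximiser
    return float(per_delay[best]), best + 1, per_delay


class DelayedMIEngine:
    """Batched delayed-MI queries over a matrix of copula-transformed profiles.

    Caches the per-gene kernel matrices for every (gene, delay, role)
    combination so that repeated pair queries -- the O(K n^2) sweep of the
    inference step and the inner loop of the bootstrap -- cost one matrix
    product each instead of re-evaluating the kernels.
    """

    def __init__(self, ranks: np.ndarray, params: MIParams = MIParams()):
        ranks = np.asarray(ranks, dtype=float)
        if ranks.ndim != 2:
            raise ValueError("ranks must be a 2-D (genes x time) array")
        n_t = ranks.shape[1]
        if n_t - params.max_delay < 4:
            raise ValueError(
                f"series of length {n_t} too short for max_delay={params.max_delay}"
            )
        self.ranks = ranks
        self.params = params
        self._grid = _grid_centers(params.grid_size)
        self._source: dict[tuple[int, int], np.ndarray] = {}
        self._target: dict[tuple[int, int], np.ndarray] = {}

    def _source_matrix(self, i: int, kappa: int) -> np.ndarray:
        key = (i, kappa)
        mat = self._source.get(key)
        if mat is None:
            v = self.ranks[i, : self.ranks.shape[1] - kappa] if kappa else self.ranks[i]
            mat = _kernel_matrix(v, self._grid, _bandwidth(v))
            self._source[key] = mat
        return mat

    def _target_matrix(self, j: int, kappa: int) -> np.ndarray:
        key = (j, kappa)
        mat = self._target.get(key)
        if mat is None:
            v = self.ranks[j, kappa:]
            mat = _kernel_matrix(v, self._grid, _bandwidth(v))
            self._target[key] = mat
        return mat

    def delayed_mi(self, i: int, j: int, kappa: int) -> float:
        return _mi_from_raw_joint(self._source_matrix(i, kappa) @ self._target_matrix(j, kappa).T)

    def per_delay(self, i: int, j: int) -> np.ndarray:
        return np.array(
            [self.delayed_mi(i, j, k) for k in range(1, self.params.max_delay + 1)]
        )

    def influence(self, i: int, j: int) -> tuple[float, int, np.ndarray]:
        per_delay = self.per_delay(i, j)
        best = int(np.argmax(per_delay))
        return float(per_delay[best]), best + 1, per_delay
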