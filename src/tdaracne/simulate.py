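"""Synthetic well-defined gene networks and their time-course expression.

The generator builds a random *well-defined* network -- every gene has
zero, one or two regulators; zero-regulator genes are *stimulators* whose
expression is exogenous noise modelling the environment -- and then
simulates expression with linear stochastic difference equations:

    x_t^i = a_i * x_{t-1}^{p_i}                      (one regulator)
    x_t^i = a_i * x_{t-1}^{p_i} + b_i * x_{t-1}^{q_i}  (two regulators)

plus zero-mean Gaussian noise eps_t of variance sigma^2 inside the
recursion, with coefficients drawn once per run from Uniform[0, 1] and
initial values and stimulator profiles i.i.d. Uniform[1, 100].  Each
profile is min-max normalised to [0, 1] at the end.  Because coefficients
are below one, genes deep in regulator chains have raw amplitudes shrunk
toward the noise floor, which is how rising sigma^2 progressively erodes
recoverability.  Among non-stimulator genes, 75% have one regulator and
25% have two by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import EvaluationResult, evaluate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationParams:
    """Settings of the synthetic benchmark generator.

    Parameters
    ----------
    n_genes, n_timepoints : int
        Network size (>= 3) and series length (>= 2).
    noise_variance : float
        Variance sigma^2 of the zero-mean Gaussian noise entering every
        regulated gene's difference equation at each time step (default
        0.02, the benchmark's reference level).
    n_stimulators : int, optional
        Number of zero-regulator genes; defaults to max(1, round(0.1 * n)).
    frac_one_regulator : float
        Among non-stimulator genes, the fraction with a single regulator
        (default 0.75; the two-regulator count is floored, remainder goes
        to one-regulator genes).
    seed : int, optional
        Seed used when no explicit generator is passed to the operations.
    """

    n_genes: int
    n_timepoints: int
    noise_variance: float = 0.02
    n_stimulators: int | None = None
    frac_one_regulator: float = 0.75
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError(f"n_genes must be >= 3, got {self.n_genes}")
        if self.n_timepoints < 2:
            raise ValueError(f"n_timepoints must be >= 2, got {self.n_timepoints}")
        if self.noise_variance < 0:
            raise ValueError(f"noise_variance must be >= 0, got {self.noise_variance}")
        if not 0.0 <= self.frac_one_regulator <= 1.0:
            raise ValueError("frac_one_regulator must lie in [0, 1]")
        if self.resolved_n_stimulators < 1 or self.resolved_n_stimulators >= self.n_genes:
            raise ValueError(
                f"n_stimulators must lie in [1, n_genes), got {self.resolved_n_stimulators}"
            )

    @property
    def resolved_n_stimulators(self) -> int:
        if self.n_stimulators is not None:
            return self.n_stimulators
        return max(1, round(0.1 * self.n_genes))


@dataclass(frozen=True)
class RegulatoryStructure:
    """Gold-standard topology: per-gene regulator lists and coefficients.

    ``regulators[i]`` is an ordered tuple of 0, 1 or 2 regulator indices
    (p_i, q_i) and ``coefficients[i]`` the matching (a_i, b_i) in [0, 1].
    Genes with an empty regulator tuple are exactly the stimulators.
    """

    gene_ids: tuple
    regulators: tuple
    coefficients: tuple

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene ids")
        if len(self.regulators) != n or len(self.coefficients) != n:
            raise ValueError("regulators/coefficients must match gene count")
        for i, (regs, coefs) in enumerate(zip(self.regulators, self.coefficients)):
            if len(regs) != len(coefs) or len(regs) > 2:
                raise ValueError(f"gene {self.gene_ids[i]}: malformed regulator spec")
            if i in regs:
                raise ValueError(f"gene {self.gene_ids[i]}: self-regulation is not allowed")
            if any(not 0 <= r < n for r in regs):
                raise ValueError(f"gene {self.gene_ids[i]}: regulator index out of range")
            if any(not 0.0 <= c <= 1.0 for c in coefs):
                raise ValueError(f"gene {self.gene_ids[i]}: coefficient outside [0, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def stimulators(self) -> tuple:
        return tuple(i for i, regs in enumerate(self.regulators) if not regs)

    def edges(self) -> set[tuple]:
        """Gold-standard directed edges: (regulator -> regulated) gene ids."""
        return {
            (self.gene_ids[r], self.gene_ids[i])
            for i, regs in enumerate(self.regulators)
            for r in regs
        }

    def write_edges_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for s, t in sorted(self.edges()):
                fh.write(f"{s}\t{t}\n")

    def write_edges_sif(self, path) -> None:
        with open(path, "w") as fh:
            for s, t in sorted(self.edges()):
                fh.write(f"{s}\tregulates\t{t}\n")


def regulator_split(n_regulated: int, frac_one_regulator: float) -> tuple[int, int]:
    """(one-regulator count, two-regulator count) with floored two-reg count."""
    n_two = int(np.floor(n_regulated * (1.0 - frac_one_regulator)))
    return n_regulated - n_two, n_two


def generate_random_network(params: SimulationParams, rng=None) -> RegulatoryStructure:
    """Draw a random well-defined network.

    Stimulators are a random subset of the genes; every regulated gene
    draws its one or two regulators uniformly from the *other* genes
    (stimulator or not), and fresh Uniform[0, 1] coefficients.  Cycles may
    arise and are permitted -- feedback is part of the target biology.
    """
    rng = np.random.default_rng(params.seed if rng is None else rng)
    n = params.n_genes
    gene_ids = tuple(f"G{i + 1}" for i in range(n))
    order = rng.permutation(n)
    stimulators = set(order[: params.resolved_n_stimulators].tolist())
    regulated = [i for i in range(n) if i not in stimulators]
    n_one, n_two = regulator_split(len(regulated), params.frac_one_regulator)
    # first n_one regulated genes (in shuffled order) get one regulator, rest two
    rng.shuffle(regulated)
    regulators: list[tuple] = [()] * n
    coefficients: list[tuple] = [()] * n
    for pos, i in enumerate(regulated):
        k = 1 if pos < n_one else 2
        others = [g for g in range(n) if g != i]
        regs = rng.choice(others, size=k, replace=False)
        regulators[i] = tuple(int(r) for r in regs)
        coefficients[i] = tuple(float(c) for c in rng.uniform(0.0, 1.0, size=k))
    return RegulatoryStructure(
        gene_ids=gene_ids, regulators=tuple(regulators), coefficients=tuple(coefficients)
    )


def _simulate_raw(structure: RegulatoryStructure, params: SimulationParams, rng) -> np.ndarray:
    n, t_max = structure.n_genes, params.n_timepoints
    sd = float(np.sqrt(params.noise_variance))
    x = np.empty((n, t_max))
    for i in structure.stimulators:
        x[i] = rng.uniform(1.0, 100.0, size=t_max)
    regulated = [i for i in range(n) if structure.regulators[i]]
    for i in regulated:
        x[i, 0] = rng.uniform(1.0, 100.0)
    eps = rng.normal(0.0, sd, size=(len(regulated), t_max)) if sd > 0 else np.zeros((len(regulated), t_max))
    for t in range(1, t_max):
        for row, i in enumerate(regulated):
            regs = structure.regulators[i]
            coefs = structure.coefficients[i]
            x[i, t] = sum(c * x[r, t - 1] for r, c in zip(regs, coefs)) + eps[row, t]
    return x


def simulate_expression(
    structure: RegulatoryStructure,
    params: SimulationParams,
    rng=None,
    raw: bool = False,
) -> pd.DataFrame:
    """Simulate a genes x time expression matrix for a given topology.

    The noisy linear recursion runs on the raw [1, 100] scale (Gaussian
    eps_t of variance ``noise_variance`` added to every regulated gene at
    every step); each profile is then min-max normalised to [0, 1].  With
    ``raw=True`` the pre-normalisation trajectories are returned instead
    (useful for verifying the recursion directly).

    Fully reproducible from the seed/generator; adding noise perturbs the
    profiles but never the gold-standard structure.
    """
    rng = np.random.default_rng(params.seed if rng is None else rng)
    x = _simulate_raw(structure, params, rng)
    time_labels = [f"t{t + 1}" for t in range(params.n_timepoints)]
    if raw:
        return pd.DataFrame(x, index=list(structure.gene_ids), columns=time_labels)
    span = np.ptp(x, axis=1, keepdims=True)
    flat = span[:, 0] == 0
    if flat.any():
        logger.warning(
            "simulate_expression: %d profiles collapsed to a constant; set to 0.5", int(flat.sum())
        )
    span[flat] = 1.0
    norm = (x - x.min(axis=1, keepdims=True)) / span
    norm[flat] = 0.5
    return pd.DataFrame(norm, index=list(structure.gene_ids), columns=time_labels)


@dataclass
class BenchmarkResult:
    """Per-run metrics and their across-run mean and standard deviation."""

    runs: list[EvaluationResult] = field(default_factory=list)

    def _stat(self, attr: str) -> tuple[float, float]:
        vals = np.array([getattr(r, attr) for r in self.runs])
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    @property
    def mean_ppv(self) -> float:
        return self._stat("ppv")[0]

    @property
    def mean_recall(self) -> float:
        return self._stat("recall")[0]

    @property
    def mean_f_score(self) -> float:
        return self._stat("f_score")[0]

    def to_dict(self) -> dict:
        out = {"n_runs": len(self.runs)}
        for attr in ("ppv", "recall", "f_score"):
            mean, std = self._stat(attr)
            out[f"mean_{attr}"] = mean
            out[f"std_{attr}"] = std
        return out


def run_benchmark(
    params: SimulationParams,
    n_runs: int = 20,
    seed: int | None = None,
    inference: dict | None = None,
    predictor=None,
) -> BenchmarkResult:
    """Average inference performance over independently drawn random networks.

    Each run draws a fresh network, simulates its expression, infers a
    network and scores it against the generating structure with directed
    matching; PPV, recall and F are averaged arithmetically across runs
    (per-run metrics first, then the mean).

    Parameters
    ----------
    inference : dict, optional
        Keyword overrides for :class:`~tdaracne.model.TDAracne`.
    predictor : callable, optional
        ``predictor(matrix, structure) -> edge set`` replacing the
        inference step (e.g. an oracle for sanity checks).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    from .model import TDAracne  # local import: model depends on nothing here

    ss = np.random.SeedSequence(params.seed if seed is None else seed)
    result = BenchmarkResult()
    for child in ss.spawn(n_runs):
        rng = np.random.default_rng(child)
        structure = generate_random_network(params, rng=rng)
        matrix = simulate_expression(structure, params, rng=rng)
        if predictor is not None:
            predicted = predictor(matrix, structure)
        else:
            fit = TDAracne(matrix, **(inference or {})).fit(seed=rng)
            predicted = fit.network
        result.runs.append(
            evaluate(predicted, structure.edges(), directed=True, universe=structure.gene_ids)
        )
    return result
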