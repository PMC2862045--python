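# tdaracne

Directed gene regulatory network inference from **short expression time
courses** via time-delayed mutual information — a Python implementation of
the TimeDelay-ARACNE algorithm, together with the synthetic benchmark
generator and directed-edge evaluation metrics used to validate it.

## Who this is for

Systems biologists with a small set of genes (tens, not thousands) measured
over an ordered, short time course (10–50 points) — cell-cycle panels,
stress-response pathways, synthetic circuits — who want a *directed* graph
of candidate regulator → target influences rather than the undirected
co-expression networks that steady-state methods produce.

## The method

For genes *a*, *b* with copula-transformed (rank-uniformised) profiles, the
**delayed mutual information** at lag κ is

    I^κ(a, b) = MI( a(t), b(t + κ) ),   κ = 1 … K,

estimated with a bivariate Gaussian-kernel density on a fixed 100 × 100
grid. The **influence** of *a* on *b* is `Infl(a,b) = max_κ I^κ(a,b)`, an
asymmetric measure: shifting *b* forward in time means a significant
influence points *from* the earlier-changing gene *to* the later one.

The three inference steps:

1. **IcE filter** — each gene's *initial change of expression* is the first
   time point where its profile leaves the fold-change band
   `[τ_down, τ_up] = [0.83, 1.2]` relative to its start; gene *a* may only
   regulate *b* if `IcE(a) ≤ IcE(b)`.
2. **Significance threshold** — a stationary block bootstrap (geometric
   block lengths, 500 replicates) resamples every profile, destroying
   cross-gene dependence; pooled null influence values give
   `I₀ = μ + α·σ`, with α chosen from the null's 95th percentile so that at
   most 5 % of null values exceed I₀. Influences at or below I₀ are
   discarded.
3. **DPI pruning** — the data processing inequality
   `I(a,c) ≤ min(I(a,b), I(b,c))` identifies the weakest edge of each
   triangle as indirect; it is removed unless within 15 % (relative) of the
   next-weakest. Applied once per single delay and once on the final
   best-delay influence graph.

## Worked example

```python
import numpy as np
from tdaracne import TDAracne, evaluate
from tdaracne.simulate import SimulationParams, generate_random_network, simulate_expression

params = SimulationParams(n_genes=10, n_timepoints=50, noise_variance=0.02, seed=3)
rng = np.random.default_rng(3)
truth = generate_random_network(params, rng=rng)
matrix = simulate_expression(truth, params, rng=rng)   # genes x time DataFrame

res = TDAracne(matrix).fit(seed=7)
print(res.summary())
print(evaluate(res.network, truth.edges(), universe=truth.gene_ids).to_dict())
```

prints (edge table abridged):

```
          TimeDelay-ARACNE network inference
==========================================================
Genes: 10     Time points: 50     Max delay K: 3
tau_up: 1.200   tau_down: 0.833   DPI tolerance: 0.15
Threshold I0: 0.0558  (mu=0.0324, sigma=0.0129, alpha=1.816, B=500)
Pairs: 90 admissible -> 14 above I0 -> 13 oriented -> 13 after DPI-1 -> 12 final
----------------------------------------------------------
source    target       influence  delay
G10       G3              0.4414      2
G10       G7              0.4536      1
G10       G9              0.4392      1
G7        G3              0.4463      1
...
==========================================================
{'tp': 8, 'fp': 4, 'fn': 3, 'ppv': 0.667, 'recall': 0.727, 'f_score': 0.696}
```

Each listed edge is a regulator → target call whose influence (nats)
exceeded the bootstrap threshold and survived both DPI passes; `delay` is
the lag (in sampling intervals) at which the dependence peaked. The
evaluation line scores the call set against the generating topology with
direction-sensitive matching.

The same pipeline runs from the shell:

```bash
tdaracne simulate --genes 10 --timepoints 50 --seed 3 --out syn
tdaracne infer syn.expression.tsv --seed 7 --out net
tdaracne evaluate net.edges.tsv syn.edges.tsv
```

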