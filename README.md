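# epinet

Structure of quantitative bipartite ecological interaction networks:
nestedness, complementary specialization, modularity, null-model
significance, and mixed-model comparison across interaction types.

## The scientific problem

Interactions between two guilds — epiphytes on host phorophytes, pollinators
on plants, frugivores on fruiting plants, ants on myrmecophytes — form
bipartite networks whose architecture carries ecological signal.  Three
properties dominate the literature:

- **Nestedness (NODF)**: do the partners of specialists form subsets of the
  partners of generalists?  For every pair of rows (and of columns) with
  strictly decreasing fill, the pair contributes
  `100 · |shared partners| / fill(poorer)`; ties contribute 0.  NODF is the
  mean over all pairs, 0–100.  A weighted variant (wNODF) applies the same
  scheme to interaction frequencies under strictly decreasing marginal
  totals.
- **Complementary specialization (H2′)**: the two-dimensional Shannon
  entropy H2 = −Σ p_ij ln p_ij of the interaction frequency table,
  standardized between the least and most even *integer* tables consistent
  with the margins: `H2′ = (H2max − H2) / (H2max − H2min)` in [0, 1].  Its
  species-level analogue d′ standardizes the Kullback–Leibler divergence
  between a species' partner use and partner availability.
- **Modularity (Q)**: the weighted bipartite (Barber-type) objective
  `Q = (1/F) Σ_ij [A_ij − K_i L_j / F] δ(m_i, m_j)` maximized over joint
  row/column partitions by simulated annealing with restarts (default 10,
  best Q kept).  Species roles are summarized by the participation
  coefficient `c = 1 − Σ_s (k_s/k)²` over modules.

Because all three metrics depend on margins and network size, observed
values are tested against a **fixed-fixed null model**: curveball-trade
randomizations that preserve every row and column sum (defaults: 1000 nulls
for NODF, 100 for Q), with a two-sided Z-test.  To compare metrics *across*
interaction types, the package fits linear mixed models
`metric ~ interaction type + network size + (1 | locality)` by REML, with
Type-II Wald χ² tests, single-step (Tukey-style) pairwise contrasts, and
Nakagawa–Schielzeth marginal/conditional R².

A synthetic-network module generates count matrices with tunable abundance
skew, planted modules, and preferred-partner specialization, plus
study-level metric tables with known type effects — so every stage can be
validated by parameter recovery.  The package also bundles the published
summary table of 12 quantitative epiphyte–phorophyte surveys from tropical
and subtropical forests.

## Worked example

```python
import numpy as np
from epinet import (GeneratorConfig, gen_modular, prune_empty, nodf, wnodf,
                    h2_prime, optimize_modules, null_test, d_prime)

net = prune_empty(gen_modular(GeneratorConfig(
    n_rows=8, n_cols=10, total_interactions=200, regime="modular",
    n_modules=2, within_between_ratio=6.0, seed=7)))

print(f"NODF  = {nodf(net).value:.2f}")
print(f"wNODF = {wnodf(net).value:.2f}")
sp = h2_prime(net)
print(f"H2'   = {sp.H2prime:.3f}  (H2 = {sp.H2:.3f} in [{sp.H2min:.3f}, {sp.H2max:.3f}])")
mod = optimize_modules(net, n_restarts=10, seed=1)
print(f"Q     = {mod.Q:.3f}  with {mod.partition.n_modules} modules")
res = null_test(net, "Q", n_null=100, seed=2, n_restarts_q=10)
print(f"Q null test: z = {res.z:.2f}, p = {res.p:.4f}, significant = {res.significant}")
print(f"d'({net.row_labels[0]}) = {d_prime(net, 0, 'row').d_prime:.3f}")
```

prints

```
NODF  = 63.69
wNODF = 35.69
H2'   = 0.216  (H2 = 3.931 in [2.492, 4.326])
Q     = 0.315  with 2 modules
Q null test: z = 1.17, p = 0.2433, significant = False
d'(H1) = 0.172
```

The network is moderately nested and weakly specialized (H2′ = 0.22: its
entropy sits near the even end of what its margins allow).  The optimizer
recovers the two planted modules with Q = 0.315, but against the binary
fixed-fixed null this small network's modularity is not distinguishable from
its margin expectation (p = 0.24) — detecting modest modularity at this size
requires more contrast than the planted 6:1 weight ratio leaves in the
binarized topology.  `H1`'s d′ of 0.17 marks it as a near-generalist.

A command-line interface wraps the pipeline stages
(`epinet simulate | metrics | nulltest | summary | compare`); metrics and
null tests run from a manifest TSV listing one network file per row with its
interaction type and locality.

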