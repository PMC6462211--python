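# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `epinet`.  It is organized by pipeline stage.

## Data model

A network is a labelled nonnegative count matrix: rows are hosts/plants
(phorophytes for the epiphyte case), columns the dependent guild
(epiphytes, pollinators, dispersers, ants).  Counts are validated as
integers (tolerance 1e-9) because the specialization bounds operate on
integer margins; a flag admits continuous weights for metrics that do not
need them.  All-zero rows and columns are pruned before any metric — they
carry no information and break the pair and entropy definitions — and a
network smaller than 2×2 after pruning is rejected as degenerate.  Network
size is the pooled species count (rows + columns).  Metadata carries the
interaction type (EP, SD, PO, AM), the locality used as the random-effect
grouping factor, habitat and sampling codes, and coordinates.

## Nestedness

NODF uses the strict decreasing-fill rule: a pair with tied fill contributes
zero.  This is the standard tie convention and materially lowers scores of
matrices with repeated rows; it is what makes the all-ones matrix score 0.
NODF is computed on the binarized matrix; wNODF applies the analogous rule
to quantitative values, conditioning on strictly decreasing *marginal
totals* and counting cells where the poorer line is positive but strictly
smaller than the richer line.  Note that vegan's `nestednodf(weighted=TRUE)`
implements a different (binary-fill-conditioned) weighted variant and is not
numerically comparable; binary NODF, however, agrees with vegan exactly and
is cross-checked against it in the test suite.  Values are kept at full
precision internally and reported to two decimals in pipeline tables.

## Complementary specialization

H2 is the Shannon entropy (nats, zero-cell terms contribute 0) of the joint
interaction frequency table.  H2′ standardizes it between the entropies of
the most and least even integer tables with the observed margins, clamped to
[0, 1]; when the margins admit only a single entropy value (H2max = H2min)
the result is 0 with a degeneracy flag.

Bounds are exact for small tables (≤ 16 cells and total ≤ 24 interactions):

- *Minimum*: entropy is strictly concave, so its minimum over the
  transportation polytope is attained at a vertex, and every vertex is
  reachable by sequentially placing min(row remainder, column remainder)
  into some cell.  A dynamic program over multisets of remaining margins
  maximizes Σ w ln w over all saturation orders, giving the exact minimum.
- *Maximum*: branch-and-bound over integer tables, pruned by the continuous
  entropy optimum (outer product) of each residual sub-problem, seeded with
  the rounding heuristic below as incumbent.

Above the gate, fast constructions take over: the most even table is the
largest-remainder rounding of the expected table r_i c_j / m (units placed
at the largest fractional remainders whose row and column still have
deficits), the most concentrated table pairs the largest remaining margins
greedily, and both are polished by steepest margin-preserving 2×2 swap
moves (bounded to ≤ 400-cell tables).  The fallback is heuristic: it can sit
slightly inside the true range, which the [0, 1] clamp absorbs.  For
realistically dense matrices the integer-lattice effect is small — scaling
all counts by 10 moves H2′ by < 0.02 in the test suite — but for very sparse
tables (totals near the species count) H2′ is strongly lattice-dependent and
should be interpreted cautiously.

d′ uses partner availability q_j = A_j/m from the *observed* column (or row)
totals.  d is the KL divergence of the species' use distribution from q;
d_max places the species' whole total on the partner with minimum
availability (concentration maximizes the divergence, so ties need no
spreading); d_min minimizes over integer allocations of the species total.
The minimization starts from largest-remainder rounding of the proportional
allocation and descends with single-unit transfers — the objective is
separable convex on the simplex lattice, so local optimality is global, and
the tests confirm exactness against exhaustive search.

## Modularity

The objective is the Barber-type quantitative bipartite modularity with
joint row/column modules.  The optimizer is simulated annealing: random
initial assignment with up to min(rows, columns) modules, single-node
reassignment moves with a whole-module merge proposal every 50 steps,
Metropolis acceptance with geometric cooling (T0 = 0.05, factor 0.995), and
termination after 2000 proposals without improvement.  Module bookkeeping is
incremental (Q = Σ_s e_s − a_s b_s), so a move costs O(columns).  Since any
single run can stall in a local optimum, the estimator runs 10 restarts by
default with sub-seeds spawned from a master seed and keeps the best Q; the
reported Q is always recomputed from the returned partition, and
planted-partition tests require ≥ 95 % recovery on two- and three-block
matrices with within:between weight ratio ≥ 5.  The within:between ratio of
the synthetic generator is defined per cell (expected weight of a
within-block cell over a between-block cell).

c-values use quantitative strengths, not binary degree, matching the rest of
the frequency-based species metrics.  The within-module degree z-score
companion metric is deliberately not implemented.

## Null models

The fixed-fixed ensemble preserves every row and column sum of the
binarized matrix.  Sampling is by curveball trades — two random rows
re-partition the columns held by exactly one of them — with a burn-in of
5·(rows·columns) attempted trades per sample, each sample an independent
chain from the observed matrix (reproducibility is cleaner than thinning a
single chain, at the cost of longer burn-ins).  Uniformity is checked by the
equifrequency of embedded checkerboard states; margin preservation is exact
by construction.

The Z-test uses the normal approximation (two-sided) with the empirical
quantile p reported alongside as a small-sample guard; a null with zero
variance (margins that pin the matrix, e.g. any perfectly packed nested
matrix, whose column sums are the conjugate of its row sums) is flagged
degenerate and never called significant.  Defaults are 1000 nulls for NODF
and 100 for Q; each Q null is re-optimized with the full restart protocol,
which is what makes Q tests expensive.  The Q null randomizes the binary
topology by default (each null scored as a 0/1 count matrix); a
weight-preserving alternative using unit 2×2 transfers on the counts
(quasiswap-style) is available behind `quantitative=True`.  On
abundance-neutral matrices the NODF test's type-I error is 0.05 at
α = 0.05 (200 replicates, 200 nulls each, computed in the test suite).

## Comparative stage

Each metric is modelled as Gaussian:
`metric ~ interaction_type + network_size + (1 | locality)`, REML-fitted via
statsmodels MixedLM.  NODF is ln-transformed; network size enters only for
network-level metrics (species-level models omit it and default to locality
as the grouping factor, with network identity available as an option).
Fits whose locality variance lands on the zero boundary — including the
identifiable-in-sum-only case of one observation per locality — fall back to
OLS for the fixed effects and carry a boundary flag rather than an error.

The interaction-type test is a Type-II Wald χ² on the type coefficients
given the size covariate.  Pairwise contrasts use the single-step max-|z|
adjustment under the joint normal law of the six standardized contrasts,
computed by Monte Carlo with 10⁵ draws and a fixed seed (no
degrees-of-freedom correction; asymptotically equivalent to the Tukey
procedure and reproducible).  The adjusted p is floored at the unadjusted p.
A compact letter display is derived by insert-and-absorb over the
significant pairs.  R² follows the variance-partition definition for
random-intercept models: Rm² = var(Xβ̂) / (var(Xβ̂) + σ²_u + σ²_e),
Rc² adds σ²_u to the numerator; var(·) is the sample variance of the
fixed-effect predictions.  Residual diagnostics are emitted as tables
(fitted/residual/normal-quantile), not plots.

## Synthetic data

Generators draw cell counts multinomially so the grand total is exact —
metrics and nulls condition on totals.  The neutral regime multiplies
lognormal row and column abundances (σ controls margin skew, the driver of
"apparent" nestedness); the modular regime plants equal blocks with a
per-cell within:between expected-weight ratio; the specialized regime mixes
a cyclic one-to-one preference with the even table via a concentration knob
in [0, 1].  Rare species may come out unobserved under strong skew — as in
field sampling — and are removed by pruning; draws with fewer than two
observed rows or columns are rejected.

The study-level generator emulates a comparative compilation: 12 EP, 13 SD,
86 PO and 11 AM networks by default, network sizes log-uniform on 16–180,
locality random intercepts (40 localities) and Gaussian noise per metric,
with per-metric scales (NODF 8.0, H2′ 0.08, Q 0.05) keeping values in their
natural ranges, and planted type shifts following the
commensalism-vs-mutualism pattern (EP more nested: +15 NODF; less
specialized: −0.25 H2′; less modular: −0.18 Q; NODF size slope −0.05 per
species).  Metric values are clipped into their defined ranges; with the
default scales clipping essentially never binds, so recovery tests are
unbiased.

What the generators do *not* emulate: phylogenetic structure, spatial
autocorrelation beyond the locality intercept, trait matching, or sampling
method effects.  Passing recovery tests therefore demonstrates correctness
of the estimators under the stated model, not robustness to those real-data
features.

## Problem sizes and determinism

Default test and acceptance runs use small networks (6–12 species per
guild, totals 80–400), 100–200 null replicates, and 200–500 simulation
replicates per calibration — sizes chosen so the complete validation suite
runs on a single CPU in minutes while keeping Monte-Carlo standard errors
well inside the asserted tolerances.  Every stochastic component takes an
explicit seed; sub-seeds are spawned via `numpy.random.SeedSequence`, and
pipeline outputs format floats at 6 significant digits so identical
configurations reproduce byte-identical files.

## Known limitations

- The heuristic H2 bounds above the small-table gate are not certified
  optima; H2′ is clamped and the bracketing tolerance (2 % on H2max) is
  asserted, not proven.
- The binary-topology default for Q nulls discards weight structure; a
  strongly weight-modular network with bland topology can test
  non-significant (the quantitative null is the remedy).
- Wald χ² and the max-|z| adjustment are asymptotic; with few localities
  they run slightly liberal, which the calibration tests bound (FWER ≤ 0.07
  at nominal 0.05).
- The bundled survey table is summary data (per-network metric values);
  full per-network matrix reanalysis requires the original interaction
  matrices, which are not redistributed here.
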