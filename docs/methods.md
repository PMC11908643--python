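# Methods

## Model

ssblend predicts a quantitative phenotype from SNP allele dosages with a
two-layer blending ensemble. Let the training rows be split into a
base-training part (fraction 1 − H) and a holdout part (fraction H).

**Layer 1 (base learners).** Three heterogeneous regressors are fitted
to the base-training rows:

- ε-SVR, RBF kernel, C = 1, ε = 0.1, γ = 1/m (the classical libsvm
  defaults; `gamma="auto"` in scikit-learn);
- a CART regression tree (unlimited depth, seed-controlled tie-breaks);
- elastic net with mixing α = 0.5, penalty chosen by internal 5-fold
  cross-validation over a 100-point path whose floor is `eps = 1e-4`
  times the maximal penalty (the glmnet convention for n > m).

Features are standardized to zero mean / unit variance using
base-training statistics only, so neither the holdout nor the test set
leaks into the base fits; zero-variance markers get scale 1. The
response is left unscaled.

**Layer 2 (meta-learner).** Ordinary least squares of the holdout
response on the three base predictions plus an intercept, solved by
`lstsq`; rank-deficient designs (base learners are often strongly
correlated) resolve to the minimum-norm solution rather than erroring.
Each layer is trained exactly once per fit.

## Stratified holdout sampling

Conventional blending draws the holdout uniformly at random; its
variance is the problem ssBlending addresses. Two stratifications are
provided, both defaulting to K = 8 layers:

**CA (cluster analysis).** k-means (k-means++ seeding, 10 restarts,
seed-controlled) on the raw dosage matrix; an optional top-variance
marker filter (`ca_top_variance_markers`) trims very wide matrices
first. Sampling weights are proportional to cluster sizes —
proportional allocation preserves the population's composition, which
is the stated purpose of stratifying. Empty k-means clusters are
dropped with a warning (K shrinks).

**PP (phenotype probability).** `[min(y), max(y)]` is cut into K
equal-width intervals, the last right-closed. A Gaussian KDE of the
trait (Silverman bandwidth) is integrated over each interval by the
midpoint Riemann rule on 1000 abscissae spanning the range; interval
masses are renormalized to sum to 1 and become the weights. Intervals
with no members are dropped and the remaining weights renormalized. A
flag (`pp_empirical_counts`) switches the weights to empirical interval
counts for users who prefer the plug-in allocation.

**Quota integerization.** The holdout target is T = round(H·n). Largest
remainder (Hamilton) apportionment assigns floors of the ideal shares
and distributes leftover units by descending fractional remainder, ties
to the lower stratum index — the only standard scheme that guarantees
the quotas sum to T exactly. A quota exceeding its stratum's occupancy
is capped and the overflow re-apportioned over the unsaturated strata by
their residual weights (iterated; terminates because T ≤ n). Within a
stratum, members are drawn uniformly without replacement. With K = 1
the procedure reduces exactly to simple random sampling — the same
generator draw — which the tests verify both bitwise and
distributionally.

## BestH tuning

The holdout rate is searched over H = 0.10, 0.15, …, 0.60 (11 values)
by a single seed-fixed 80/20 inner split of the training set: each H is
fitted on the inner 80% and scored (Pearson r) on the inner 20%; the
argmax is BestH, ties going to the smallest H (the cheapest
meta-training set). One inner split, not repeated CV, keeps the cost
linear in the grid and preserves blending's train-once character. The
same stratification strategy is used inside tuning as in the final fit,
avoiding a train/deploy mismatch. An H producing constant predictions
scores −∞ with a warning; if every H does, tuning raises.

## Simulator

`ssblend.simulate` implements the additive model y = Xβ + e:

- dosages: p_j ~ Uniform(maf_low, maf_high) per marker (defaults
  0.05–0.5), individual dosages Binomial(2, p_j), drawn as the sum of
  two Bernoulli haplotype fields for speed;
- q QTNs sampled without replacement; β ~ N(0, 1) — the β scale is
  immaterial because the residual is calibrated to the genetic
  variance;
- residual e ~ N(0, σ²_e) with σ²_e = var(g)·(1 − h²)/h² computed from
  the *realized* sample variance of g = X[:,qtn]β, which makes
  var(g)/var(y) concentrate tightly on the target h² (at h² = 1 the
  residual is exactly zero). If every sampled QTN is monomorphic the
  QTN set is resampled up to 10 times, then the simulation errors.

Defaults are the study-grid conditions: n = 3000, m = 20000,
h² ∈ {0.2, 0.5, 0.8} × q ∈ {200, 2000, 5000} (`simulate_grid`); QTN
counts above m are capped with a warning so the grid also runs at
reduced scale. Dimensionally β has length q (equivalently m with zeros
off the QTN set).

What the simulator deliberately omits: linkage disequilibrium,
population structure, dominance/epistasis, and realistic allele-count
spectra. Passing tests therefore demonstrate that the algorithms are
implemented correctly and behave sensibly under a known additive
architecture — not that any particular accuracy margin transfers to
real livestock, crop or yeast panels, whose LD and family structure
materially change both the clustering and the prediction problem. In
particular, with independent markers the CA strata are much weaker than
on structured populations.

## Numerical and design choices

- Heritability bounds every analysis: corr(g, y)² → h², so test-set
  Pearson accuracy cannot systematically exceed √h²; tests assert the
  ceiling with a +0.1 finite-sample margin and that accuracy increases
  with h².
- Missing dosages (`NA`, PLINK's `-9`) are imputed with the per-marker
  mean at load; imputation never alters observed entries. Monomorphic
  markers are kept but flagged.
- Outer train/test fraction defaults to 0.2 (configurable); sample
  alignment is by ID intersection in genotype-file order; all indices
  are 0-based internally, files carry IDs only.
- The skewness threshold for the CA/PP recommendation is |skew| ≤ 0.5
  (adjusted Fisher–Pearson) — a conventional "moderate skew" boundary;
  the rule is qualitative guidance, not a guarantee.
- Improvements are reported in percentage points,
  (r_method − r_blending) × 100.
- Determinism: every stochastic step (splits, k-means, holdout draws,
  tree tie-breaks, elastic-net CV folds) is governed by integer seeds;
  replicate/grid seeds are derived via `SeedSequence` so runs are
  reproducible end to end.

## Problem sizes used in the checks

The test-suite and calibration runs use reduced scales chosen to
exercise every code path with stable statistics: heritability
calibration at n = 1000, m = 2000, q = 200 over 20 replicates per h²
level; accuracy ceiling/monotonicity at n = 600, m = 500 over
10 repeats per condition; the strategy comparison at n = 500, m = 300
over 20 repeats with a fixed holdout rate (tuning the full 11-point
grid per repeat changes cost, not the qualitative comparison); the
full-scale 3000 × 20000 grid is generated once to verify structure.

## Known limitations

- The evolutionary-search regression tree used by some reference
  analyses is represented by a standard CART tree behind the same
  interface; only the induction algorithm differs.
- No PLINK-style quality control or sparse-PLS dimensionality
  reduction is performed; inputs are assumed QC'd upstream. The
  top-variance marker filter is a convenience, not a substitute.
- Single-trait, regression-only; no significance testing between
  methods in the benchmark report (per-repeat accuracies are recorded
  so users can test as they see fit).
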