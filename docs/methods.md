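# Methods

## Distance and decomposition

The core statistic is the squared 2-Wasserstein distance in its quantile
representation, d = ∫₀¹ (F_A⁻¹(u) − F_B⁻¹(u))² du.  Both empirical
quantile functions are evaluated on a fixed probability grid
p_k = (k − 0.5)/K, k = 1..K (default K = 1000), using the
left-continuous inverse of the empirical CDF (no interpolation), and d is
the mean of squared differences of the two quantile vectors.  The grid
midpoints avoid u = 0, 1, and the no-interpolation choice has a useful
exactness property: for two samples of equal size n with n | K, d equals
the mean squared difference of the two sorted samples, which serves as an
independent brute-force oracle in the tests.

Moments of the quantile vectors use divide-by-K (population) variances.
With location = (μ_A − μ_B)², size = (σ_A − σ_B)² and
shape = 2σ_Aσ_B(1 − ρ), the identity d = location + size + shape is an
algebraic identity on the quantile vectors and holds to round-off
(verified at 1e−10 relative on 10,000 random pairs).  ρ is the Pearson
correlation of the paired quantiles; because both vectors are
non-decreasing it is nonnegative (Chebyshev's sum inequality), and tiny
negative or above-one values produced by floating arithmetic are clipped
to [0, 1].  Degenerate inputs: if either quantile vector has zero spread
the shape term is zero for any ρ, so ρ is reported as 1 with a degeneracy
flag; if d = 0 all fractions are reported as 0 with the same flag.
Fractions are kept at full precision; rounding is left to output
formatting.

## SP test (permutation + GPD tail)

H₀: F_A = F_B is tested via H₀: d = 0 against d > 0.  The null
distribution is built from N_sub random label permutations that preserve
group sizes (default N_sub = 1000, CLI-overridable), and the empirical
p-value uses a pseudo-count, (#{d_perm ≥ d_obs} + 1)/(N_sub + 1), giving
the floor 1/(N_sub + 1).  Ties count as exceedances (the ≥ convention).

When fewer than 10 permuted values reach the observed statistic the
empirical p-value is resolution-limited, and the tail is refined with a
generalized Pareto distribution: the threshold is the
(N_sub − n_exc)-th order statistic, exceedances above it are fitted by
maximum likelihood (probability-weighted-moments fallback on
non-convergence), and n_exc shrinks from 250 in steps of 10 down to 50
until a goodness-of-fit test at α = 0.05 no longer rejects.  The GoF test
is a Kolmogorov–Smirnov test of the exceedances against the fitted GPD;
with estimated parameters its p-value is conservative (it under-rejects
the fit), which errs toward using more exceedances — acceptable here
because the refined p-value is used for ordering far below any
rejection threshold.  The refined p-value is
(n_exc/N_sub)·(1 − GPD(d_obs − threshold)), floored at 1e−300 so that no
p-value is ever exactly zero.

## ASY test (continuous data)

For continuous, tie-free data the permutation null can be replaced by an
asymptotic one.  Both samples are first passed through the pooled
empirical probability transform (pooled mid-ranks scaled to (0, 1)).
Under H₀ the transformed samples are asymptotically uniform, and the
scaled statistic T = nm/(n+m) · d converges to ∫₀¹ B(t)² dt for a
standard Brownian bridge B — the same limit as the two-sample
Cramér–von Mises statistic.  This transform is what makes the limit
parameter-free: without it the limiting law of nm/(n+m)·d depends on the
underlying density (and for Gaussian tails does not even converge without
additional centering), so a plain variance standardization cannot be
calibrated against a universal reference.  The choice is validated by
calibration: at n = m = 500 the empirical type-I error at α = 0.05 is
0.043–0.047 across seeds (1000 replications).

The reference law is simulated once: bridges on a grid of 1000 equispaced
points from cumulative Gaussian increments with the endpoint pinned to
zero, integral approximated by the grid mean of B², 10⁵ draws by default,
cached to disk (values + metadata; reloaded only when n_sims/grid_size/seed
match).  Analytic checks: mean 1/6, variance 1/45; the discretization
bias of the grid mean is O(1/G²) ≈ 2·10⁻⁷, far below the Monte-Carlo
standard error.  The p-value is the pseudo-counted upper-tail fraction of
the reference at T.  A warning is issued when more than 1% of pooled
values are tied; genuinely discrete data (scRNA-seq counts) should use the
SP test.

## Zero-expression tests

scRNA-seq distributions carry a point mass at zero that is tested
separately from the non-zero part.

**DPZ logistic regression (variant A).**  The per-cell zero indicator is
regressed on condition and the cellular detection rate (CDR, the fraction
of genes detected per cell, computed on the full pre-filtered matrix —
it is a per-cell covariate, not a per-gene one).  The model is Bayesian in
the weakly-informative sense: independent Cauchy priors, scale 2.5 on the
(standardized) condition and CDR coefficients and 10 on the intercept,
with the binary condition centred and the CDR centred and scaled to
sd 0.5.  The fit is the posterior mode (Cauchy-penalized likelihood,
BFGS), and the p-value is a two-sided Wald test on the condition
coefficient using the observed information at the mode (likelihood
information plus clipped prior curvature as fallback when the Cauchy
tails make the observed information indefinite).  The prior resolves
complete separation — estimates stay finite — though the Wald test is
conservative in that regime (Hauck–Donner flattening); full posterior
inference (MCMC) is deliberately out of scope.  Calibration under the
null: rejection 0.054 at α = 0.05 over 500 replications of n = 400
cells.

**CMH test (variant B, paired).**  Per replicate, a 2×2 table of
condition × (zero, non-zero); the Cochran–Mantel–Haenszel chi-square
statistic (1 df) without continuity correction — the uncorrected form
matches the chi-square limit used for calibration and the direct textbook
formula Σ(a_r − E a_r)² / Σ Var(a_r), against which the implementation is
tested to 1e−10.  Strata with a zero row or column margin carry no
information and are skipped; if every stratum is degenerate (e.g. a gene
with no zeros anywhere) the zero stage is uninformative and p = 1.

## Pipelines

**Variant A** (one replicate per condition): DPZ p-value from the
logistic model; SP p-value on the strictly positive values only, with the
decomposition attached; Fisher combination
X² = −2(ln P.zero + ln P.nonzero) against χ²₄.  The SP stage requires at
least 3 non-zero values per condition (quantiles of ≤2 points are
uninformative); when one stage is not computable, P.comb falls back to
the other stage's p-value — combining with a dummy value would
artificially deflate it — and a flag records the skip.  The DPZ stage is
run even when the zero indicator is constant (the prior-regularized fit
then gives p ≈ 1), so an all-zero gene still yields a well-defined,
uninformative result.

**Variant B** (R ≥ 2 replicates per condition): all R_A·R_B
between-condition distances D_BC (on non-zero values, replicates with <3
non-zero values dropped) and all C(R_A,2)+C(R_B,2) within-condition
distances D_WC; a one-sided "greater" Wilcoxon rank-sum test of D_BC vs
D_WC (a true distributional difference makes between-condition distances
stochastically larger; the sidedness is an option).  The exact rank-sum
distribution is used whenever the distance values are tie-free, so
complete separation attains the exact one-sided minimum for the given
group sizes, 1/C(|D_BC| + |D_WC|, |D_BC|) — e.g. 1/C(28, 16) for R = 4.  The overall decomposition is
the average of the D_BC fractions over non-degenerate pairs.  The zero
stage uses per-replicate strata directly in the paired case; unpaired but
balanced designs are rank-paired by zero fraction, and unbalanced designs
skip the zero stage with a flag (log-linear DPZ modelling is out of
scope).  The D_BC/D_WC sets share replicates and are therefore not
independent samples; the rank-sum stage is nevertheless well calibrated
empirically (null rejection 0.026–0.044 at α = 0.05 over 500
replications), i.e. slightly conservative.

Multiple testing uses Benjamini–Hochberg step-up adjustment, applied
separately to the zero, non-zero and combined columns; NaNs (skipped
stages) pass through unadjusted.

Per-gene reproducibility: each gene's permutation seed is derived from
the master seed and a CRC-32 of the gene id, so results are independent
of gene order.

## Simulator

The single-cell generator reproduces the classic scDD benchmark design:
1000 genes, two conditions with C cells each, 100 DD genes split 25/25/25/25
over DE/DP/DM/DB and 900 null genes split 450/450 over EE (one NB
component) and EP (two NB components, same mixing in both conditions).
Defaults and choices:

- baseline NB mean drawn log-uniformly on [20, 500] and NB size
  (dispersion) uniformly on [0.5, 5] — realistic overdispersed magnitudes
  for normalized counts; the original benchmark inherits empirical
  hyperparameters from an example dataset that are not printed anywhere,
  so these ranges are explicit and config-exposed;
- fold change between modes FC ~ Normal(fc_mean, 2) truncated at 1.5,
  with fc_mean ∈ {2, 4, 6} for weak/medium/strong DD (default 4); the
  truncation prevents mode collisions;
- DP mixing proportions 1/3 vs 2/3 (unstated in the benchmark's
  description; exposed in the config), EP mixing 0.5;
- DB condition A is unimodal at the midpoint of the two modes;
- zeros arise naturally from the NB draws — no extra dropout layer, since
  the non-zero stage of the pipelines is evaluated on the non-zero part.

What the simulator does *not* emulate: library-size variation and
cell-level coverage effects (CDR is essentially constant by design), batch
or replicate structure within conditions, gene–gene correlation, and the
Dirichlet-process machinery of scDD itself.  Passing benchmarks therefore
demonstrate correctness and calibration of the testing machinery under a
clean generative model, not robustness to normalization artefacts in real
data.

The continuous generator draws i.i.d. normal or gamma pairs for
validating the SP/ASY tests and the decomposition against closed-form
population values (e.g. N(0,1) vs N(2,1) → d = 4, pure location; N(0,1)
vs N(0,3) → d = 4, pure size).

## Evaluation

Positive calls use p ≤ threshold (consistent with the discrete support of
permutation p-values).  Sensitivity/specificity/precision/accuracy report
None on empty denominators.  ROC curves score genes by −p and the
trapezoidal AUC equals the tie-averaged Mann–Whitney statistic (tested
against that oracle).  Per-category power is the per-category fraction of
detections among DE/DP/DM/DB.  The default p-value for simulator
benchmarks is P.nonzero, matching the benchmark's restriction of method
comparisons to the non-zero part.

## Problem sizes

The packaged verification runs use sizes chosen to make Monte-Carlo error
small relative to the tolerances while keeping the full suite fast:
10,000 random pairs for the decomposition identity, 1000 pairs for the
oracle equivalence, 1000 replications for SP (n = m = 50, Gamma) and ASY
(n = m = 500, normal) calibration, 10⁵ draws for the bridge reference,
500 replications for variant-B calibration, and a reduced benchmark of
200 genes (10 per DD category, 80 EE, 80 EP; C = 500; fc_mean = 6;
N_sub = 500) for the power pattern.

## Known limitations

- The SP test's GPD refinement orders extreme p-values correctly but far
  below the permutation floor the absolute values rest on the tail-model
  extrapolation; with complete separation the refined value can reach the
  1e−300 floor.
- The ASY test is for continuous data only; heavy ties void its limit.
- The DPZ Wald test loses power near complete separation.
- Variant B needs ≥ 2 informative replicates per condition after the
  minimum-non-zero filter; unbalanced unpaired designs get no zero-stage
  p-value.
- Inputs must be pre-filtered and pre-normalized; the package validates
  but never normalizes, and shape-changing normalizations (quantile
  normalization, gene-wise standardization) would invalidate the
  decomposition's interpretation.
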