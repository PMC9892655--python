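# Methods

## Model

`dtusage` tests for differential transcript usage (DTU): changes between
conditions in the *relative* composition of a gene's transcripts,
independent of the gene's overall expression level.

Let `Y_gti` be the expression estimate of transcript `t` (of `T_g`
transcripts in gene `g`) in sample or cell `i`, `Y_g.i = sum_t Y_gti` the
gene total, and `U_gti = Y_gti / Y_g.i` the usage. Each transcript is
modelled marginally with a quasi-binomial GLM:

    E[U_gti | X_i, Y_g.i] = pi_gti,      logit(pi_gti) = X_i' beta_gt
    Var[U_gti | X_i, Y_g.i] = pi_gti (1 - pi_gti) / Y_g.i * phi_gt

i.e. a binomial-proportion variance with the gene total as the effective
trial count, inflated (or deflated) by a transcript-specific dispersion
`phi_gt`. Only the first two moments are specified; no full likelihood is
assumed. Coefficients are log-odds of transcript choice, so any contrast
`L'beta` is a log-odds ratio of usage between covariate patterns.

Assumptions worth keeping in mind:

- transcripts are modelled one at a time; the negative within-gene
  correlation of usages is not modelled jointly (unlike a
  Dirichlet-multinomial across the whole gene);
- `Y_gti` is treated as known; quantification uncertainty in the
  abundance estimates is ignored;
- observations with `Y_g.i = 0` carry no usage information (the variance
  above is undefined) and are given zero weight, and are excluded from
  the effective sample size and residual degrees of freedom.

## Estimation

The GLM is fitted by iteratively reweighted least squares with prior
weights `w_i = Y_g.i`, working weights `w_i pi(1-pi)`, convergence when
the relative quasi-deviance change drops below 1e-8 (at most 50
iterations). Initialisation is at the empirical usages shrunk toward 1/2
by `0.5/n_eff`, which avoids `logit(0)` at the start. A fit whose linear
predictor exceeds 15 in absolute value (fitted usage within 3e-7 of 0 or
1) is treated as quasi-complete separation: no finite estimate exists, the
transcript is flagged and excluded from downstream inference and from
empirical-null estimation. For a saturated group-means design the fit has
a closed form — the gene-total-weighted pooled proportion `sum(y)/sum(Y)`
per group — which the test suite uses as an exact oracle.

Dispersion is estimated from Pearson residuals,

    phi_hat = sum_i w_i (u_i - pi_i)^2 / (pi_i (1 - pi_i)) / (n_eff - p),

chosen over the deviance-based alternative, which is biased at small
totals. Underdispersion (`phi_hat < 1`) is retained, not floored.

## Empirical-Bayes moderation

Per-transcript dispersions with few residual degrees of freedom are
noisy. They are shrunk toward a common prior by the standard
moment-matching procedure on the log scale: observed dispersions are
modelled as `s0^2 * F(df, d0)` draws, `(d0, s0^2)` are solved from the
mean and excess variance of `log(phi_hat)` via digamma/trigamma identities
(with a Newton inversion of the trigamma function), and each transcript
receives

    phi_post = (d0 * s0^2 + df * phi_hat) / (d0 + df).

Saturated fits (`phi_hat = 0`, log undefined) are excluded from prior
estimation and assigned `phi_post = s0^2`. When the observed spread of
log-dispersions does not exceed what sampling alone explains, `d0` is
infinite and all transcripts receive `s0^2`. With fewer than two usable
dispersions no moderation is performed.

Contrasts are tested with moderated t-statistics
`t = L'beta / sqrt(phi_post * L' (X'WX)^{-1} L)` on `df + d0` posterior
degrees of freedom (standard normal when `d0` is infinite).

## Empirical-null recalibration

In large-scale single-cell settings the theoretical t null can fail
(correlation between transcripts and between cells, unmodelled
heterogeneity), making raw p-values mis-calibrated. Following the
empirical-null idea, two-sided p-values are mapped to z-scores,

    z = qnorm(p / 2) * sign(t),

a normal `N(mu*, sigma*)` is fitted to the central mass of the z-scores,
and recalibrated statistics

    z* = (z - mu*) / sigma*,      p* = 2 * pnorm(-|z*|)

replace the originals before Benjamini-Hochberg adjustment (applied per
contrast). Note the sign convention maps significant positive-t tests to
large *negative* z; since the recalibration depends only on the centred
magnitude, results are invariant to this global flip (asserted by test).
When `(mu*, sigma*) = (0, 1)` the recalibrated p-values are exactly the
normal-quantile round trip of the raw ones.

The null fit is a maximum-likelihood fit in the locfdr style: z-scores
inside a central window enter a truncated-normal likelihood, and the
*count* of z-scores falling inside the window enters a binomial term in
which the null proportion `p0 <= 1` is profiled out. The count term
matters: the pure truncated likelihood on a narrow window is nearly flat
in `(mu, sigma)` and can diverge (as `sigma` grows the truncated density
tends to a uniform over the window), whereas the constraint `p0 <= 1`
caps the window probability at the normal's own mass and restores
identifiability. The default window is the adaptive ML interval

    median(z) +/- 4.3 * exp(-0.26 * log10(N)) * s,

with `s` the normalised interquartile range of the z-scores: wide when
few tests are available (where a narrow window makes the fit unstable)
and narrowing as `N` grows (where tail contamination by true effects is
the bigger risk). A fixed quantile window, e.g. the central 50%, is
available through the `central` parameter. With fewer than 200 finite
z-scores the fit falls back to the theoretical `(0, 1)` with a warning.
Optimisation is Nelder-Mead from `(median, 1.4826 * MAD)` with fixed
tolerances, so results are deterministic.

## Filtering

Two retention strategies precede fitting; both end by dropping any gene
left with a single transcript (usage analysis is vacuous there).

- **edgeR-style** (lenient): keep a transcript if its CPM is at least
  `min_count` in at least `n_required` samples and its CPM sum is at
  least `min_total_count`. Presets: bulk `(10, min(10, 0.7 n_s), 10)`;
  single-cell `(1, 0.5 n_s, 0)`, with `n_s` the smallest group size. A
  fractional `n_required` acts as a ceiling ("at least n samples"). This
  is the pure CPM thresholding rule as usually described; it does not
  replicate `filterByExpr`'s internal library-size-adjusted cutoff.
- **DRIMSeq-style** (stringent), three sequential steps on raw counts:
  count >= 10 in >= `n_s` samples; within-gene proportion >= 10% in >=
  `n_s` samples; and removal of every transcript of a gene whose total
  falls below 10 in *any* sample.

## Synthetic benchmark generator

The generator emulates a two-group, swap-perturbed benchmark: per-gene
baseline usages from a flat Dirichlet; gene-level mean totals lognormal
around `mean_total` (default 100 counts/cell, log-sigma 1); per-cell gene
totals negative binomial (gamma-Poisson, dispersion 0.3); transcript
counts Dirichlet-multinomial around the baseline with concentration
`1/usage_overdispersion` (default 1/0.02 = 50, i.e. moderate usage
overdispersion, Pearson phi around 2-3 at the default totals; 0 gives
conditionally multinomial counts with phi ~ 1, asserted by test). Defaults
are 3000 genes with 2-5 transcripts each and 20 vs 20 cells.

DTU ground truth is introduced non-parametrically: in a 15% sample of
genes (uniform over genes with >= 2 transcripts), `k` transcripts' count
rows are permuted by a uniformly random cycle *in one group only*, with
`k = min(T_g, max(2, Binomial(T_g, 1/3)))`. A cycle guarantees every
selected transcript actually changes usage. Swapping leaves every
per-cell gene total unchanged, so the signal is pure DTU with no
differential gene expression. Swaps are applied to counts — the scale the
model operates on; proportion-scale swapping (which perturbs counts of
non-selected transcripts as a side effect) is out of scope.

What the generator does *not* emulate: transcript-length and coverage
biases, library-size variation between cells, correlated gene programs,
dropout beyond what the NB totals produce, and quantification
uncertainty. Calibration and FDR results on this generator therefore
demonstrate internal statistical correctness of the pipeline, not
robustness to those real-data artefacts.

## Evaluation

A transcript is "true DTU" iff it belonged to a swap set. Calls are
`BH-adjusted p* <= alpha`; missing statistics are non-calls. Confusion
counts give `TPR = TP/(TP+FN)` and `FDP = FP/(FP+TP)` (0 by convention at
zero calls). The FDR-TPR curve ranks transcripts by `p*` with
deterministic tie-breaking (|t| descending, then transcript id) and marks
working points at nominal 1%, 5% and 10% BH levels, flagged as achieved
when the empirical FDP is at or below the nominal level. With repeated
simulations, curves are computed per repeat; any averaging is pointwise
over ranks and left to the caller.

Per-gene visualization data report, per transcript and group, both the
raw mean usage and the model-estimated mean usage (the gene-total-weighted
pooled proportion). The two diverge exactly when cells with small gene
totals sit at extreme usages — the weighted estimate discounts them, the
raw mean does not — which is the motivating case for weighting.

## Problem sizes and determinism

The shipped benchmark settings (5 seeds x 3000 genes, ~10,000 retained
transcripts, 40 cells) run in under a minute total; the null-calibration
check uses ~2,300 transcripts. All randomness flows through
`numpy.random.default_rng` seeds carried in the parameter objects, so
matrices, truth lists and result tables are bit-identical across runs
with the same seed.

## Known limitations

- Marginal per-transcript modelling double-counts genes in the sense
  that a swap between two transcripts yields two correlated discoveries.
- The empirical-null correction assumes the central z-scores are
  dominated by nulls; it degrades when the true-effect fraction is very
  large or effects are weak and central.
- Equivalence-class input must already be gene-unambiguous (a validator
  drops multi-gene classes); the package does not build classes.
- `d0 = 0` (no moderation) and `d0 = inf` (complete pooling) are handled,
  but `df_residual = 0` transcripts never receive their own dispersion
  and rely entirely on the prior.
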