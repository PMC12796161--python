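# Methods

## The analysis problem

The package studies multivariate association between two blocks of
subject-level variables: an X block combining questionnaire scores (the seven
PSQI sleep-quality components; eleven ASR depressive-symptom items) and
grey-matter volume means over 262 whole-brain parcels, and a Y block of
motor-performance measures. The scientific question is whether a latent mode
— one linear combination per block, maximally correlated between blocks —
links behavior and brain structure to motor performance, and whether that
mode generalizes to unseen subjects and replicates across cohorts.

## Regularized CCA

For standardized matrices `X (n×p)` and `Y (n×q)` with sample covariances
`Sxx`, `Syy`, `Sxy` (1/(n−1) normalization), the solver maximizes
`corr(Xu, Yv)` under the regularized constraints `u′[(1−cx)Sxx + cx I]u = 1`
and `v′[(1−cy)Syy + cy I]v = 1`, `cx, cy ∈ [0, 1]`. All modes come at once
from the SVD of the doubly whitened cross-covariance
`Rx^{−1/2} Sxy Ry^{−1/2}` with `R = (1−c)S + cI`; the k-th singular triplet
maps back through the whitening transforms. `c = 0` is classical CCA (and
requires a nonsingular covariance; the solver errors with an instruction to
regularize otherwise); `c = 1` replaces the covariance metric by the
identity and yields the PLS limit (weights = singular vectors of the raw
cross-covariance). The path between the limits is continuous, which the test
suite checks numerically.

Numerical choices:

* inverse square roots are taken by eigendecomposition; an eigenvalue below
  `1e−10` times the largest raises rather than being clipped silently;
* weights are renormalized exactly under the regularized metric after the
  mapping back, so mode variates are orthonormal under that metric;
* sign convention: each mode is flipped so the largest-magnitude Y-side
  weight entry is positive. CCA is sign-invariant; a deterministic rule
  makes runs and repeats comparable;
* reported per-mode "training correlations" are Pearson correlations of the
  training variates. At `c = 0` they equal the singular values; at `c > 0`
  the singular values live in the regularized metric and are not
  correlations, while the Pearson values remain consistent with what
  projection of the training data returns.

Loadings are Pearson correlations of each input variable with its own
side's variate; cross-loadings with the opposite side's variate. At the CCA
limit the stationarity conditions give exactly
`cross-loading = loading × r`, which the suite asserts to 1e−10. The
redundancy index of Y for mode k is `mean(loading²) × r²` — the share of Y
variance explained through the X-side variate.

## Deconfounding without leakage

Age, age², and sex are removed from every block (plus total intracranial
volume whenever the X block contains GMV, and one-hot cohort indicators when
cohorts are pooled) by OLS of each feature on an intercept plus mean-centered
confounds, followed by z-scoring of the residuals. Every parameter —
regression coefficients, confound centering means, residual means and SDs —
is estimated on training rows only and frozen; held-out rows are transformed
row-independently. Standardization is bundled with residualization because
the blocks mix units (mm³ parcels vs questionnaire points); it is a flag
(default on). Features whose training residuals have zero variance are
dropped and recorded; linearly dependent confound columns are dropped with a
warning.

## Multiple-hold-out framework

Defaults mirror the study design: 100 outer splits into 80% optimization /
20% hold-out; within each optimization set, 50 inner 80/20 train/test
splits. Splitting is family-respecting: families are shuffled and assigned
whole to the held-out side until its count first reaches the target
fraction, so no family ever straddles a split (asserted exhaustively in
tests).

Hyperparameter selection scores each candidate `(cx, cy)` pair on two axes:
the mean inner-test mode-1 correlation, and the stability of its weight
vectors across the inner refits (mean absolute pairwise cosine similarity,
averaged over the X and Y sides; absolute value absorbs sign
indeterminacy). Both axes are min-max rescaled across the grid — the two
criteria have no common scale otherwise — and the candidate with the
smallest Euclidean distance to the ideal point (1, 1) wins; ties break
toward the stronger penalty. A constant axis is uninformative and is mapped
to the ideal so the other axis decides. The default grid crosses
`{0, 0.1, 0.3, 0.5, 0.7, 0.9, 0.99, 1}` with itself, spanning the CCA and
PLS limits with density near the extremes.

Per outer repeat, the winning pair is refit on the full optimization set and
the hold-out subjects are projected onto the frozen deconfounders and
weights; the hold-out canonical correlation is the Pearson correlation of
the projected variates. Reported correlations are means over repeats;
loadings are computed on each repeat's optimization set (a flag switches to
the hold-out set) and averaged after aligning each repeat's sign to the
first successful repeat via the weight-vector dot products. Redundancy
indices per repeat use that repeat's Y loadings and hold-out correlation.
Per-repeat seeds derive from the master seed by seed-sequence spawning, so
results do not depend on execution order. A failed repeat is recorded and
excluded with a warning.

`deconfound_mode="all"` fits deconfounders on all rows instead of the
training rows. It exists purely as an instrumented positive control: with a
full-sample regression every hold-out residual inherits a projection of the
training noise of its own side, so the direction the solver overfits on the
training data reappears in the hold-out residuals of both sides and the null
hold-out correlation inflates. The effect scales like `n_confounds/n`,
which is why the leakage experiment uses a deliberately small cohort
(n = 60): at that size the inflation (~0.02) is detectable over 50 seeds
with a paired one-sided t-test, while at n ≳ 100 it drowns in Monte-Carlo
noise.

## Permutation inference

Significance of the first mode uses the completed outer splits with the
regularization pair fixed to the per-component median of the selected pairs
(the inner search is not repeated under the null). Each permutation draws
one row mapping of Y and applies it across all outer folds; the Y-side
deconfounder is refit on the permuted training rows so the null pipeline
matches the observed one stage for stage. The summary statistic is the
Fisher-z mean (`tanh(mean(atanh r))`) of the hold-out correlations, and
`p = (1 + #{null ≥ observed}) / (1 + n_perm)` — the standard positive-biased
estimator, which avoids p = 0 and differs from the raw proportion by at most
`1/(n_perm+1)`.

Exchangeability blocks: the default permutation scheme composes
within-family shuffles with swaps of whole same-size families, so family
structure is preserved under the null; `mode="free"` permutes all subjects
unrestricted. Both are exposed because either reading of the design is
defensible; the block-respecting scheme is the stricter default.

## Model comparison and replicability

Hold-out correlation vectors (Fisher-z transformed) and redundancy-index
vectors of two models are compared pairwise by the corrected resampled
t-test: `t = mean(d) / sqrt((1/K + n_test/n_train)·var(d))`, `df = K−1`.
The correction term accounts for the overlap of optimization sets across
repeats, which makes the naive paired test anti-conservative; the corrected
|t| is strictly smaller. Families of p-values are Benjamini–Hochberg
FDR-adjusted per metric.

Across samples, averaged first-mode loadings are compared by Spearman rank
correlation over shared feature names, separately per scope — GMV parcels,
and pooled PSQI+ASR items — because motor instruments differ between
cohorts and those comparisons stay conceptual. P-values are FDR-adjusted
across all pairs and scopes.

Cohort characterization uses Welch's t-test (Satterthwaite df) with pooled-SD
Cohen's d for approximately normal measures, and the Mann–Whitney U with the
rank-biserial correlation `2U/(n1 n2) − 1` for questionnaire scores. Cohen's
d keeps the conventional pooled-SD form even though the test is Welch's.

## Synthetic cohorts

The generator emulates the statistical skeleton of the study cohorts, not
their content: one latent factor `z ~ N(0,1)` drives all domains
(`x = a z + Γx c + f + ε`, `y = b z + Γy c + f + η` with isotropic noise),
confounds are age (uniform on a configurable range), age² (derived), sex
(balanced binary), and TIV (log-normal around 1450 cm³), confound effects
are per-SD additive vectors, and families are drawn with sizes in a
configurable range (optionally exactly `n_families`), with an optional
shared Gaussian family intercept (default SD 0). Questionnaire-like integer
clipping exists for I/O realism only and is off by default — the analysis
operates on real matrices.

The planted first canonical correlation has the closed form
`ρ = sqrt(‖a‖²/(‖a‖²+σx²)) · sqrt(‖b‖²/(‖b‖²+σy²))`, verified in the test
suite against a brute-force population CCA on the explicitly constructed
two-block covariance; the formula (and hence the oracle) is only valid with
zero confound and family effects, and the function refuses otherwise.

What the generator does not emulate: item-level questionnaire
distributions (only ranges), spatial covariance of parcels, multi-modal age
structure, missingness mechanisms (missing cells are injected by tests, not
the generator). Passing recovery tests therefore shows the machinery is
correct and calibrated under the assumed single-factor linear-Gaussian
structure — not that real cohorts satisfy that structure.

## Experiment sizes

The standard self-checks (`modecca.experiments`) use scaled-down designs
chosen so Monte-Carlo error is well inside the tolerance being checked:

* recovery: ρ = 0.5, n = 600, p = 30 (7+11+12), q = 5, 20 outer × 10 inner
  repeats over the full default grid; tolerance ±0.1 on the mean hold-out
  correlation;
* type-I calibration: 200 null cohorts (n = 160, psqi-vs-motor model),
  8 outer × 4 inner, 4-pair grid, 99 permutations; the rejection count at
  α = 0.05 is compared with the exact central 95% binomial interval;
* leakage control: 50 null cohorts (n = 60) with a planted age effect on
  both sides, paired leak-free vs leaky runs.

## Known limitations

* Deflation uses successive singular triplets of one whitened
  cross-covariance; no re-deflation between modes. Higher modes of a
  single-mode construction correctly generalize near zero, but multi-mode
  recovery beyond the first mode is not a validated use case.
* The stability-distance selector's axis scales (min-max) and similarity
  metric (absolute cosine) are explicit design choices; other toolkits make
  different ones, and selected pairs are comparable only within one grid.
* The corrected resampled t-test is a heuristic; its type-I control is
  approximate by construction.
* With very small hold-out sets (< ~15 subjects) hold-out correlations are
  noisy and the permutation p conservative.
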