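# Methods

`immunage` implements an analysis pipeline for asking how a disease state
(here modelled after treated chronic HIV infection) distorts the normal
aging of the immune system, using only parameters measurable in blood: flow
cytometry frequencies and MFIs, plasma cytokines and soluble receptors, and
serology titers. The pipeline has four statistical components plus a
synthetic-cohort generator that provides a known ground truth for testing
all of them.

## Inflammatory index

Candidate plasma markers are reduced by backward stepwise regression of
chronological age on the markers. The default criterion is AIC on the
Gaussian linear model: starting from the full model, the marker whose
removal most lowers AIC is dropped until no removal lowers it. Two variants
are exposed: drop-while-max-p (threshold 0.157, the AIC-equivalent p cutoff)
and a 10-fold cross-validated lasso. Greedy backward elimination is not
guaranteed to find the AIC-optimal subset; on well-separated synthetic
instances it does, and the test suite checks one such instance against
exhaustive enumeration of all 2^10 subsets.

The selected markers x_i are standardized with pooled-cohort mean and SD
(z_i = (x_i − m_i)/s_i), and the index is

    index = sign × Σ_i w_i z_i

with w the unit-norm first-principal-axis loadings of the standardized
matrix and sign ∈ {+1, −1} fixed so the index has non-negative Spearman
correlation with age on the fitting data (PC loadings are sign-ambiguous).
Pooled (not per-group) standardization is deliberate: the index is compared
across groups, and per-group standardization would remove exactly the group
difference of interest. Group contrast uses Welch's two-sided t-test.
Applying a fitted index to new participants reuses the stored constants and
never refits; scores are therefore invariant (to ~1e-9) under positive
affine rescaling of the raw marker columns only when the model is refit on
the rescaled data.

## Age-association screen

Each parameter is tested within each group for Spearman correlation with
age: average ranks for ties, two-sided p from the t-approximation
t = ρ√((n−2)/(1−ρ²)), appropriate at the cohort sizes involved (~100 per
group). Significance is raw p < α (default 0.05) with no multiplicity
adjustment — this matches the screening convention the pipeline emulates —
but a Benjamini–Hochberg flag is available, and with ~1,357 parameters the
unadjusted screen is expected to flag ~5% of null parameters; the null
calibration test verifies exactly that. Constant columns yield an undefined
ρ and are excluded from significant sets rather than erroring the screen.
Cross-group classification partitions significant parameters into shared /
exclusive sets, and shared ones into same- vs opposite-direction by the sign
product of the two ρ values. "Top" lists use the strict inequality
|ρ| > threshold (default 0.4).

## Penalized age model with bootstrap stability selection

The model-building protocol, applied per participant group to the
parameters that passed that group's screen:

1. **Mixing/penalty selection.** The elastic net is parameterized as in
   glmnet: penalty λ[α|β|₁ + (1−α)/2|β|₂²] with α scanned over
   {0, 0.05, …, 1}. For each α, a 50-point geometric λ path is laid from
   λ_max (the smallest λ zeroing all coefficients, mixing floored at 1e-3
   for ridge-ward α) down to λ_max/100, and k-fold CV (default 10-fold)
   repeated R times (default 500; desk-scale runs use 20–50) gives an
   averaged validation RMSE per (α, λ). α* is the smallest α attaining the
   minimal averaged RMSE (ties resolved ridge-ward for stability). λ_min
   minimizes the averaged RMSE at α*; λ_1se is the largest λ whose averaged
   RMSE is within one standard error of that minimum. The one-SE band is
   cv.glmnet's quantity — per-repeat SD across fold RMSEs divided by √k —
   averaged over repeats: repetition stabilizes the band. (Dividing instead
   by √(Rk) would shrink the band to zero as R grows and collapse λ_1se
   onto λ_min, producing dense models.) A Nadeau–Bengio variance-corrected
   band is available behind a flag. Features are standardized inside each
   training fold only, so no validation-fold information leaks into the fit.

2. **Stability selection.** Participants are resampled with replacement
   (same n) B times (default 500; tests use 100) and the elastic net is
   refit on each resample at α* with λ held at the full-data λ_1se — the
   bootstrap assesses the λ_1se model. Per-resample λ re-selection by a
   single internal CV is available as an option. A marker is retained if its
   coefficient is nonzero in strictly more than the retention threshold
   (default 250 of 500, i.e. a strict majority; scaled runs use >50 of 100).
   Degenerate resamples with constant age are redrawn and logged.

3. **Final fit.** Ordinary least squares of age on the retained markers
   (standardized; coefficients in years per SD). Collinear retained sets
   raise an error naming a dependent subset found by pivoted QR.

`tune()` wraps 1–3 behind a 70/30 train/test split stratified by age decile
(so the two splits cover the same age range), reports held-out R²/RMSE, and
computes permutation feature importance as the mean increase in test RMSE
over 20 shuffles of each retained column.

A fitted model applied to another group (or any new participants) reuses its
training standardization and coefficients verbatim. The combined model takes
the union of two group-specific marker sets (first model's order, then the
second's novel markers) and refits OLS separately per group, giving one
signature with group-specific coefficient vectors.

## Aging rate and age advancement

Aging rate is predicted age divided by chronological age. Strata are Young
(< 40 yrs), Middle (40–59) and Old (≥ 60), with half-open boundaries (40 →
Middle, 60 → Old). Within each stratum (and pooled, "all") the case group's
mean rate is compared to the reference with Welch's t-test (pooled-variance
t available). The percent difference is 100(μ_case − μ_ref)/μ_ref, and the
age advancement in years is

    advancement = (μ_case − μ_ref) × mean chronological age of the
                  reference group in that stratum,

chosen because a rate excess of 18.47% at a reference mean age of 30.1 yrs
then corresponds to ≈ 5.6 yrs — the scale on which such differences are
usually reported. Strata missing a group are reported as untestable rather
than dropped.

## Synthetic cohorts

The generator draws a two-group cohort (default 104 per group) over a
configurable age range (default 19–77, uniform; an optional Young/Middle/Old
stratified draw is provided for rate studies) and a feature matrix (default
1,357 parameters) with four kinds of planted age signal: shared between
groups, exclusive to either group, and opposite-direction (default counts
78/164/378/35, the partition implied by a 277-vs-491 significant screen with
113 overlapping parameters of which 78 agree in direction). A planted
feature is ±(latent age) plus Gaussian noise whose SD is calibrated by
bisection on a large fixed reference sample so the population Spearman
correlation with age hits the configured target (default 0.3, the
weak-correlation regime typical of immune parameters; rank-based targets
admit no closed-form noise mapping, hence the numerical calibration).
Group-exclusive features are mean/variance-matched noise in the silent
group, so groups are not trivially separable.

The plasma block (default 26 markers) loads on a single latent inflammatory
factor that increases with age (standardized age plus factor noise of SD
1.5, giving the weak index–age correlation regime), with linearly declining
loadings and an additive factor shift (default +0.5) in the case group.

Latent immunological age equals chronological age except for case-group
participants in a flagged stratum (default Young), whose latent age is
multiplied by the aging-rate multiplier (default 1.18); the multiplier feeds
every planted feature of those participants, mirroring the interpretation
that young cases carry systemically older immune profiles. A single root
seed drives independent substreams for ages, planted features, the plasma
block, and filler noise, so outputs are bit-reproducible.

What the generator does **not** emulate: compositional constraints among
cell subsets (frequencies summing within a gating hierarchy), heavy-tailed
or bounded marker distributions, batch effects, and missingness. Passing
tests therefore demonstrate that the statistical machinery recovers planted
structure under clean Gaussian noise — not that the pipeline is robust to
every artifact of real cytometry data. No marker distributions are asserted
as faithful; all distributional choices are config-exposed stand-ins.

## Numerical choices and scales

- Elastic-net fits use coordinate descent (scikit-learn `enet_path`) with
  warm starts along descending λ; default tolerance 1e-4, tightened (1e-12)
  when resolving the vanishing-penalty OLS limit.
- The AIC used for stepwise elimination is n·log(RSS/n) + 2(k+1); constant
  offsets cancel in comparisons.
- Welch tests on two identical constant samples return (0, 1) rather than
  NaN, so degenerate toy inputs behave as the null they are.
- Test-suite and acceptance-script problem sizes are desk-scale by design:
  CV repeats 20–50, B = 100 bootstraps, retention threshold > 50 of 100
  (the same strict-majority fraction as 250 of 500), cohorts of 80–209
  participants; `PenalizedSpec` defaults remain the full-scale protocol
  (500/500/>250). Reported results carry the repetition counts used.
- End-to-end runs write all artifacts as TSV/JSON with fixed float
  formatting; artifact paths in the manifest are relative to the output
  directory, so a rerun with the same config and seed is byte-identical.

## Known limitations

- Greedy backward elimination can miss the AIC-optimal subset on highly
  collinear panels; the exhaustive-search guarantee is only verified on
  separated synthetic instances.
- The unadjusted screen at α = 0.05 over ~1,357 parameters is deliberately
  anticonservative (it reproduces the emulated convention); use the BH flag
  for error-controlled inference.
- Rate-recovery accuracy is bounded by regression attenuation: a predictor
  built on noisy features under-recovers a planted rate multiplier (≈16.7%
  recovered for a planted 18% at feature–age ρ = 0.9), an intrinsic
  property of prediction-based age acceleration estimates.
- The per-group refit of the combined model partially absorbs a planted
  acceleration confined to one stratum of one group; group contrasts of
  rates are correspondingly conservative.
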