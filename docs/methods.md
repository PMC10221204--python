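# Methods

This note documents the statistical models, the tunable parameters, the
synthetic-data generators and the numerical choices behind `parpbridge`.

## Calibration model

Instrument response is the analyte/IS peak-area ratio; concentration enters
in ng/mL. The model is a straight line fitted by weighted least squares,
solved via a least-squares factorisation of the √w-scaled design matrix
(numerically safer than forming the normal equations, which the test suite
uses as an independent oracle). Candidate weights are the three used in
regulated bioanalysis: 1, 1/x, 1/x². Each fit reports

* `ss_` — weighted residual sum of squares Σ wᵢ(yᵢ − ŷᵢ)²;
* `r_` — the *weighted* Pearson correlation between observed and fitted
  responses (whether published correlation coefficients in this setting are
  weighted or unweighted is rarely stated; the weighted form is consistent
  with the loss actually minimised, and a configurable linearity check at
  r ≥ 0.997 is exposed in the pipeline config);
* `aic_` — n·ln(SS_w/n) + 2k with k = 2. AIC for weighted regression has no
  single convention; this Gaussian-profile form is kept in one place so an
  alternative can be swapped in;
* `re_by_point_` / `sum_abs_re_` — percent relative error of each
  back-calculated concentration, %RE = (C_found − C_nom)/C_nom·100.

Back-calculation is the exact inverse (y − a)/b and deliberately does not
truncate to [LLOQ, ULOQ]; range flagging belongs to the caller.

### Heteroscedasticity F-test

Replicate response variances at the ULOQ and LLOQ are compared by
F = s²_ULOQ/s²_LLOQ with (n_hi − 1, n_lo − 1) degrees of freedom against the
upper α quantile, α = 0.01 by default. Responses grow with concentration, so
under proportional noise the ULOQ variance is the larger one; a
`two_sided=True` variant (larger/smaller variance against the α/2 quantile)
is available. A single run of duplicate calibrators leaves the test with
(1, 1) df and essentially no power — the critical value at α = 0.01 is
≈ 1.6·10⁴ — so selection should be run on replicates pooled across runs
(`gen_calibration_study` pools three, giving six replicates per level),
mirroring how linearity is assessed over multiple runs in practice.

### Weighting selection

If the F-test is not significant the data are treated as homoscedastic and
w = 1 is kept. Otherwise candidates are ranked lexicographically by
AIC → SS → Σ|%RE| → |1 − r|, ties broken toward the stronger weighting. AIC
leads because it is the only criterion framed as model comparison; in
practice the criteria rarely disagree. Floating-point dust is snapped to
zero before ranking (SS below 1e−16 of the weighted total SS, Σ|%RE| below
1e−9, |1 − r| below 1e−12) so that a noise-free data set is recognised as a
genuine three-way tie rather than ranked on rounding noise.

## Acceptance rules

Acc% = 100·mean/nominal; CV% uses the sample (n − 1) standard deviation.
Bands are boundary-inclusive: 115.0 passes, 115.1 fails. The standard band
is 85–115% with CV ≤ 15; the LLOQ band is 80–120% with CV ≤ 20. Both are
plain dataclasses and fully configurable. Between-run summaries pool all
replicates across runs into one mean/CV (the n = 15 presentation style); an
ANOVA-based intermediate-precision decomposition is out of scope.

QC placement: qc_low = 2.55·LLOQ, qc_mid = 0.34·ULOQ, qc_high = 0.85·ULOQ.
The mid factor is 0.34 (not "35% of the range") because that is the value
that reproduces the validated mid-QC levels exactly; it is exposed in the
function signature.

Recovery divides each normal-extraction replicate signal by the mean
post-extraction signal (unpaired design: the replicate count, and hence the
CV, comes from the normal-extraction side). The signal is the analyte/IS
area ratio by default so IS variability cancels; `use_ratio=False` gives
raw-area recovery. The IS-normalised matrix factor is a ratio of ratios per
donor, MF_analyte/MF_IS with MF = post-extraction area / mean neat area; a
matrix effect common to analyte and IS cancels exactly, which is the point
of IS normalisation and is property-tested.

## Bridging

CF is the unweighted arithmetic mean of per-sample C_DBS/C_pla ratios —
a deliberate choice of a scale-free single number over a formula involving
hematocrit. Geometric-mean and regression-through-origin pooling are
available behind `DbsToPlasmaConverter(method=...)` but are not default.
Eligibility: hematocrit within the closed interval [29, 45]% (the validated
DBS window) and determined no more than 14 days before sampling; a missing
hematocrit excludes the sample, a missing determination date does not.
The ≥ 40 samples / ≥ 25 subjects recommendation is reported as a flag, not
enforced.

### Passing–Bablok regression

All pairwise slopes (yⱼ − yᵢ)/(xⱼ − xᵢ), i < j; 0/0 pairs are omitted,
pairs with equal x but different y contribute signed infinite slopes, slopes
exactly −1 are omitted, and the offset K counts slopes below −1. The slope
is the K-shifted median; the intercept is median(y − b·x). Confidence
bounds use the rank-based normal approximation C = z·√(n(n−1)(2n+5)/18)
with index shift K. The estimator is exactly scale-equivariant only when
all pairwise slopes share a sign (otherwise K itself changes), and on data
whose spread is narrow relative to the noise the slope estimate is noisy
and mildly biased — the CI, not the point estimate, carries the inference.

### Cusum linearity test

Residuals about the fitted line score +√(L/l) above and −√(l/L) below
(l, L the counts above/below). Scores accumulate in order of position along
the fitted line, ranked by the fitted coordinate (monotone in x): an
ordering that used the observed y would destroy the symmetry of |cusum|
under mirroring the residuals. The statistic max|cusum| is compared with
Kolmogorov–Smirnov bounds 1.36·√(l+L+1) (5%) and 1.63·√(l+L+1) (1%), and
the result is reported as a band (p > 0.05 / ≤ 0.05 / ≤ 0.01), which is how
the test is conventionally tabulated. Note the sign-based scores cap the
statistic at √(lL); for symmetric curvature (e.g. a parabola, whose fitted
line crosses it twice) about n ≥ 30 points are needed before the 5% bound
is reachable in practice.

### Bland–Altman and companions

Differences d = EC_pla − C_pla: bias = mean(d), limits bias ± 1.96·SD(d)
(multiplier configurable), bias CI via Student t. The Spearman correlation
between d and the pairwise means flags concentration-dependent trends; its
p-value is exact (full permutation enumeration) for n ≤ 8 and the
t approximation with average ranks above that — exact enumeration beyond
8! permutations buys nothing for a trend screen. Lin's CCC uses population
(1/n) moments: 2·s_xy/(s_x² + s_y² + (x̄ − ȳ)²). The %diff rule divides by
the pairwise mean, counts |%diff| ≤ 20 as within (boundary-inclusive, with
a 1e−12 guard so exact boundaries are never lost to rounding), and passes
at a fraction ≥ 2/3. ISR reuses the engine with the repeat − original
orientation.

## Synthetic data

The generators encode the study conditions, not convenient test settings:

* **Calibration**: eight levels per drug on the fixed ladder
  LLOQ × {1, 2, 5, 10, 20, 30, 40, 50} (olaparib 140–7000, rucaparib
  100–5000, niraparib 60–3000 ng/mL), duplicate calibrators, noise either
  proportional (constant CV, default 5%) or additive (constant SD). Real
  LC-MS/MS calibration noise is proportional; the additive mode exists to
  exercise the homoscedastic branch of the selector.
* **Paired clinical cohorts**: per-drug design (n_subjects, n_samples) =
  olaparib (16, 52), niraparib (21, 43), rucaparib (4, 16); true CF =
  0.718 / 1.440 / 1.427. Plasma trough concentrations are lognormal
  (positive, right-skewed), moment-matched to the published mean ± SD
  exposures (649 ± 135, 1754 ± 805, 1290 with 76% CV ng/mL). C_DBS =
  CF·C_pla·(1 + N(0, cv)) with ratio CV 8% — the between-sample spread of
  the DBS/plasma ratio is not a published value; 8% was fixed once as a
  realistic assay-plus-physiology spread. Hct is uniform on [29, 45]% with
  no Hct-dependent bias by default (an Hct-bias hook exists for robustness
  studies).
* **ISR**: repeat = original·(1 + N(0, cv)).

Everything is driven by `numpy.random.default_rng(seed)` and is
bit-reproducible.

What the generators do *not* emulate: chromatographic signals and
integration, carryover kinetics, spot-spreading physics, Hct-dependent
recovery, within-subject pharmacokinetic structure (samples are exchangeable
within subject), or correlation between plasma level and Hct. Passing tests
therefore demonstrate the statistics are computed correctly under the
declared model, not that a real assay would validate.

## Problem sizes

The default test and acceptance runs use 200–500 seeded calibration studies
for selection rates, 25 study-sized cohorts per drug for the bridging
properties, 300 seeds × n = 200 for CF parameter recovery, and a single
n = 10⁵ sample for limits-of-agreement coverage — sizes at which every
Monte-Carlo margin in the assertions is several standard errors wide.

## Known limitations

* Between-run precision is pooled, not variance-decomposed.
* The cusum test reports a band, not a continuous p-value.
* Passing–Bablok CIs use the large-sample rank approximation; bootstrap CIs
  are not implemented.
* The conversion factor is a single scalar per drug; no covariate model
  (Hct, time since dose) is fitted, by design.
* S/N for the sensitivity check is an input, never computed from raw
  chromatograms.
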