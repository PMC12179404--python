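# Methods

This note documents the models implemented in `glymphkit`, the
assumptions behind them, the conventions chosen where the underlying
measurement procedures are underspecified, and what the synthetic-data
generator does and does not emulate.

## Scientific setting

The glymphatic system is the brain-wide perivascular fluid-exchange
pathway: CSF produced by the choroid plexus (ChP) enters the brain
along periarterial spaces, exchanges with interstitial fluid, and
drains along perivenous spaces toward the meningeal lymphatic vessels
(MLVs) and cervical lymph nodes. The package quantifies this
circulation from MRI-derived inputs on both the inflow side (ChP
volumetrics, global BOLD–CSF coupling) and the outflow side (DTI-ALPS,
DCE kinetics of the MLVs), quantifies white-matter-hyperintensity
(WMH) burden, and estimates the statistical structure linking them to
cognition (ANCOVA, correlation, robust regression, bootstrap
mediation, latent-variable SEM).

## DTI-ALPS

At the level of the lateral-ventricle body the deep medullary veins run
along x, perpendicular to projection fibers (z) and association fibers
(y). The index

```
ALPS = (Dx_proj + Dx_assoc) / (Dy_proj + Dz_assoc)
```

is computed from arithmetic means of the directional diffusivity maps
over one 3×3 in-plane voxel ROI per fiber system per hemisphere
(~5.4 mm per side at 1.8-mm voxels). ROI placement is operator input
(voxel coordinates); no atlas lookup is attempted, and the
slice-selection rule is deliberately left to the operator. A zero
denominator yields NaN with a flag rather than a silent drop. The
index is scale-invariant and strictly monotone in each mean, which the
tests exercise directly.

## Global BOLD–CSF coupling

Preprocessing: drop the first 10 volumes, convert each series to
percent change about its temporal mean, and apply a zero-phase
order-2 Butterworth band-pass. The band edges default to
0.01–0.1 Hz — the vasomotor band implicated in CSF pulsatility — and
are configurable. Correlation profiles are Pearson correlations
between CSF(t) and a reference at integer-TR lags within ±20 s,
computed on the overlapping support only (no padding, which would bias
large lags relative to small ones). The reference is either the BOLD
signal or its negative first derivative (central differences,
one-sided at the ends). Sign convention: positive lag means BOLD leads
CSF. The per-subject summary records the signed correlation of largest
magnitude (ties resolved toward lag 0), the +2 s and −6 s lag
strengths read directly off the grid (an off-grid request is an error,
never an interpolation), and the derivative coupling at lag 0. The
"strongest coupling" is defined as magnitude-maximal rather than
most-negative; the choice is configurable in analysis code because
observed peaks are typically negative either way.

## DCE kinetics

The time–intensity curve is sampled on 23 series of 16.78 s with
contrast injected at the end of series 2; the pre-injection samples
define the baseline S0 and enhancement e(t) = (S − S0)/S0. Contrast is
treated as arriving strictly after the injection sample, so the
baseline is uncontaminated by the plasma term.

Semiquantitative descriptors (vendor definitions are unpublished, so
the conventions here are explicit):

- **wash-in**: maximum forward-difference slope of e between injection
  and peak, in 1/s;
- **TTP**: time of peak enhancement minus injection time, in minutes;
- **AUC**: trapezoidal integral of e over a 120-s post-injection
  window divided by the window length (dimensionless). The window and
  normalisation land values in the ~0.05–0.15 range typical of MLV
  measurements.

Quantitative parameters come from the extended Tofts model
e(t) = v_p·C_a(t) + K_trans·(C_a ∗ exp(−k_ep t))(t) with a
bi-exponential population AIF C_a(t) = A1·e^(−m1 t) + A2·e^(−m2 t)
(defaults A1 = 5, m1 = 3/min, A2 = 1, m2 = 0.1/min, giving a
bolus-plus-tail whose Tofts response peaks 1–2 min post injection).
A measured MLV curve can serve as its own input function in vivo; a
simulator must replace it with a parametric form, hence the
bi-exponential. The convolution is evaluated analytically (sums of
exponential convolutions), exact on the coarse grid; an independent
fine-grid trapezoidal convolution agrees to <0.1% and serves as the
test oracle. Fitting is trust-region nonlinear least squares with
bounds K_trans, k_ep, v_p ≥ 0 and five seeded log-uniform starts;
V_e is always reported as K_trans/k_ep (zero, flagged, when
K_trans ≈ 0), so the identity V_e·k_ep = K_trans holds in every fit.
`fit_deviation` — never defined by vendors — is the RMS residual
normalised by peak |e|; the quality filter retains fits with deviation
strictly below 0.05.

## WMH morphometry

Lesions are 26-connected components of the binary mask (standard for
lesion masks; labels ordered by descending volume, ties by
lexicographic centroid). Per lesion: centroid as the voxel-centre mean
in mm; distance to the ventricular system as the minimum over lesion
voxels of the anisotropic Euclidean distance transform of the
ventricle mask — a surface-to-surface reading, which is what makes an
8-mm rule meaningful for extended lesions (a centroid mode is
available); principal axis lengths from the moment ellipsoid,
2·sqrt(5·λ) per covariance eigenvalue, the 3-D analogue of the 2-D
region-property convention, which recovers the full axes of a uniform
ellipsoid exactly. Classification: distance ≤ 8 mm (inclusive —
"within") is periventricular, > 8 mm deep; the threshold is
configurable. Class volumes are voxel counts × voxel volume, so
PWMH + DWMH = total holds exactly. Summed periventricular + deep
Fazekas scores (0–3 each) define severity groups: 0 → HC, 1–3 → mild,
4–6 → severe.

## ChP metrics

Volumes are voxel counts × voxel volume; ChP/LatVent and ChP/ICV are
exact quotients. Whether the lateral-ventricle mask should exclude ChP
voxels is unspecified upstream; subtraction is available but off by
default. Reliability uses ICC(A,1) — two-way model, single measure,
absolute agreement (McGraw & Wong) — computed from the two-way ANOVA
mean squares; no alternative ICC form is offered, preventing silent
mismatch. A constant panel has undefined agreement (NaN).

## Univariate statistics

One-way ANOVA with Tukey HSD post hoc; χ² without continuity
correction by default (three-group tables; 2×2 correction
configurable). ANCOVA is an OLS fit of outcome ~ group + covariates
(age, sex, education by default) with a group F-test and pairwise
adjusted-mean contrasts Bonferroni-corrected over the three pairwise
comparisons per outcome (the family definition is this package's
choice). Rank ANCOVA rank-transforms the outcome first and is
therefore invariant to monotone transforms. A second categorical main
effect (e.g. hypertension) can be added for two-way questions.
Cohen's d uses the pooled SD (df-weighted), consistent with the
conversion r = d/√(d² + 4). RANSAC robust regression first
residualizes the control variables out of predictors and outcome by
OLS, then runs consensus sampling (minimal samples of p + 1, up to
1000 trials, seeded) with an inlier threshold of 1.5 MAD-based robust
SDs of the OLS residuals, and refits the consensus set by least
squares.

## Mediation

Three OLS fits on standardized variables give the a, b, total and
direct paths; the indirect effect a·b gets a seeded percentile
bootstrap CI over row resamples (degenerate resamples skipped and
counted). In OLS algebra c_total = c' + a·b exactly, which is asserted
to machine precision. Partial mediation requires the indirect CI to
exclude zero while the direct effect stays nonzero at α. Missing data
are handled by listwise deletion throughout the inference back end.

## Structural equation model

The measurement model loads each of 11 indicators on exactly one of
four latents — Inflow (ChP/LatVent, coupling maximum), Outflow (ALPS
average, dorsal TTP/AUC/k_ep), WMH (PWMH, DWMH, Fazekas total),
Cognition (MMSE, MoCA) — with the first loading per latent fixed to 1
(marker-variable identification). Structural part: WMH regressed on
Inflow and Outflow (the Inflow path is toggleable), Cognition on WMH,
Inflow and Outflow freely correlated. Estimation minimises the ML
discrepancy F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p with an analytic
gradient under L-BFGS-B; χ² = (n−1)F, df = p(p+1)/2 − 26 = 40 for the
default model. Fit indices: CFI against the uncorrelated-indicators
baseline, RMSEA = √(max(χ²−df,0)/(df(n−1))), GFI from the ML
discrepancy of Σ̂ vs S; χ²/df is always derived, never stored.
Negative variance estimates (Heywood cases) are flagged, not
truncated. Indicator signs are not constrained: TTP loads negatively
by construction of the data (longer TTP = worse outflow), and the
expected orientation (negative Outflow→WMH, negative WMH→Cognition)
emerges from simulation rather than being hard-coded. Bootstrap path
CIs are percentile intervals over row-resampled refits warm-started at
the full-sample solution; the run aborts with diagnostics if fewer
than 95% of resamples converge (a lower bar can be passed explicitly
in calibration studies, where aborted replicates are simply skipped).

## Synthetic-data generator

Each generator is a pure function of (truth, seed).

- **Diffusivity fields** plant exact ROI means on a constant
  background, optionally with additive Gaussian noise clipped at zero.
- **BOLD/CSF series**: BOLD is band-limited (0.01–0.1 Hz) Gaussian
  noise; CSF is the lag-shifted negative discrete derivative of BOLD
  plus white noise scaled so the peak of the derivative-reference
  correlation profile equals the planted strength at the planted lag
  (that correlation is analytic in the generator's linear model; the
  plain BOLD-vs-CSF peak is then a derived quantity). An SNR can be
  given instead, implying the strength. Series are returned raw
  (positive means) so preprocessing is exercised.
- **DCE curves** are the analytic forward Tofts model on the
  acquisition grid with Gaussian or Rician noise on the enhancement
  scale.
- **Lesion scenes** are axis-aligned ellipsoids against a ventricle
  slab, chosen so centroids, axes and surface distances have analytic
  ground truth; the random-spec helper keeps every lesion at least a
  configurable margin (default 2 mm) clear of the 8-mm boundary so
  intended classes are unambiguous.
- **Cohort tables** draw the four latents from the structural truth
  (standardized metric, residual variances derived so all variances
  are 1), map them through the loadings, then rescale each indicator
  affinely to plausible observed units (means/SDs chosen from typical
  cohort values, e.g. ALPS ≈ 1.5 ± 0.2, ChP/LatVent ≈ 0.065 ± 0.032).
  Correlations are unaffected by the rescale, so the analytic implied
  covariance of the truth is also the implied correlation of the
  output — the oracle used by the convergence test at n = 10⁵.
  Default truth: loadings 0.646 (ChP/LatVent) and 0.712 (ALPS) on
  their latents, structural paths −0.30 (Inflow→WMH), −0.572
  (Outflow→WMH), −0.705 (WMH→Cognition), Inflow–Outflow correlation
  0.40; the remaining loadings are moderate-to-strong values oriented
  by the physiology (e.g. TTP negative, coupling maximum negative
  because stronger coupling is a more negative correlation).
  Demographics (age, sex, education) are generated alongside and can
  confound indicators linearly (default coefficients 0) so covariate
  adjustment can be tested against known truth.

What the generator does **not** emulate: MR physics (no k-space,
bias fields or motion), the heavy right skew of real WMH volume
distributions (indicators are Gaussian; the cohort-table conversion
clips volumes at zero and discretizes Fazekas scores to integers,
which the SEM oracle path deliberately bypasses by keeping continuous
indicators), non-Gaussian measurement noise (all noise defaults are
Gaussian and documented as assumptions), and real spatial anatomy of
ventricles or fiber tracts. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to real-data artefacts.

## Numerical choices and problem sizes

Tolerances: Tofts least-squares runs with tight (1e-14) stopping
tolerances to resolve the flat K_trans→0 ridge; SEM optimisation stops
at gradient norm 1e-6 (1e-5 for warm-started bootstrap refits). Ties
in the coupling maximum resolve toward lag 0. Degenerate inputs (flat
DCE curves, constant rating panels, zero denominators) are flagged or
NaN rather than silently dropped.

The recovery and calibration studies in the test suite and acceptance
script run at sizes chosen to make Monte-Carlo noise small relative to
the tolerance being checked while keeping the whole suite quick on one
CPU: 200 noisy ALPS fields, a 27-point noiseless Tofts grid plus
60–100 noisy fits, 200–300 coupling subjects, 100–200 planted lesions,
300–500 mediation replicates with 300–400 bootstrap resamples each,
SEM bias at n = 20000 over a handful of replicates, and SEM bootstrap
coverage at n = 117 over 50–100 replicates of 150–200 resamples.

## Known limitations

- The SEM estimator handles the single-group, continuous-indicator ML
  case only (no WLSMV for categorical indicators, no multi-group or
  longitudinal models).
- ALPS ROI placement and the coupling CSF ROI are inputs; nothing
  here reproduces the image-space delineation steps.
- DCE signal is treated as proportional to concentration (no
  T1-mapping), and the AIF is a population form, so fitted K_trans
  values are comparable within this pipeline rather than absolutely
  calibrated.
- Percentile bootstrap CIs (chosen to match the simple interval form
  used in this literature) undercover slightly at n ≈ 117; BCa is a
  possible extension.
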