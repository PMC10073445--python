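# Methods

This note documents the models behind `qspect`, the defaults and why they
were chosen, and what the simulators do and do not emulate.

## Phantom simulator

The simulator emulates *post-reconstruction* SPECT count maps, not the
acquisition chain: no projections, attenuation, scatter or iterative
reconstruction are modelled. A phantom insert (sphere or axis-aligned
cylinder) of known volume and activity concentration is rasterized on a
voxel grid by **voxel-center inclusion** — a voxel belongs to the insert if
its center lies inside the geometry. Partial-volume effects are supplied by
the blur step rather than by sub-voxel weighting, which keeps the
rasterization brute-force checkable.

The forward model maps concentration to count density through the
calibration line `counts/cc = a·C + b` in the hot region *and* in the
background; with zero background concentration the intercept `b` acts as a
count-density floor, mirroring the nonzero background plateau of a real
reconstruction and making the intercept meaningful in simulation.

Degradation:

* **System PSF** — isotropic Gaussian convolution, σ = FWHM/2.3548 per
  axis in mm, reflective boundary padding (total counts conserved to
  <0.1%).
* **Counting noise** — an independent Poisson draw per voxel with the
  blurred value as its mean; deterministic given the seed. Phantom series
  use per-phantom child seeds spawned from the series seed.

Defaults: 128³ grid at 3.3 mm isotropic (the reconstruction-space analogue
of a 128×128 clinical matrix at zoom 1.5) and FWHM 10 mm, a typical
reconstructed resolution for this camera class. Neither is a measured
property of any particular scanner; both are configurable. Default
concentrations span 28.5–151.33 kBq/mL (0.77–4.09 μCi/mL) and default
insert volumes cover the three standardization ranges with 3–4 spheres
each (6–30, 500–1500, 2400–3200 mL).

## Segmentation and threshold standardization

Segmentation thresholds at a fixed percentage of the maximum voxel value
**within the analysis box** (not the global image), so liver and spleen can
be delineated independently on one scan. The supra-threshold set is reduced
to its largest 6-connected (face-connectivity) component; slice-wise
contouring on coronal slices, as done on clinical workstations, is
subsumed by this 3-D operation — a documented deviation. The estimated
volume is exactly the mask cardinality times the voxel volume; no surface
interpolation.

The standardization sweep evaluates thresholds 19–52% in 1% steps. Per
volume range, the selected threshold minimizes the **summed absolute volume
error** across that range's phantoms (the criterion "best volume
estimation" is otherwise underspecified); ties break toward the lower
threshold. The report includes the Pearson correlation between estimated
and true volumes at the selected threshold. Range membership uses a 1e-9
relative tolerance so a sphere constructed for exactly 6.0 mL is not
excluded by floating-point rounding.

Degenerate inputs: an all-zero analysis region raises a "no signal" error;
a threshold above every value (possible only with pathological input, since
the comparison is ≥) returns an explicitly flagged empty result.

## Calibration

Ordinary least squares of mean count density on concentration, with r and
two-sided p recorded; at least two distinct concentrations are required.
Canonical units are μCi/mL for concentration, mL (= cc) for volume, raw
counts for voxel values; activity unit conversions use the exact definition
1 μCi = 37 kBq. Inversion maps counts below the intercept to zero
concentration (concentration is physically non-negative) and counts the
clamped values on the model.

An important self-consistency property: a calibration fitted from
*blurred* phantom data at the working threshold carries a slope lower than
the noiseless forward line, because the PSF moves counts outside the
iso-contour. Quantifying organs against this measured line cancels the
same spill to first order — recovering a known dose fraction to ~1%
relative, versus ~7% if the noiseless forward coefficients are used
directly. This is the methodological point of phantom standardization, and
the end-to-end tests exercise the full loop.

## Quantification

Per masked voxel: counts → counts/cc (divide by voxel volume) →
concentration via the inverted calibration → μCi (multiply by voxel
volume); summed over the mask. Percent uptake references the injected
activity at scan time: decay correction `A(t) = A₀·2^(−t/T½)` with
T½ = 360.4 min (⁹⁹ᵐTc) is **on by default** — standard quantitative
practice — and can be disabled; the choice is recorded on the result.
Residual syringe activity is assumed zero. `%ID/mL` is computed as
`%uptake / volume`, so the identity `%ID/mL × volume = %uptake` holds to
machine precision by construction. Uptake above 100% of the injected dose
raises an error, since it can only arise from a calibration or unit fault.

## ICG kinetics

Default estimation is a log-linear OLS fit of ln C(t) over all five
samples (0, 5, 10, 15, 20 min), which uses every draw and is robust to
noise in any single one; the bedside ratio `R15 = 100·C(15)/C(0)` is
available for parity. The t = 0 sample is included by default (it is
collected by the protocol); mixing-phase exclusion is a flag. Derived
quantities: `R15 = 100·e^(−15k)`, `PDR = 100·k` in %/min.

Clinical classification uses strict inequalities: R15 < 10.0% is normal
retention, PDR > 18.0 is normal clearance; boundary values are abnormal.
The reference threshold for PDR is sometimes quoted in mL/min, but typical
patient PDR values (~6) are consistent with %/min; the package implements
%/min and applies the 18.0 threshold numerically.

## Statistics

* **Pearson** — r, t-transform p (n−2 df), Fisher-z 95% CI.
* **ROC / Youden** — AUC by the rank (Mann–Whitney) formulation with half
  credit for ties, which equals the trapezoidal area under the empirical
  ROC. The direction is auto-detected so AUC ≥ 0.5 (markers that fall with
  severity get direction "lower") and recorded. Cutoff candidates are
  midpoints between adjacent distinct scores; ties in J break toward
  higher sensitivity, then the lower cutoff value. A case is positive when
  strictly beyond the cutoff. PPV/NPV/accuracy come from the confusion
  matrix at the selected cutoff.
* **Survival** — Kaplan–Meier and (two-group or k-sample) log-rank via
  lifelines; Cox proportional hazards via lifelines' partial-likelihood
  Newton solver with Breslow tie handling, Wald CIs and p-values.
  Degenerate designs (constant covariates, <2 events) and non-convergence
  raise immediately.
* **Group tests** — Welch t (unpaired) / paired t, with Mann–Whitney U /
  Wilcoxon signed-rank as rank-based alternatives; all two-sided.
* **Strata report** — per-CTP-class and per-MELD-stratum means ± SD,
  one-way ANOVA across CTP classes, and ROC analyses of %QLU, liver volume
  and ICG-R15 for each severity dichotomy, with the more severe group as
  the positive class.

A cohort-level flag controls outcome recoding: by default transplant and
loss to follow-up count as events (12-month transplant-free survival);
standard censoring is available because the composite rule is unusual and
must remain explicit.

## Cohort generator

The default mode draws one latent severity axis s ~ N(0,1) per patient and
makes every marker affine in s plus independent Gaussian noise:
X = μ + σ(λs + √(1−λ²)ε), so corr(X, Y) = λ_X λ_Y. Loadings are derived
from target correlations with %QLU (λ_%QLU = −0.88): CTP −0.728,
MELD −0.743, ICG-R15 −0.720, PDR +0.754, with LV/%QSU/SV tied through
their CTP correlations. CTP and MELD are rounded and clipped to their
clinical ranges (CTP 5–15, classes A 5–6 / B 7–9 / C 10–15; MELD 6–40);
rounding attenuates correlations by well under the reporting tolerance.
%QLU and %QSU clip to (0, 100), volumes and rates to positive values.
%ID/mL is derived per record as uptake/volume, never simulated
independently. A single-factor model cannot hit an arbitrary correlation
matrix; loadings outside [−1, 1] raise an infeasibility error.

Because conditional stratum means of real severity classes are not
Gaussian slices of one factor, a **stratified mode** draws patients
stratum-by-stratum with per-stratum means/SDs; the `table1_strata` preset
uses it with published-range CTP-class weights (10/56/43 of 109) and
per-class marker statistics. In that mode the survival severity proxy is
the standardized CTP score.

Survival is exponential with log-hazard linear in s and treatment arm,
administratively censored at 12 months. The default baseline rate
(0.0542/month) is calibrated by Gauss–Hermite inversion so untreated
marginal 12-month survival is 51%; the default treatment log-HR is
ln(0.414). The `fig2_survival` preset instead solves *both* the baseline
rate and the arm hazard multiplier so the two arms' marginal 12-month
survivals are exactly 51% and 75%. Follow-up markers shift by arm-specific
deltas (e.g. %QLU +5.1 under G-CSF, −1.1 under standard therapy) plus a
within-patient change noise; the change SD of 6.0 %QLU points was chosen
as typical test–retest variability of quantitative SPECT (source tables
report only marginal SDs, not paired-difference SDs). Event subjects get a
categorical outcome label (death/transplant/lost to follow-up, default
85/10/5%) so both recodings can be exercised.

What the generator does **not** emulate: mechanistic disease progression,
non-Gaussian marginals and skewness of real biomarkers, informative
censoring, per-cycle treatment pharmacodynamics, and measurement error
correlated across visits. Passing tests therefore demonstrate the
correctness of the estimators under the stated generative model, not
clinical performance on real patients.

## Problem sizes and numerical choices

Simulation-based checks use sizes at which Monte-Carlo error is well below
the tolerances being asserted: phantom standardization on 3–4 inserts per
range at the default 128³ grid; cohort fidelity at n = 10,000; hazard-ratio
recovery over 200 replicates of n = 1,000 with exponential event times;
ICG noise recovery over 1,000 replicates. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`, with
independent child seeds spawned via `SeedSequence` where a series needs
per-item streams; every pipeline artifact embeds the configuration hash,
seed and package version, and reruns are bit-identical.

Known limitations: voxel-center rasterization biases small-insert volumes
at coarse spacing (the 6-mL sphere spans ~170 voxels at 3.3 mm); a single
threshold per volume range cannot be optimal for every insert in the
range, which dominates the small-range error budget; the Gaussian PSF is
stationary and isotropic, unlike a real collimator's distance-dependent
response; and the cohort generator's single severity axis understates the
dimensionality of real clinical covariance.
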