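# qspect

Quantitative ⁹⁹ᵐTc-sulfur-colloid liver SPECT/CT analysis: phantom-based
standardization, fixed-threshold iso-contour volumetry, counts-to-
concentration calibration, per-organ uptake quantification, the indocyanine
green (ICG) reference test, and the prognostic statistics that connect these
markers to disease severity and survival in cirrhosis.

## The problem

Functional liver reserve drives prognosis in decompensated cirrhosis, but
the clinical severity scores (Child–Turcotte–Pugh, MELD) are indirect and
the reference ICG clearance test is cumbersome. ⁹⁹ᵐTc-sulfur colloid is
phagocytosed by hepatic Kupffer cells, so the fraction of an injected dose
that localizes in the liver — measurable on a SPECT/CT count map — is a
direct imaging proxy for functional liver mass. Turning a reconstructed
count map into physical quantities requires two scanner-specific
standardizations, both built here:

1. **Volumetry** — an organ is segmented as the largest 6-connected
   component of voxels at or above a fixed percentage of the regional
   maximum. The optimal percentage is found by sweeping thresholds
   (19–52%) against phantoms of known volume, separately per volume range
   (6–30, 500–1500, 2400–3200 mL).
2. **Calibration** — mean count density (counts/cc) in phantom inserts of
   known activity concentration C (μCi/cc) is regressed as
   `counts/cc = a·C + b`; inverting this line converts patient voxels to
   concentrations.

From a segmentation, a calibration and the injected dose A₀ the package
computes the organ volume (LV/SV), the percent quantitative liver/spleen
uptake

```
%QLU = 100 · Σ_mask [ (counts/cc − b) / a ] · v_cc / A(t_scan),
```

(with `A(t) = A₀·2^(−t/T½)`, T½ = 360.4 min for ⁹⁹ᵐTc), and
`%ID/mL = %QLU / LV`. The ICG module fits the mono-exponential
`C(t) = C₀ e^(−kt)` to timed blood samples, giving the retention
`R15 = 100·e^(−15k)` and the plasma disappearance rate `PDR = 100·k`.
The statistics layer provides Pearson correlation with Fisher-z intervals,
ROC analysis with Youden-optimal cutoffs, Kaplan–Meier/log-rank and Cox
proportional-hazards survival analysis, and group comparisons.

No scanner or patient data ship with the package: a digital phantom
simulator (calibration forward model + Gaussian system PSF + Poisson noise)
and a synthetic cirrhosis cohort generator (single latent severity axis
with configurable correlation targets, two treatment arms, exponential
survival) provide fully reproducible inputs for every analysis.

## Worked example

Standardize a calibration from three simulated 1000-mL phantoms, then
quantify a simulated 1200-mL liver that holds 30% of a 166-MBq dose:

```python
from qspect import *
from qspect.calibration import CalibrationPoint, fit_calibration, convert_activity
from qspect.phantom import PhantomSpec
from qspect.segmentation import iso_contour_segment, roi_box_for
from qspect.quantification import DoseRecord, organ_quant, decay_correct

grid = default_grid()
points = []
for i, conc in enumerate((28.5/37, 74/37, 151.33/37)):   # kBq/mL -> uCi/mL
    spec = PhantomSpec(sphere_for_volume(1000.0, grid.center_mm), concentration=conc)
    vol = add_poisson_noise(apply_system_blur(rasterize_phantom(spec, grid), 10.0), 10 + i)
    seg = iso_contour_segment(vol, 38.0, roi_box_for(spec, grid))
    points.append(CalibrationPoint(seg.mean_counts_per_voxel / grid.voxel_volume_mL, conc))
model = fit_calibration(points, threshold_pct=38.0)

dose = DoseRecord(166.0, injection_to_scan_min=30.0)
activity = convert_activity(decay_correct(dose), "MBq", "uCi")
spec = PhantomSpec(sphere_for_volume(1200.0, grid.center_mm),
                   concentration=0.30 * activity / 1200.0)
vol = add_poisson_noise(apply_system_blur(rasterize_phantom(spec, grid), 10.0), 99)
seg = iso_contour_segment(vol, 38.0, roi_box_for(spec, grid))
q = organ_quant(vol, seg, model, dose)
print(f"liver: volume={q.volume_mL:.0f} mL, %QLU={q.pct_uptake:.2f}%, "
      f"%ID/mL={q.pct_id_per_mL:.4f}")
```

This prints

```
liver: volume=1203 mL, %QLU=30.30%, %ID/mL=0.0252
```

— the volume is recovered to 0.3% and the known 30% dose fraction to 1%
relative. Note the fitted slope (≈6158 counts/cc per μCi/cc here) is lower
than the noiseless forward line: the PSF pushes counts outside the
iso-contour, and the calibration absorbs that loss — which is exactly why
quantification against the *measured* line recovers the truth.

The same workflow is available from the shell:

```sh
qspect cohort --preset fig2_survival --n 1000 --seed 1 --out cohort.csv
qspect stats survival --cohort cohort.csv
```

```
log-rank chi2=66.354 p=3.77e-16
  12-month survival [SMT]: 50.5%
  12-month survival [GCSF]: 75.0%
  HR[gcsf]=0.431 (0.348-0.534) p=1.1e-14
  HR[meld]=1.137 (1.096-1.180) p=1.36e-11
```

`qspect run --seed 7 --out bundle/` chains everything (standardize →
calibrate → cohort → quant → stats) into a provenance-stamped, bit-
reproducible output bundle.

## Layout

| module | contents |
| --- | --- |
| `qspect.phantom` | grids, geometries, PSF blur, Poisson noise, phantom series |
| `qspect.segmentation` | iso-contour segmentation, threshold sweep, per-range standardization |
| `qspect.calibration` | counts/cc ↔ μCi/cc regression, unit conversions |
| `qspect.quantification` | decay correction, %QLU/%QSU/%ID/mL, visit deltas |
| `qspect.icg` | dilution curve, clearance kinetics, clinical classification |
| `qspect.stats` | Pearson, ROC/Youden, KM/log-rank, Cox, group tests, strata report |
| `qspect.cohort` | synthetic cohort generator and scenario presets |
| `qspect.io` / `qspect.pipeline` / `qspect.cli` | NIfTI I/O, run config, pipeline, CLI |

See `docs/methods.md` for the models, defaults and their rationale.
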