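# surrocor

**Skin-surface respiratory surrogates for lower-lung-lobe motion, measured
on 4DCT contour sets.**

Optical surface guidance (SGRT) tracks a region of interest (ROI) on a
patient's skin as a surrogate for internal tumour motion. Not every patch
of skin is an equally good surrogate: its respiratory excursion must be
large compared with the gating window, and it must correlate strongly with
the target's motion. `surrocor` quantifies both over the whole torso from
routine 10-phase 4DCT skin contours:

- **Beam-length motion maps.** Per axial slice, the skin contour centroid
  is found (area-weighted shoelace centroid); a central craniocaudal axis
  is fitted through the centroids by least squares; 180 radial beams at 1°
  intervals (θ = 0°, …, 179°; 0° = patient right, 90° = anterior) are cast
  from the fixed axis point to the outermost skin crossing. For beam
  lengths ℓ_p over phases p = 0..9, the respiratory magnitude is
  max_p ℓ_p − min_p ℓ_p (mm) and the skin-to-tracking-structure
  correlation is the sample Pearson R between ℓ_p and the craniocaudal
  coordinate z_TS(p) of a tracking structure (TS) in the lower lung.
- **Nine-ROI summaries.** Beams are partitioned into rows A/B/C by the
  xipho-sternal line and subcostal plane and columns right/central/left by
  the angular bands [30°, 75°), [75°, 105°), [105°, 150°).
- **L4 adiposity.** On a single axial slice at L4, adipose tissue is the
  HU range [−150, −20]; a supplied inner-abdominal-wall polygon splits it
  into subcutaneous (SAT) and visceral (VAT) tissue, reported as % of the
  body cross-section.
- **Cohort statistics.** Friedman χ² (tie-corrected) with Dunn–Bonferroni
  post hoc across ROIs; Mann–Whitney U (min-U convention, continuity- and
  tie-corrected z, effect size r = |z|/√N) for sex differences; Spearman's
  ρ for adiposity/BMI/height covariates; pooled t-test with Cohen's d for
  the TS magnitudes.
- **Synthetic breathing phantom.** A torso whose radius breathes with a
  raised-cosine waveform under a configurable amplitude field M(θ, z),
  phase-lag field φ(θ, z) and noise, plus an L4 slice of nested ellipses —
  all with closed-form ground truth, standing in for patient data.

## Worked example

```python
import numpy as np
from surrocor.phantom import PhantomConfig, generate_torso, generate_ts
from surrocor.geometry import polygon_centroid, fit_axis, build_beam_length_field
from surrocor.maps import pearson_map, magnitude_map

cfg = PhantomConfig()                      # 100 slices, 5 mm anterior lobe
phase_sets, truth = generate_torso(cfg)
cents = [(polygon_centroid(s), s.z) for s in phase_sets[0].slices]
field = build_beam_length_field(phase_sets, fit_axis(cents))
cmap = pearson_map(field, generate_ts(cfg))
mmap = magnitude_map(field)
print("max |R - 1| :", np.max(np.abs(cmap.r - 1.0)))
print("magnitude at (slice 50, 90 deg):", mmap.m[50, 90], "mm")
```

prints

```
max |R - 1| : 2.220446049250313e-16
magnitude at (slice 50, 90 deg): 5.000000000000682 mm
```

i.e. on a lag-free noise-free phantom every beam is perfectly correlated
with the TS and the anterior beam recovers the 5 mm amplitude exactly.

The full synthetic study lives under `analysis/`:

```bash
python analysis/01_phantom_validation.py   # pipeline vs analytic truth + maps PNGs
python analysis/02_cohort_tables.py        # 57-patient cohort -> results/cohort.csv
python analysis/03_cohort_stats.py         # Friedman / sex / Spearman reports
```

On the default seed the cohort reports show the constructed study
conditions: abdominal-row magnitudes larger for men (e.g. region B median
4.03 vs 3.19 mm, p < 0.001, r = 0.46), no sex difference in the TS
magnitudes, and negative, significant Spearman ρ between BMI and the
rib-cage (A-row) magnitudes and correlations.

A CLI mirrors the stages: `surrocor phantom|maps|roi|adipose|stats|run`
(see `surrocor --help`).

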