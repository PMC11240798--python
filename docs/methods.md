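# Methods

## Geometry of the beam-length surrogate

Each axial skin contour is a closed simple polygon in mm, normalised to
counter-clockwise orientation on load. The per-slice centroid is the
area-weighted (shoelace) centroid, which is insensitive to uneven vertex
density; the central craniocaudal axis is two independent ordinary
least-squares lines, x(z) and y(z), fitted through the slice centroids.
The axis is fitted **on phase 0 only** and held fixed across phases, so
beam-length variation measures skin motion rather than phase-to-phase
centroid drift.

The beam fan is θ = 0°, 1°, …, 179° — a half-open [0°, 180°) sampling of
180 beams, one per degree. Beam direction is d(θ) = (−cos θ, sin θ) with
x increasing to the patient's left and y anterior, so θ = 0° points to the
patient's right lateral side and θ = 90° anterior. Casting solves the
ray–edge intersection o + t·d = p₁ + s·e in closed form for every polygon
edge and keeps the **largest** positive t: when skin folds make a ray
cross the contour several times, the outermost crossing is the surface an
optical camera sees. A ray with no forward crossing (origin outside a
malformed contour) yields a flagged-invalid entry, never a silent zero.
The kernel is validated against a shapely segment-intersection oracle to
1e−6 mm on random star-shaped polygons.

## Maps

Per beam, over the P = 10 phases:

- magnitude = max_p ℓ_p − min_p ℓ_p (mm);
- correlation = sample Pearson R between ℓ_p and the TS craniocaudal
  coordinate z_TS(p).

A beam whose length series is exactly constant is flagged *undefined*
rather than assigned R = 0 — a motionless beam carries no correlation
information. The constant-series test uses the exact value span (max =
min), not a variance threshold, so floating-point residue from demeaning
cannot leak a constant beam through. The TS coordinate is used signed (a
coordinate, not a displacement). Undefined and invalid beams carry reason
codes and are excluded (and counted) downstream.

## Nine-ROI partition

Columns: right [30°, 75°), central [75°, 105°), left [105°, 150°) —
half-open, so each boundary beam belongs to exactly one region; beams in
[0°, 30°) and [150°, 180°) are left unassigned (lateral skin is not part
of the nine-ROI scheme). Rows: A above the xipho-sternal line, B between
xipho-sternal line and subcostal plane, C from the subcostal plane to an
inferior limit near L4. Landmark heights are per-patient inputs located
anatomically on the CT; automatic landmark detection is out of scope. Both
mean (default) and median aggregators are provided; reports record which
was used.

## L4 adiposity

Adipose tissue is the inclusive HU interval [−150, −20] inside the body
mask. A supplied inner-abdominal-wall polygon (manual delineation in
practice) splits it: VAT = adipose pixels whose centres fall inside the
wall, SAT = the rest; the split is an exact partition by construction.
Areas are pixel counts × pixel area. Percentages are relative to the body
cross-section by default — the denominator that makes fractions comparable
across scanners — with the full image frame available as an alternative
reference.

## Cohort statistics

Conventions follow the SPSS-style reporting of the clinical literature:

- **Friedman**: within-patient mid-ranks, tie-corrected χ² with df = k−1,
  upper-tail χ² p. Verified against an exhaustive brute-force rank oracle
  on all small rank-order tables and against scipy.
- **Dunn–Bonferroni**: z = (R̄ᵢ − R̄ⱼ)/√(k(k+1)/6n) on the Friedman mean
  ranks; two-sided normal p; Bonferroni factor k(k−1)/2.
- **Mann–Whitney**: U = min(U₁, U₂); z from the normal approximation with
  tie correction and 0.5 continuity correction toward the mean (hence
  z ≤ 0 as printed in clinical tables); effect size r = |z|/√N. These
  conventions reproduce every printed (z, r) pair they are checked
  against. If all pooled values are tied, z = 0 and p = 1. The empirical
  type-I error at the study's group sizes (26/31) is calibrated at the
  nominal 5% level by simulation.
- **Spearman, pooled t-test**: delegated to scipy behind the module
  surface; Cohen's d = |mean difference|/pooled SD, with the conversion
  d = |t|·√(1/n₁ + 1/n₂) exposed separately (an algebraic identity for
  the pooled test, verified to 1e−12).
- Two-sided p everywhere.

## The breathing-torso phantom

Temporal model: phase 0 is the fully expanded end-inspiration envelope;
w(f) = (1 − cos 2πf)/2 is the exhale depth at cycle fraction f (a standard
surrogate waveform; for even P the binned values reach 0 and 1 exactly).
The skin radius at vertex angle θ, slice z, phase p is

    ρ(θ, z, p) = ρ0(θ, z) − M(θ, z) · w((p/P − φ(θ, z)) mod 1) + ε,

with amplitude field M ≥ 0 (mm), lag field φ (cycle fraction), and
optional Gaussian vertex noise ε. The TS trajectory is
z_TS(p) = base − amp · w(p/P). Skin length and TS coordinate therefore
**co-vary positively** for a lag-free torso — the sign convention chosen
to match the strongly positive skin-to-TS correlations observed on real
free-breathing 4DCT — and a uniform lag of half a cycle flips R to −1
exactly. Ground truth is computed on the same length-P discrete series as
the pipeline measures (peak-to-peak magnitude; exact Pearson R of the
noise-free series), so tests compare like with like; a zero-amplitude beam
has undefined truth correlation.

Defaults are the study conditions: 10 phases; 100 axial slices at 1 mm;
an elliptical 150 × 100 mm torso; contour vertices every 0.5°, so the
1°-spaced beams pass exactly through vertices and the polygon-chord
sampling error is far below 1% (measured < 0.2% worst-case); a 5 mm
anterior amplitude lobe; an 8 mm TS excursion. Noise-free contours are
star-shaped about the slice centre, so every beam has a unique crossing.
The L4 phantom nests skin/SAT/muscle-wall ellipses with visceral fat as
seeded non-overlapping discs; compartment areas follow from ellipse and
disc formulas, and rasterisation at 1 mm pixels recovers them within 2%.

### Synthetic cohort

`cohort.synthesize_cohort` draws reproducible patients under the study
conditions: 26/31 male/female split at n = 57; row amplitudes A ≈ 1 mm,
B ≈ 3–4 mm, C ≈ 5–6 mm with men larger in B/C; BMI ~ N(27.5, 4.5²)
damping the A-row amplitude (5%/unit) and adding upper-thorax phase lag
(0.006 cycle/unit), which produces the negative BMI/VAT% associations
with rib-cage magnitude and correlation; TS excursion ≈ 8 mm for both
sexes; L4 ring thickness and blob count grow with BMI. Cohort-scale runs
use 37 slices at 5 mm and the analytic beam-length field (exact for the
star-shaped phantom) — problem sizes chosen so the whole study runs in
seconds; the contour-casting path is exercised by the validation analysis
and the pipeline tests.

**What the phantom does not emulate**: deformable anatomy and sliding
tissue interfaces, irregular or drifting breathing patterns, CT
reconstruction/binning artefacts, non-elliptical body habitus, and any
anterior–posterior TS motion (the craniocaudal component is the dominant
one for lower-lobe structures and the only one modelled). Passing phantom
tests therefore demonstrates correctness of the measurement pipeline and
statistics, not clinical performance on patient data.

## Numerical choices and degenerate inputs

- Ray–edge hits accept s ∈ [0, 1] with 1e−9 slack so rays through shared
  vertices are never dropped; duplicate hits are harmless under the max-t
  rule.
- Zero-area polygons, non-nested L4 rings, all-tied Friedman tables,
  zero pooled variance, empty groups, missing cohort columns and
  mismatched phase grids all raise with the offending item named; no
  imputation anywhere.
- Pearson/Spearman values are clipped to [−1, 1] against rounding
  overshoot; undefined entries are NaN plus an explicit flag.
- Determinism: every stochastic step (vertex noise, blob placement,
  cohort draws) flows from a single seeded generator; identical
  configuration and seed give bit-identical outputs.

## Known limitations

- The inner abdominal wall must be supplied; no automatic segmentation.
- Beam origins come from the phase-0 axis; a patient whose centroid path
  is strongly curved is still measured from the straight least-squares
  axis, as in the original measurement design.
- The Mann–Whitney p uses the normal approximation (appropriate at the
  cohort's group sizes), not the exact permutation distribution.
- DICOM-RT import is an extension point; the supported interchange format
  is the documented contour JSON.
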