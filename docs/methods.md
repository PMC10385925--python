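# Methods

This note records the measurement conventions, statistical procedures,
simulator models and numerical choices implemented in `adrenoct`, and what
the synthetic validation does and does not demonstrate about clinical data.

## Grids, masks and orientation

A CT study is a regular voxel grid of Hounsfield units with millimetre
spacing. Geometry is voxel-centre based: voxel `i` along an axis with
spacing `s` spans `[i·s − s/2, i·s + s/2)` mm. Each array axis carries an
anatomical label — craniocaudal (CC), dorsoventral (DV) or mediolateral
(ML) — because heights and widths are defined anatomically. Labels are
recovered from NIfTI affine orientation codes (both polarities of an
anatomical axis map to the same label; extents and volumes do not depend on
polarity) or must be given explicitly; they are never guessed from image
content, since scan posture (dorsal vs ventral recumbency) is not
recoverable from the voxel data. DICOM series are read with the rescale
slope/intercept applied; a missing pixel-spacing attribute is a hard error,
not a default.

In-plane resampling to a common pixel size (clinically 0.26–0.97 mm
interpolated to 0.2 mm) uses trilinear interpolation for intensities and
trilinear-then-threshold-0.5 for masks. Sample positions are cell-centred:
the voxel extent is tiled with cells of the target size and their centres
are interpolated. This makes resampling at the current spacing the exact
identity and — unlike edge-aligned sampling — avoids placing samples
exactly on the 0.5 iso-contour at integer refinement ratios, where the tie
direction would bias thresholded volumes by a surface layer (several
percent for a 5 mm sphere at a 2:1 ratio; with cell-centred sampling the
change is below 1%, as exercised in the tests). The through-plane (slice)
spacing is preserved.

NIfTI stores spacings as 32-bit floats; round-trips are bit-exact for
representable spacings and otherwise exact to metadata precision (~1e-7
relative). Mask/grid compatibility tolerates 1e-4 mm.

## Volumetry and attenuation

The slice addition technique multiplies the segmented voxel count per slice
by the single-voxel volume and sums over slices. Since counts are integers
this equals the total count times the voxel volume exactly, and is
independent of the slice axis; the per-slice decomposition is retained for
reporting and asserted to sum identically. No partial-volume correction is
applied — the voxel-counting model *is* the measurement.

Attenuation is the mean and population SD of HU over exactly the masked
voxels, boundary voxels included; partial-volume blending at the organ
border is part of the measurement by design. The `homogeneous` flag
(default SD ≤ 25 HU) is an operational stand-in for the qualitative
"homogeneous contrast distribution" inclusion criterion; the underlying
criterion is not quantified anywhere, so the threshold is configurable and
results depending on it should be read accordingly. Vessel exclusion
(phrenicoabdominal vein/artery) is the segmenter's responsibility; masks
are taken as given.

Surfaces are extracted by marching cubes at iso-level 0.5 on the
zero-padded mask, giving a watertight genus-0 mesh for well-formed glands.
Enclosed volume tracks the SAT volume within a few percent for masks of
≥ 1000 voxels; for very small structures marching cubes systematically
under-encloses (the iso-surface cuts between voxel centres), so mesh
volume is a rendering by-product, not the volumetric measurement.

## Caliper protocol

Workstation practice fixes the maximal craniocaudal length in a sagittal
view with a 3-D measuring tool, then tilts the transverse plane orthogonal
to that line so every gland is sectioned in a standardised pose. Here the
length is formalised as the 3-D farthest-point distance between occupied
voxel centres — the rotation-invariant version of that measurement,
computed exactly via the convex hull. Whether the original tool measured a
free 3-D chord or a sagittal-projected one cannot be determined from the
protocol description; the farthest-pair definition is the documented
choice. Voxel-centre chords underestimate surface-to-surface lengths by up
to one voxel per end.

The gland frame takes the length direction as its first axis; the
transverse DV/ML directions are the projections of the anatomical DV/ML
axes onto the orthogonal plane, renormalised (minimal-rotation convention),
so H and W keep their anatomical meaning in the adjusted plane. The mask is
resampled into this frame at isotropic spacing (default: the finest
original spacing) with trilinear interpolation and a 0.5 threshold; volume
is preserved to ~1% for well-resolved glands.

Measurement stations along the length axis are localised from the
cross-sectional area profile: the cranial pole is the maximal-area section
within the cranial half of the occupied length (ties toward the cranial
end), the caudal pole likewise in the caudal half (ties toward the caudal
end), and the isthmus is the minimal-area section strictly between the
poles (ties toward the midpoint). The half-length windows are configurable.
This is an operationalisation — the clinical protocol says only that poles
and isthmus were measured — and it degenerates deliberately: a sphere has
its maximal section in both windows, leaving no station strictly between
the coinciding poles, which is reported as an error rather than silently
resolved. At least five occupied stations are required. By convention the
low-index end of the length axis is called cranial; on real data the
caller's axis labels determine which anatomical end that is.

H and W at a station are axis-aligned extents (max − min + 1 voxels,
converted to mm) along DV and ML — matching how the calipers are drawn on
the adjusted plane — not maximal rotated in-plane calipers. The aortic
dorsoventral diameter uses the same extent rule at a caller-supplied
transverse station (conventionally just caudal to the cranial mesenteric
artery; landmark detection is out of scope).

## Indices and reference intervals

- **RVA** = ∛(volume in mm³) / aortic DV diameter in mm; computed with
  `cbrt` so the unit case (1 cm³, 10 mm) is exactly 1. Invariant under
  uniform anatomical scaling (volume × s³, diameter × s).
- **CV** of breed means = sample SD (n−1 denominator) of the breed mean
  values divided by their arithmetic mean. Display rounding is 2 decimals;
  unrounded values are always retained. On the published six-breed mean
  lengths and caudal-pole diameters this reproduces the printed 0.20,
  0.22, 0.09, 0.11 and 0.07; rows whose unrounded CV sits within 0.005 of
  a rounding boundary (isthmus height, left cranial height) depend on
  whether the original computation used rounded or unrounded breed means
  and are not asserted.
- **Correlation bands** partition |r|: [0, 0.2) very weak, [0.2, 0.4)
  weak, [0.4, 0.6) moderate, [0.6, 0.8) strong, [0.8, 1] very strong (a
  printed "0.79" boundary resolves into the strong band).
- **Weight classes**: light strictly below 20 kg, heavy otherwise; the
  boundary case 20.0 kg is classed heavy (the prose "less or more than
  20 kg" leaves it unaddressed; this choice is fixed and configurable).
- **Reference tables** hold p10/Q1/median/Q3/p90 per (weight class × side
  × metric), computed with linear interpolation between order statistics
  (`numpy.quantile`, method `"linear"`). Which percentile definition the
  original statistics suite used is unknown; the definition is exposed as
  an option rather than guessed. Strata below a minimum n (default 5) are
  omitted with a warning. Screening a gland returns below-p10 / within /
  above-p90 flags per metric plus a flag against the universal 7.4 mm
  left caudal-height threshold.

## Statistical battery

Normality is gated by Shapiro–Wilk at α = 0.05, applied per group; the
parametric branch requires every group to pass (whether the original gate
was per group or pooled is not stated; per-group is the stricter documented
default).

**Parametric branch:** one-way ANOVA, then the REGWQ multiple range test.
On means ordered ascending, the range of `p` adjacent means is tested with
the studentized-range statistic `q = (m_max − m_min) / √(MSE/ñ)` at level
`α_p = 1 − (1−α)^(p/k)` for `p ≤ k−2` and `α_p = α` for `p ∈ {k−1, k}`,
where MSE is the pooled within-group variance with N−k degrees of freedom
and `ñ` is the harmonic mean of the group sizes in the tested range (the
classical unequal-n adaptation; the procedure's behaviour with unequal n is
otherwise undefined). The step-down recursion never tests a sub-range of an
accepted range; letters encode the maximal accepted (homogeneous) ranges,
so two groups share a letter iff some non-rejected range contains both.
Under a complete null the first (full-range) test is the only rejection
opportunity, so the familywise error equals α; the test suite verifies
5% ± 2 points empirically at 2000 replicates of six groups of ten.

**Nonparametric branch:** Kruskal–Wallis; pairwise two-sample Wilcoxon
tests are run only when Kruskal–Wallis rejects, with raw (uncorrected)
p-values, mirroring how pairwise p-values are conventionally reported in
this literature (a correction hook exists but defaults off). Letters come
from maximal runs, in mean-rank order, within which every pair was
non-rejected. Gating the pairwise tests on the omnibus rejection keeps the
branch's familywise error near α despite the absence of correction.

Side differences use the paired t-test or Wilcoxon signed-rank on
left−right pairs, gated on the normality of the differences. Weight-class
differences use the two-sample Wilcoxon (Mann–Whitney) test.
Weight relationships use Pearson's r with the verbal band. Inclusion
screening drops dogs under 2 years, records missing either gland, and
glands flagged non-homogeneous, recording a reason per exclusion.

## Synthetic data: what it emulates and what it does not

**Phantoms** digitise ellipsoids, cylinders and dumbbells by voxel-centre
inclusion — the same counting model as SAT, so digitisation error is the
only volumetric error and vanishes as spacing → 0 (< 1% at 0.2 mm for the
reference ellipsoid with 15/5/4 mm semi-axes). The dumbbell union volume
(two spheres plus connecting cylinder minus the sphere-embedded stubs) has
a closed form, as do all lengths and section diameters. HU fields are
foreground/background constants plus optional Gaussian noise; identical
seeds give bit-identical phantoms.

**Cohorts** follow the study's structure: six breeds with sizes
(10, 16, 8, 14, 12, 6), truncated-normal weights and ages per breed, and
the recorded sex/neuter composition. Gland volumes follow
`V = a·w^b·exp(ε)` with `ε ~ N(0, 0.15²)`; the defaults
(left: a = 0.2362, b = 0.4852; right: a = 0.2297, b = 0.5105) are a one-off
least-squares fit of log mean volume on log mean weight across the six
published breed summaries — a calibration, not ground truth. The aortic DV
diameter follows `d = 3.172·w^0.3553·exp(δ)`, `δ ~ N(0, 0.07²)`, chosen so
the weight-class RVA medians land at the published ≈1.25 (light) and ≈0.98
(heavy) and aortic calibres stay physiological (≈7 mm at 10 kg, ≈11 mm at
35 kg). Linear metrics are per-metric shape factors times ∛V (in mm) with
lognormal residuals (σ = 0.09); factors were calibrated the same way, and
transverse calipers are capped at 95% of the length to respect the
measurement geometry (a < 10⁻⁵ tail event per gland). Attenuation is drawn
per breed and side from the published means/SDs, which builds the
higher-right-than-left enhancement pattern into the generator directly.
A global seed fans out into one substream per dog, so enlarging a cohort
never changes earlier records.

Under these defaults the simulator reproduces the published cohort
*distributionally*: weight–volume Pearson r ≈ 0.85–0.9 (printed: 0.84
right, 0.80 left), REGWQ letters separating the three large from the three
small breeds, light-class RVA quantiles elementwise above heavy-class ones,
and a heavy-class left caudal-height p90 near 10 mm against the universal
7.4 mm threshold. It does **not** emulate CT physics (beam hardening,
contrast kinetics, dose modulation), organ-shape variation beyond the three
phantom families, segmentation error, or any record-level feature of the
clinical cohort — no per-dog raw data exist. Passing tests therefore
demonstrate correctness of the measurement and statistical machinery under
the stated generating model, not agreement with any individual clinical
measurement.

## Numerical choices and problem sizes

- Studentized-range critical values come from
  `scipy.stats.studentized_range.ppf` and are cached per
  (level, range size, df); zero pooled variance falls back to comparing
  means directly.
- Farthest pairs are computed over convex-hull vertices (exact; brute
  force for degenerate/tiny point sets).
- Quantiles: linear interpolation between order statistics throughout.
- Reorientation resamples at the finest original spacing; masks are
  re-thresholded at 0.5.
- Simulation sizes were chosen to estimate each rate with a standard error
  well inside its acceptance margin: 2000 replicates for the null
  familywise error (SE ≈ 0.5 points), 200 for breed separation, 40 seeds ×
  ~500 dogs for allometric recovery, and a ten-fold (660-dog) cohort for
  stable reference-table percentiles.
- The acceptance script derives every stream from `--seed` via
  `SeedSequence` spawning, keeping derived seeds below 2³¹.

## Known limitations

- Pole/isthmus localisation is area-profile-based and undefined for
  near-spherical masks (deliberate error) and noisy profiles may shift a
  pole by a station; the clinical protocol's observer judgement has no
  formal counterpart.
- Length is a voxel-centre chord; surface-based length would add up to one
  voxel per end.
- The homogeneity flag is a stand-in for an unquantified criterion.
- The simulator's allometric constants are calibrated to six published
  breed-level summary pairs; uncertainty in that calibration is not
  propagated.
- DICOM support covers plain single-frame axial series with uniform slice
  spacing; no multi-frame, gantry-tilt or compressed transfer syntaxes.
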