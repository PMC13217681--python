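# Methods

This note records the models, conventions and design choices behind
`ctveval`, in the order the pipeline applies them.

## Geometric metrics

Masks are 3-D boolean lattices with strictly positive per-axis spacing
(axis 0 = slice axis) and an origin at the centre of voxel (0,0,0). Two
masks are only ever compared on an identical grid; no resampling is
performed, and NIfTI affines with rotation/shear or axis flips are
rejected rather than silently reoriented.

Overlap metrics (DSC, CI, Inclusion, RVD) are pure voxel counts. The
conformity index is the Jaccard index, so CI = DSC/(2−DSC) holds as an
algebraic identity and is enforced by tests to 1e−9. The inclusion index
divides by the reference volume: it asks how much of the expert volume
the observer covered, so over-contouring cannot disguise a miss. RVD is
signed, negative when the observer contour is smaller than the reference.

Surface metrics use a discrete surface: foreground voxels with at least
one background 6-neighbour (out-of-bounds counts as background).
Distances are Euclidean between voxel centres with anisotropic spacing,
obtained by evaluating an exact Euclidean distance transform of one
surface at the other surface's voxels; brute-force all-pairs enumeration
on small random masks is the test oracle. Conventions that have
alternatives in the literature:

* **ASD** is symmetric and *pooled*: the mean of the concatenated
  directed distance lists a→b and b→a, not the mean of the two directed
  means. The two differ only when the surfaces have unequal voxel
  counts; switching is a one-line change in `average_surface_distance`.
* **Percentile Hausdorff distance** is the maximum of the two directed
  p-th percentiles, with linear-interpolation percentiles; p = 100
  recovers the classical Hausdorff distance.
* **DC** uses unweighted foreground-voxel centroids in physical space.

Mesh-based sub-voxel surface distances are out of scope; at the 1.25 mm
in-plane / 5 mm slice grids this package targets, the voxel-centre
discretisation error is well below the interobserver signal.

Empty masks raise rather than return sentinels — a silent 0 mm surface
distance or 0 % overlap entering a cohort mean would bias every
downstream statistic.

## Cohort statistics

* **Interobserver variability** of structure volumes: sample SD (n−1
  denominator — the cohort is treated as a sample of the observer
  population), CV = SD/mean, and MVR = Vmax/Vmin. At least two positive
  volumes are required.
* **Paired pre/post tests**: a Shapiro–Wilk test on the paired
  differences at α = 0.05 (configurable) selects the paired t-test when
  normality is not rejected, otherwise the Wilcoxon signed-rank test.
  The Wilcoxon uses the mainstream convention: zero differences dropped,
  tie-corrected normal approximation, no continuity correction, and at
  least five nonzero pairs. Z is signed by the rank-sum difference of
  pre − post, so an improvement (post > pre) yields negative Z, matching
  how such studies report their statistics. Effect sizes follow the test:
  d = |t|/√n for the t-test, r = |Z|/√n for Wilcoxon, with n the number
  of pairs.
* **No multiplicity adjustment** is applied; reports print raw p-values
  with a single-star p < 0.05 marker. Users running many
  metrics × structures should interpret secondary rows accordingly.
* **Correlations** between Likert items and metrics use Spearman rank
  correlation (average ranks for ties), computed per item × metric on
  pre, post, or per-observer delta (post − pre on both sides) values.
  Because four metrics improve downward (95%HD, ASD, DC, RVD), their
  correlations are negated for display so red always means
  "self-assessment aligned with quality". The literal sign flip is also
  applied to RVD even though RVD is signed (|RVD| proximity to zero is
  an alternative quality reading); with the directional rule, a cohort
  that systematically over-contours and knows it still shows positive
  alignment.

## Quality control

Exclusion mirrors the inclusion flow of prospective delineation studies,
per observer and case: missing phase, voxel-for-voxel identical pre/post
submission (detected on occupancy, not file checksums, to catch re-saved
copies), unreadable/empty/grid-mismatched files, and — for the
questionnaire only — a ceiling effect, operationalised as *all*
pre-training items at the scale maximum, since such a respondent cannot
register improvement. Filtering never raises; every excluded observer
lands in the exclusion log exactly once per analysis with a
machine-readable reason code.

## Synthetic cohorts

The generator emulates the study conditions of a contouring course and is
the package's substitute for clinical data, which such studies do not
deposit.

* **Reference anatomy**: a deterministic union of ellipsoids — a central
  body with two elongated lateral lobes standing in for pelvic nodal
  volumes — voxelised at 657 cm³ on the default grid (5 mm slices,
  1.25 mm in-plane, 60×160×160 voxels). The lobes matter: they give the
  shape a realistically high surface-to-volume ratio, so boundary noise
  moves DSC at rates seen in real cohorts instead of being averaged away
  by a compact blob.
* **Observer model**: three severity knobs applied to the reference's
  signed distance field — random rigid translation (per-axis normal SD,
  mm), uniform boundary growth/erosion (signed mm), and smooth radial
  boundary jitter (SD in mm, Gaussian random field with a fixed 20 mm
  correlation length, the scale of the anatomical features observers
  disagree on). On the distance field these are exact level-set
  operations. The field is boundary-consistent: a half-voxel support
  correction makes its level sets track the geometric boundary at
  sub-voxel precision, so a +2 mm growth reproduces the analytic shell
  volume of a sphere to ~6 % at default spacing.
* **Default severities**: pre-training translation SD 4 mm and jitter SD
  10 mm, giving DSC 0.83 ± 0.04, centroid distance ≈ 10 mm and volume
  ≈ 650 cm³ at study scale — the low-0.8 DSC regime reported for whole
  pelvic CTVs. Post-training halves both severities (2 mm, 5 mm),
  DSC ≈ 0.91. This deliberately produces a *large, unambiguous* training
  effect (paired d ≈ 2): the generator is calibrated to the right orders
  of magnitude and a clearly detectable improvement, not to reproduce
  any particular cohort's exact distributions.
* **Questionnaires**: each observer × item score is a latent normal
  (default mean 3.4, SD 0.9, matching typical pre-training self-ratings)
  rounded and clipped to 1–5; post-training adds a +0.9 latent shift.
  Clipping guarantees valid 5-point responses for any parameters.
* **Reproducibility**: every output is a pure function of (spec, master
  seed). Observer sub-seeds come from numpy `SeedSequence` spawn keys
  indexed by (observer, phase), so enlarging a cohort never reshuffles
  existing observers.

What the generator does **not** model: real CT anatomy and intensity,
observer-specific systematic styles (each contour is an independent
draw, so pre/post correlation within observer is absent), slice-wise
contouring artefacts, and multi-structure anatomical constraints.
Passing tests therefore demonstrate that the *analysis machinery* is
correct and calibrated — not that any particular clinical cohort would
show a given effect.

## Problem sizes and numerical choices

Simulation-heavy checks (detection-rate and null-calibration suites, 50
and 200 cohorts of n = 19) run on the `CohortSpec.small()` preset: the
same 5 mm slices and severities on a 2.5 mm in-plane grid with the
anatomy scaled to 80 % linearly (~340 cm³, 22×56×56 voxels). This keeps
a full cohort under a second to generate and score while preserving the
DSC regime and effect structure; single-cohort analyses and the CLI
default to the full study-scale grid.

Other numerics: percentiles use linear interpolation; the Wilcoxon
normal approximation is compared against exact sign-flip enumeration for
n ≤ 8 in tests (agreement within 0.02 in the decision-relevant p range);
Spearman on constant vectors, all-zero paired differences, and
perturbations that empty a mask raise typed errors instead of producing
NaNs. The null rejection rate of the gated paired comparison on
simulated cohorts sits near its nominal 5 % (measured 2–6 % across seed
batches; the Shapiro gate makes the procedure slightly conservative on
bounded DSC differences).

## Known limitations

* CI and Inclusion have several definitions in the delineation
  literature; this package fixes CI = Jaccard and
  Inclusion = |test∩ref|/|ref|, the pair consistent with the
  DSC/CI/Inclusion/RVD values co-reported in published pelvic-CTV
  cohorts. Alternative readings would need new functions, not new
  parameters, to avoid silent incompatibility.
* Masks must share grids exactly; cross-grid comparison requires
  external resampling, deliberately outside this package.
* The QC ceiling rule ("all pre scores maximal") is one reasonable
  operationalisation of a criterion that published studies state only
  qualitatively.
* Correlation analyses treat observers as independent; repeated
  measures across cases/structures are not modelled (no mixed-effects
  machinery).
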