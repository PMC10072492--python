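# Methods

## The measurement model

Femoral torsion of a fractured neck is measured *directly*, inside one
neck-aligned axial CT section, as the signed angle between two axes:

* the **medial axis** — the line joining the center of the best-fitting
  circle in the femoral head and the center of a circle seated in the
  lateral opening of the head (the aperture where the neck cortices
  meet the head sphere). This axis belongs to the medial (head)
  fragment and rotates with it.
* the **lateral axis** — the line joining the centers of two circles
  inscribed between a supporting tangent along the ventral cortex of
  the greater trochanter and its parallel through the dorsal border at
  the lesser trochanter. Because both inscribed circles are tangent to
  the same parallel pair, this axis is parallel to the tangent; it
  encodes the intact lateral fragment's orientation.

Anteversion (medial axis tipped ventrally relative to the lateral
axis) is positive; retroversion negative. Magnitudes are acute
(≤ 90°).

### Why the section is near-axial

The goniometer (and an implant that rotates postoperatively) turns the
head fragment about an axis approximately parallel to the femoral
shaft. A 2D section can only report the projection of that rotation
onto its own plane: the projected angle scales with cos∠(rotation
axis, section normal). A plane truly containing the 3D neck axis (the
neck is elevated 20–40° out of the axial plane) would have its normal
~30° away from the rotation axis and compress a 30° displacement to
~24° — incompatible with validated recovery. The section used here is
therefore the classic near-axial neck-aligned reformat: its normal is
the superior (shaft) axis tilted `frontal_tilt_deg` (default 10°)
laterally in the frontal view — the section "guided down by the
calcar" — and its in-plane x axis is the axial projection of the neck
axis. With the section tilt matching the device tilt the residual
projection distortion over ±30° is < 0.2°; if the true rotation axis
were exactly vertical instead, the worst-case distortion at 30° would
still be only ~0.5°.

### Frame alignment

Operators supply two hints: the approximate (displaced) head center
and the lateral-fragment neck direction. Alignment then proceeds from
image content:

1. **Head center** — iterated centroid of bright voxels in a ball of
   1.1 × head radius (the ball must clip the head surface, otherwise
   every interior point is a fixed point), with a symmetric ±0.8 r band
   along the neck axis that excludes the attached neck stump. Converges
   to < 0.1 mm on noiseless phantoms.
2. **In-plane orientation** — the flat ventral cortex of the greater
   trochanter (the cortex the tangent is drawn *along*) is parallel to
   the intact neck axis. The frame is iteratively rotated in-plane
   until that cortex line, fitted by total least squares on the
   ventral-extreme contour band, runs along the x axis. This emulates
   the operator rotating the view until it follows the neck, and makes
   the lateral reference an image measurement: hint-direction errors of
   several degrees are corrected to ~0.1°.

   A 3D alternative (principal axis of the segmented head+neck region)
   was evaluated and rejected: near the neck base the segmentation
   merges with shaft and trochanters, and including the medial stump
   couples the reference to the displaced fragment.

### Contours and landmarks

The 5-mm slab is a mean-intensity projection of (by default) 7
resampled planes. Before contouring, the slab is smoothed with a
0.6-mm Gaussian — a scanner-PSF-like regularisation that suppresses
the staircase aliasing of iso-contours on near-grid-aligned edges
(without it, per-level errors reached ~1.7° at ±10°). Contours are
sub-pixel iso-lines at the bone threshold (default 150, between
background 0 and trabecular 300), assigned to the medial or lateral
fragment via connected components across the osteotomy gap. Landmarks
are labeled by position: the head arc by an annulus around the
expected head disc (iteratively re-centered on its own circle fit,
then tightened to ±0.6 mm to shed junction points), the medial stump
cortices by an in-plane distance window from the head center split by
side, the ventral/dorsal cortices of the lateral fragment by extremal
bands. Every missing landmark raises an error naming it.

## The phantom

A stylised left proximal femur (mirrorable) built from closed-form
solids so all ground truth is exact: sphere head (r 24 mm), tapered
frustum neck (r 13→17 mm over 50 mm), cylinder shaft (r 14 mm),
ellipsoid trochanters. Defaults: neck-shaft angle 120° (varus end of
normal) and a lesser trochanter placed at neck-base height — both
chosen so the single near-axial slab shows the head disc, both stumps,
and both trochanter cortices at once, as the workstation views in this
protocol do. The greater trochanter carries a flat ventral cortical
facet parallel to the neck axis, the phantom's analogue of the
extended "frontal cortex" a tangent can be laid along. Intensities:
background 0, trabecular 300, cortical 1200 (2-mm shell), additive
Gaussian noise (default SD 25), default spacing 0.6 × 0.6 × 1.0 mm
(0.8 mm isotropic in the validation runs).

The basicervical osteotomy is a planar cut ⊥ neck axis, 40 mm from the
head center (both trochanters verified lateral at build time), with a
4-mm kerf. The medial fragment rotates rigidly about the displacement
axis — the shaft direction tilted 10° laterally in the frontal plane,
through the osteotomy-plane center — over set angles in [−30°, +30°],
anteversion positive. Because that axis is far from the cut-plane
normal, a rigid cut fragment would collide with its counterpart when
rotated; as a physical jig must, the lateral fragment carries a
one-time *relief cut*: the medial fragment's full ±30° swept volume,
plus 2.5 mm clearance, is carved out. The lateral fragment is then
identical at every set angle (bone volume conserved to < 0.1%), and
disabling the relief (`relief_cut=False`) reproduces the collision
error. Ground truth (landmarks, axes, set angle) travels with the
volume as a JSON sidecar; the stored fragment axes reproduce the set
angle exactly when projected about the displacement axis.

## Rater model and study harness

`run_study` mimics the validation protocol: one phantom per level,
blinded randomized measurement order per rater, ten replicates. Rater
variability is injected where human variability lives — in the
alignment hints (head center ± 1.5 mm, neck direction ± 1.5°, both
Gaussian) — and propagates through the geometry. Because the frame
refinement recovers most of the perturbation, the automated operator
is steadier than the human raters (per-level SD ≈ 0.1–0.4° vs
0.56–2.49° reported): passing the recovery envelope (|bias| ≤ 1.5°,
SD ≤ 2.5° per level) shows geometric soundness of the construction,
not human-level difficulty. `simulate_goniometer_series` provides the
complementary statistical model (measured = set + bias + ε,
ε ~ N(0, σ²), default σ = 1.5°) for exercising the statistics without
imaging.

What the generator does **not** emulate: osteosynthesis hardware and
metal artifacts, beam hardening and streaks, cortical thickness
variation and trabecular texture, soft tissue, Hounsfield calibration,
and the free-hand variability of a human drawing the tangent. Results
on the phantom therefore bound the method's geometric error, not its
clinical inter-rater spread.

## Statistics

* **ICC(A,1)** — single-measures, absolute agreement, from the two-way
  single-observation ANOVA decomposition; 95% CI via the
  Satterthwaite-df F procedure and p for H₀: ICC = 0 from
  F = MSR/MSE (df n−1, (n−1)(k−1)), matching SPSS's "two-way mixed,
  absolute agreement" output (cross-checked against pingouin and an
  explicit double-loop ANOVA oracle to 1e−10). Single measures is the
  right flavor because each cell is one measurement. A zero-residual
  matrix (perfect agreement) reports ICC with a degenerate CI and
  p = 0 rather than NaN.
* **Paired t** — accepts raw differences or printed (mean, SD, n)
  summaries, allowing published confidence bounds to be re-derived
  from a results table; zero-variance differences are reported as
  exact agreement, flagged, rather than NaN.
* **Pearson r** — two-tailed t-based p; α conventions follow the
  study: 0.05 for ICC/t, 0.01 for Pearson. No multiple-testing
  correction is applied across the six per-level tests (none was in
  the study design).
* The battery computes per-replicate ICCs (subjects = the six levels)
  *and* a pooled ICC over all (level, replicate) pairs, labeled
  distinctly, since "mean of all" is ambiguous between the two.

## Numerical choices

* Circle fit: Pratt's algebraic fit (stable on partial arcs) seeds a
  Gauss–Newton refinement of the geometric residual, so the result is
  the true least-squares circle (within 1e−6 of a grid-search oracle's
  cost). Collinear input raises.
* Supporting tangent: exact extremal point of the contour in the
  outward direction; line direction ⊥ outward. Ties resolve to the
  first extremal point (stable under fixed input order).
* Inscribed circles: require band lines parallel within 0.5° and the
  station strictly inside the band.
* Signed angles orient both (undirected) axes 90° clockwise from the
  ventral reference before taking the signed acute angle — a
  convention that is invariant to line flips and gives
  anteversion-positive on both sides; `anteversion_positive=False`
  flips the report.
* World frame LPS (mm); NIfTI I/O negates the first two axes (RAS).
  Slab grids are row-major with the ventral coordinate on rows.
* Determinism: identical volume + hints + parameters give bit-identical
  results; all study randomness descends from one integer seed via
  `SeedSequence` spawning.

## Problem sizes

The validation runs use 0.8-mm isotropic phantoms (~2 × 10⁶ voxels,
~5 s to build, ~0.4 s per measurement), six levels × 10 replicates × 2
raters for the study and 200 simulated series for the agreement model —
sizes chosen to mirror the study design while keeping a full validation
run in the minutes range on one CPU.

## Known limitations

* The "lateral opening" circle is a formalisation (inscribed in the
  medial stump cortices at the head–neck junction); the workstation
  procedure leaves its placement to the operator's eye.
* The inscribed neck circles' stations (fractions 0.35/0.65 of the
  band between opening and lateral cortex) are configurable defaults;
  the angle is insensitive to them because both circles share the band
  mid-line.
* Accuracy degrades with voxel size (≈ ±0.8° worst-case per level at
  1.0 mm vs ±0.6° at 0.8 mm in our runs) and the pipeline assumes the
  two fragments are separable at the bone threshold across the
  osteotomy gap.
* Native anteversion defaults to 0 so the measured angle equals the
  set displacement directly; with a non-zero baseline the measurement
  reports the inter-fragment angle, not anatomical version.
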