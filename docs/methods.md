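# Methods

## The measurement model

The 3D gap area condenses intra-articular fracture displacement into one
number: the total area of the surface that would "fill" the fracture gaps
between the articular portions of all fragment pairs. The pipeline is a
chain of geometric reductions — volume → fragment meshes → articular
patches → boundary contours → fracture lines → spanning surfaces — and
each reduction is deterministic given its parameters, so identical inputs
byte-reproduce the report.

### Segmentation

Bone is extracted with a strict global threshold, HU > 225 (a voxel at
exactly 225 is background). Cortical bone sits far above this on the
Hounsfield scale; the phantom assigns bone 700 HU and background
−1000 HU so the threshold separates them cleanly even with realistic
additive noise. Seeded region growing (26-connectivity) retains only the
components a user marks, which removes both reconstruction noise and
bones adjacent to the radius. Fragment splitting takes one seed group per
fragment: connected components owned by a single group go to that group;
components contested by several groups are divided by a
distance-transform watershed so each voxel joins the group whose seeds
are nearest. A precomputed label mask bypasses splitting entirely, which
is the recommended path when a manual segmentation exists.

Meshing is marching cubes at the 0.5 level of each binary label, with
vertices placed in the volume's physical mm space. There is **no mesh
smoothing by default**: smoothing systematically shrinks surface area and
would bias the gap metric. An opt-in Taubin pass (`smooth=True`) exists
for curved anatomy, where the staircase of a binary isosurface *inflates*
area instead — on a spherical cap phantom 10 Taubin iterations reduce the
patch-area error from ≈ +8% to under 1% while preserving volume.

### Articular marking

Marking proxies generalize the manual painting of the joint surface:

- **face list** — indices taken verbatim (the manual ground truth path);
- **ROI volume** — faces whose *centroid* lies inside a binary volume;
  centroid membership makes boundary triangles deterministic. An ROI may
  carry a direction with a minimum cosine (default 0.3): the articular
  surface faces the carpus, and the orientation gate keeps side walls and
  fracture surfaces out even when their centroids graze the ROI;
- **fitted sphere** — faces within a tolerance band of a sphere whose
  outward normal points away from the center, modeling the gently concave
  carpal-facing surface.

The built-in `top_surface_roi` marks, per grid column, the topmost
foreground voxel and the background voxel above it. On phantoms this
selects the articular top face *including the half-voxel chamfer ring*
marching cubes puts on sharp edges. Including the ring is deliberate: the
patch boundary then lies on the true fracture plane rather than inset by
half a voxel, which is what makes the flat-phantom gap area accurate to
≈ 1% at 0.5 mm voxels. The ring also inflates the reported patch *area*
by roughly perimeter × spacing/√2 (≈ +3% at 0.5 mm, ≈ +1.5% at 0.25 mm);
patch area is a classification input, not the displacement metric, so the
trade is worthwhile.

A fragment is intra-articular when its marked area reaches `min_area`
(default 5 mm²). The threshold is this implementation's operationalization
of "carries articular surface"; it suppresses sliver selections and is
overridable.

### Fracture lines

Boundary edges of a patch (edges with exactly one selected face) are
chained into loops. An edge is a *fracture* edge when the boundary of
another fragment's patch lies within `tol` (default 3 mm, must exceed the
true gap and stay below rim-to-rim distances) **and** that boundary is
geometrically plausible as an opposing fragment:

- it lies ahead of the edge's outward in-plane normal (facing cosine
  ≥ 0.25, evaluated after projecting out the patch's mean normal so the
  chamfer tilt does not distort the angle), or
- it lies essentially above/below the edge (a pure step-off: vertical
  component ≥ 0.7 of the offset, lateral component ≤ 0.3 of the vertical),
  or
- it is in contact (within 1.5 median edge lengths) and the offset is not
  directed along the edge itself.

The lateral exclusions matter at junctions where three or more fragments
meet: without them, the last half-millimetre of one pairwise border leaks
into the neighbouring border. Maximal runs of fracture edges are split
where the nearest opposing fragment changes — the pairwise decomposition
of a junction — and runs shorter than 1 mm (sub-voxel slivers at
junction corners) are dropped.

### Matching and stitching

Lines are matched greedily: repeatedly pair the two unmatched lines from
distinct fragments with the smallest symmetric mean closest-point
distance, while it is ≤ `match_limit` (default 10 mm); ties break on
lower (fragment id, line index). Unmatched lines are reported, never
silently dropped — silent omission would hide comminution. They
contribute zero area.

Each pair is stitched by the classic two-contour construction: both
polylines are resampled to a uniform ≤ 0.5 mm step (area becomes
insensitive to mesh tessellation), the second is reversed if that lowers
the summed endpoint distance, and dynamic programming over the
(|a|−1)×(|b|−1) advance lattice finds the minimal-total-area monotone
triangulation. The DP is exact within the monotone class (verified
against exhaustive enumeration); non-monotone surfaces are out of scope.
Triangle areas are invariant under rigid motion, and resampling is
arc-length based, so the whole computation is rigid-motion invariant to
float precision.

### 2D measures

Sagittal/coronal slices: each fragment's articular contour is its
column-wise top pixel face (half-voxel sub-pixel localization); the gap
is the along-surface distance between the facing contour endpoints of
adjacent fragments, the step-off the offset of the contour heights there,
i.e. perpendicular to the articular tangent. Axial slices carry gap only:
the minimum boundary distance between Voronoi-adjacent fragments (minus
one voxel of center-to-face correction). Where an observer would pick
"the slice with the largest gap", the package scans *every* slice of
every plane — deterministic, and at least as large as any manual choice.
The surgical rule is strict: a maximal gap or step-off of exactly 2.0 mm
is *below* the cut-off.

### Agreement statistics

ICC form is fixed to ICC(2,1) — two-way random effects, absolute
agreement, single rater — because raters are interchangeable in this
design and a constant rater bias should (and does) lower the coefficient.
From the two-way ANOVA mean squares:

ICC = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E)),

with the F-based 95% CI for this form (cross-checked to 1e−10 against an
independent hand-summed ANOVA oracle and against `pingouin`). The model
string is recorded in every result so a deviation from another package's
variant is visible. Quartiles use linear interpolation between order
statistics (recorded in the output; printed IQR endpoints depend on the
convention). Inter-observer differences pool all per-case pairwise
absolute differences by default (`per_case` mode reduces each case to its
median difference first). Missing cells are dropped complete-case.
Outcome records (DASH and PRWE, both 0–100, lower is better) are grouped
by the reference observer's strict 2 mm verdict and summarized as
medians/IQRs only.

## The phantom: what it emulates, what it does not

The phantom is a voxelized articular block — flat plate (analytic
workhorse) or spherical cap (curvature) — cut by oriented planes into
fragments, each rigidly displaced, imaged at a chosen voxel size with
optional Gaussian HU noise from one explicit integer seed. For
translations the expected gap area per interface is the closed form
L·‖t⊥‖ (exact); with rotations no closed form is claimed and the analytic
gap fields are `None`. The observer-table simulator draws a two-way
crossed model y_ij = μ + subject_i + observer_j + ε_ij with chosen
variance components, so reliability estimators can be validated by
parameter recovery (generative ICC 0.8 at the study's 40 × 3 shape is
recovered with |bias| < 0.01 and ≈ 95% CI coverage).

The phantom does **not** emulate anatomical radius geometry, cancellous
texture, soft tissue, beam hardening or metal artifacts, partial-volume
HU blur, or observer variability in marking. Passing phantom tests
therefore demonstrates the geometry engine is correct at a given voxel
size — not that segmentation or marking of clinical CTs is
observer-equivalent.

## Numerical behaviour and problem sizes

- Flat-phantom totals are within 1% of L·d at 0.5 mm voxels for
  d ∈ [1, 5] mm (the residual is a constant ≈ +0.2 mm² corner term).
- Junctions erode each interface end by about half a voxel, so
  multi-fragment phantoms are measured at 0.25 mm spacing where ≤ 5%
  accuracy is wanted (the four-fragment cross reads ≈ 77 of 80 mm² at
  0.25 mm versus ≈ 74 at 0.5 mm).
- Zero displacement yields exactly coincident boundaries and zero area;
  the `no displacement` flag refers to the absence of matched pairs.
- Test and acceptance problem sizes (20 mm plates, 0.25–0.5 mm voxels,
  500-table Monte-Carlo) run in seconds on one CPU and were chosen as the
  smallest sizes at which discretization effects sit clearly below the
  tolerances being asserted.
- Degenerate inputs: fragments that interpenetrate after displacement,
  cuts that miss the plate, seeds on background, patches without
  boundary, and zero-variance observer tables all raise informative
  errors rather than returning numbers.

## Design choices on genuinely open points

- The paper-style workflow marks fracture vs rim by eye; the `tol`
  classifier plus facing/step-off/contact gates is this package's
  operationalization, with every constant exposed.
- How junctions of ≥ 3 fragments are handled is unspecified in the manual
  workflow; the pairwise decomposition (split runs, per-pair surfaces,
  summed) is this package's choice.
- Gap areas are articular-only: extra-articular fracture extensions do
  not contribute.
- The 150 mm² "large gap area" outcome threshold is exposed as a
  report-only flag and deliberately not acted upon — it is a hypothesis,
  not a validated decision rule.
- The greedy mutual-nearest matcher can mis-pair pathological line
  configurations a human would resolve by context; an exhaustive
  assignment was rejected as unnecessary at clinical fragment counts
  (≤ ~6 intra-articular fragments).

## Known limitations

Rotational displacements are voxelized correctly but lack analytic ground
truth; accuracy claims are therefore translation-based. The 2D articular
contour model assumes the joint surface is the top-exposed surface along
one axis, which holds for phantoms and distal-radius-like orientations
but not for arbitrary anatomy. DICOM reading assumes a single axial
series. ICC confidence intervals are asymptotic F-based intervals; for
very small tables (n < 6) their coverage degrades as expected.
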