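# Methods

This note documents the models, parameter choices and numerical details
behind `embryoalign`, and what the synthetic-data experiments do and do
not demonstrate.

## Coordinate and unit conventions

All internal coordinates are micrometers. Volumes are boolean arrays in
(x, y, z) axis order on an isotropic voxel grid; 0-based index `i` maps
to physical position `(i + 0.5) · voxel_size`. The acquisition schedule
is two-phase: `slow_count` stacks at `slow_interval` (default 20 × 10
min, used for staging and shape) followed by `fast_count` stacks at
`fast_interval` (default 2 min, morphogenesis through twitching). The
default acquisition voxel size is 0.1625 µm.

Rigid transforms act as `x ↦ R x + t` with `det R = +1` enforced to
1e-9; transform composition and inversion satisfy the group laws to the
same tolerance. The embryo frame (P1, P2, P3) is right-handed with +P1
anterior; rotations about P1 are positive counterclockwise in the P2–P3
plane (viewed from the anterior).

## Temporal registration

Counts are interpolated with `scipy`'s PCHIP (monotone cubic Hermite) at
factor 5, i.e. four inserted samples per 10-min frame, giving a 2-min
lattice matching the fast-imaging step. The offset objective is the
summed squared count difference divided by the number of overlapping
lattice points; without that normalization a maximal offset that shrinks
the overlap usually wins. Candidate offsets span ±60 min (embryos are
staged to within about an hour at mounting) and candidates leaving less
than 25% of the reference window overlapping are excluded. The offset is
the value *added to the test clock* to land on the reference clock: a
test embryo whose curve is a delayed copy of the reference gets a
negative offset. Multiplicative time rescaling is deliberately omitted;
on aligned count curves the residual dispersion does not support it.

Plateau detection restricts to counts inside (120, 220) and (220, 350),
flags points whose absolute percentage change from the previous
interpolated point is at or below a threshold, and raises the threshold
from 0 in 0.05-percentage-point increments until a connected run longer
than fifteen points appears. One detail worth knowing: the first point
of a perfectly flat stretch carries the entering jump's percentage
change, so a flat run of n samples yields a plateau of n − 1 members.

## Hull moments and scaling

The embryo solid is the uniform-density interior of the convex hull of
the nuclear centers. Volume, centroid and second moments are computed
exactly: the hull (from `scipy.spatial.ConvexHull`) is decomposed into
tetrahedra joining each facet to an interior point, and each
tetrahedron's second-moment matrix uses the closed form
`∫ x_i x_j dV = V/20 (Σ_k v_ki v_kj + (Σ_k v_ki)(Σ_k v_kj))`. A
voxel-fill Monte-Carlo computation and an independent signed-tetrahedron
decomposition against the origin serve as test oracles only. Eigenvalues
of the inertia tensor are sorted ascending; the P1 axis (smallest
moment) is sign-aligned and averaged over the T15–T30 window, during
which the embryo fills the eggshell without elongation reshaping it.

Because moments of a uniform solid scale as the 5th power of distance
(3 from mass, 2 from the distance weighting), two scale factors suffice:
with `a` the long-axis moment and `b` the mean of the two short-axis
moments (the early embryo is nearly rotationally symmetric about P1),
`q1 = a_ref/a_test`, `q2 = (b_ref − a_ref/2)/(b_test − a_test/2)`,
`r_l = q1^(−1/5) q2^(2/5)`, `r_s = q1^(3/10) q2^(−1/10)`. The quantity
`b − a/2` isolates the long-axis second moment, so `r_l` depends only on
length. `b − a/2 ≤ 0` cannot occur for a genuine solid and raises a
geometry error. Windows are averaged on moments and (sign-aligned) axes
separately rather than on inertia tensors, which is robust to centroid
drift between timepoints.

## Point-set registration

`cpd_rigid` is an EM fit of a Gaussian-mixture correspondence model
(source points as mixture centroids, uniform outlier component with
weight w, default 0.1) with a rigid motion model solved each M-step by
weighted orthogonal Procrustes. Instead of re-estimating the Gaussian
width each step, the width follows a deterministic annealing schedule:
it starts at the data scale (or an explicit `initial_width_um`), decays
geometrically (default 0.97/iteration) to a floor, and convergence is
declared on the change of the transform parameters themselves (the
log-likelihood is flat near the optimum). With an automatic floor
(0.3× the mean nearest-neighbor spacing of the target) a final polish
phase continues annealing toward hard assignment, which removes the
small soft-correspondence bias; an explicitly supplied floor is treated
as a contract and never undercut. The algorithm contains no randomness.

The rotation-damped variant multiplies each iteration's incremental
rotation angle by `damping_factor` (default 0.1) while the annealed
width is above `release_width_um` (default 2× mean nearest-neighbor
spacing), then relaxes the factor linearly to 1 as the width approaches
the floor. Translations are never damped. The damping schedule in the
original description is qualitative ("directly reducing the size of
calculated rotations"); multiplicative angle damping is one concrete
realization. Its effect is to permit only rotations that match points to
nearby points, which avoids spurious large-rotation optima created by
partial symmetries or expression differences — demonstrated in the test
suite on a two-optimum cloud where undamped registration rotates ~50°
chasing a bright moved cluster while the damped variant stays at the
true near-identity optimum (verified against a brute-force likelihood
scan over rotations).

`kabsch` provides the closed-form SVD solution for known
correspondences (with reflection correction) and is the oracle for the
EM route; three non-collinear correspondences determine a 3-D rigid
transform uniquely, two leave a one-parameter family.

## Rotation tracking

5000 fiducial voxels (or all, if fewer) are sampled without replacement
per timepoint, projected to (P2, P3), and consecutive pairs registered
in 2-D. The translation is replaced by a center correction fixing the
projected hull centroid, because fiducial nuclei exhibit small concerted
linear movements that would otherwise masquerade as frame drift; the
result is a pure rotation about P1 per step. Cumulative angles are
composed once from the first fast frame rather than resampling masks
incrementally, which avoids compounding interpolation error (at the
cost of intermediate frames not being individually resampled).

For segmented-mask clouds the annealing floor is kept at the nucleus
scale (0.75 µm by default) rather than the voxel scale: below the voxel
pitch the registration locks the two nearly-identical voxel lattices
onto each other and reports zero motion, whereas a nucleus-scale floor
matches whole blobs and averages out rasterization, recovering sub-voxel
per-step rotations (~0.3° accuracy per step in the simulations,
random-walking to ≤3° over a ~40-step track).

## Mapping onto the reference

The composed per-timepoint transform is

    derotate(test track) → test-frame coords → diag(r_l, r_s, r_s)
    → roll by the early-refinement angle → reference-frame coords
    → rerotate(reference track) → per-timepoint rigid refinement

Mapping through both intrinsic frames implicitly performs the coarse P2
alignment; the coarse angle is still reported. The early refinement
registers projected fiducial clouds at the first matched fast timepoint
(2-D by default; the 3-D variant is available) and corrects the
~10–15° scatter inherent in the fiducial-derived P2; a residual above
40° is flagged as a likely alignment failure, matching the observed
failure signature of the method. The final per-timepoint refinement is
rotation-damped 3-D registration with the rotation magnitude capped at
10° (cap saturation sets a QC flag). Timepoints are matched through the
temporal offset rounded to the fast-imaging step. Every stage can be
toggled off in `PipelineConfig`.

The ablation stages used for overlap reporting are: `none` (raw),
`long_axis` (origins, P1 and scale aligned; roll left uncorrected via a
camera-derived perpendicular frame), `indirect` (everything except the
final refinement), and `full`.

## Quantification

Overlap is the fraction of labeled voxels of one mask within 1.0 µm
(inclusive, exact Euclidean distance transform in physical units) of any
labeled voxel of the other, reported in both directions. The nerve-ring
plane fit splits the trace into arms about a supplied center line (split
axis = dominant perpendicular direction), averages all bottom→top
inter-arm vectors into a side-to-side vector (pairs subsampled
deterministically to ≤10⁴; the average is pair-order invariant),
averages the sign-aligned residuals into a forward vector, and takes the
normalized cross product as the plane normal, hemisphere-fixed (positive
dot with +P1 by default). Residuals must be sign-aligned because they
point both ways around the ring and would otherwise cancel exactly.
Compared to a total-least-squares plane, the decomposition is less
sensitive to short non-planar excursions mid-arm (cell-body regions);
the test suite quantifies this on a constructed fixture. Centroid and
plane-angle deviations are point-weighted (trace density is treated as
uniform) and permutation-invariant.

## Synthetic embryos

The generator emulates the statistical structure the pipeline assumes,
not embryo biology:

- **Geometry**: ellipsoid with semi-axes 25 × 12.5 × 12.5 µm; per-embryo
  length jitter up to 9.3% and width jitter up to 4.8% (the observed
  maxima); long axis tilted up to a few degrees off the camera axis with
  a uniform random initial roll.
- **Nuclei**: non-overlapping hard spheres of 1.5 µm radius placed by
  rejection sampling; counts follow a monotone two-plateau template
  (~194 and ~330 nuclei) plus integer-rounded Gaussian noise (sd 2).
- **Fiducial channel**: an anterior cluster growing from 4 to 40 nuclei
  plus exactly 4 posterior-ventral nuclei that define P2. Cluster
  *template* positions are shared across a cohort — the reporter labels
  the same cells in every embryo — then scaled per embryo, with optional
  per-embryo placement noise and per-frame segmentation dropout (5%).
- **Rotation**: per-step magnitudes |N(1.7°, 1.4°)| over the fast pairs
  up to twitching, rescaled to sum exactly to a total drawn from
  N(34.8°, 47.5°), all steps sharing the counterclockwise-preferred
  sign.
- **Temporal offset**: the embryo's developmental clock is shifted by
  `offset` relative to the template; twitching occurs at template time
  270 min.
- **Reporter channel**: a one-voxel-thick ring of radius 7 µm near 2/3
  embryo length, tilted 10° and centered slightly off-axis so that roll
  errors displace its voxels, dilated to ~2 voxels, plus two cell-body
  blobs outside the ring.
- **Frame jitter**: optional per-frame Gaussian translations (sd 0.8 µm)
  emulating the concerted nuclear movements the center correction must
  cancel.

Default synthetic movies use 0.75 µm voxels (grid 78 × 46 × 46) and a
55-frame fast window — coarser and shorter than the acquisition defaults
— sized so that full-cohort simulation studies run on a single CPU in
minutes; the alignment pipeline itself is resolution-agnostic. The
end-to-end recovery experiments use five test embryos with offsets up to
±20 min and scale jitter up to 5%, generated noise-free so that residual
error is attributable to the pipeline.

What passing these experiments shows: the pipeline's stages invert the
generator's known distortions (offset, anisotropic scale, accumulated
rotation, frame placement) to stated tolerances, and each computational
primitive matches an independent oracle. What it does not show:
robustness to segmentation artifacts of real microscopy (nonuniform
false-negative structure, intensity-dependent detection, optical
anisotropy), to non-rigid deformation after twitching onset, or to
fiducial expression patterns differing strongly between individuals —
real fiducial variability is emulated only as placement noise plus
dropout around a shared template.

## Known limitations

- Rotation tracking assumes most inter-frame fiducial change is bulk
  rotation; pathological expression changes between neighboring frames
  would be absorbed into the track.
- The rotation-damping schedule and its thresholds are heuristic; the
  cap on final refinements (10°) trades failure containment against the
  ability to correct genuinely large residuals.
- Mask transformation uses nearest-voxel rasterization of voxel centers,
  adding up to half a voxel diagonal of error to overlap statistics at
  the synthetic resolution.
- Plateau search uses acquisition-clock times; offset-corrected plateau
  timing is available by shifting the series before detection.
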