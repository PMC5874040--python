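# embryoalign

Automated spatiotemporal alignment of 4D *C. elegans* embryo fluorescence
movies, from pre-morphogenesis through the onset of muscle twitching.

Developing embryos are imaged in arbitrary orientations, start imaging at
slightly different developmental ages, differ in size by a few percent,
and rotate bodily about their long axis inside the eggshell during
morphogenesis. Quantitative comparison of cell and neurite positions
across individuals therefore requires registering every movie onto a
common spatiotemporal reference. `embryoalign` implements that
registration for movie bundles consisting of a pan-nuclear channel
(segmented nuclear centers) and a sparse, anteriorly-biased fiducial
nuclear channel, plus a ground-truthed synthetic-embryo generator for
validating every stage. It is aimed at developmental biologists and image
analysts working with light-sheet recordings of embryogenesis.

## The method

Given a reference embryo and a test embryo, alignment proceeds in stages:

1. **Temporal registration.** Nuclear counts over the slow-imaging window
   (T1–T20, 10-min intervals) are interpolated with monotone piecewise
   cubic Hermite polynomials (5× density) and the test curve is shifted
   by the lattice offset δ minimizing `SSE(δ)/overlap(δ)`; normalizing by
   the overlap prevents the degenerate maximal-offset optimum. Cell-count
   plateaus (~200-cell and ball stage, count windows 120–220 and 220–350)
   are detected by raising a |%-change| threshold from 0 until a
   connected run of more than fifteen interpolated points appears.
2. **Long axis.** The embryo body is modeled as the uniform-density solid
   bounded by the convex hull of the nuclear centers. Its inertia tensor
   is computed exactly by tetrahedral decomposition; the long
   (anterior–posterior) axis P1 is the principal axis of the smallest
   moment, averaged over T15–T30, and oriented by the anterior bias of
   the fiducial reporter.
3. **Size correction.** Moments of inertia of a uniform solid scale as
   the fifth power of a spatial scale factor. With `a` the long-axis
   moment and `b` the mean short-axis moment, the factors applied to a
   test embryo are

       q1 = a_ref / a_test,  q2 = (b_ref − a_ref/2) / (b_test − a_test/2)
       r_l = q1^(−1/5) · q2^(2/5),  r_s = q1^(3/10) · q2^(−1/10)

4. **Perpendicular axes.** The vector from the mean posterior to the mean
   anterior fiducial position, projected onto the plane normal to P1,
   defines P2 (and P3 = P1 × P2), giving each embryo a time-invariant
   intrinsic frame before morphogenesis.
5. **Rotation tracking.** During morphogenesis the embryo rotates about
   P1. Fiducial voxels of consecutive fast timepoints (2-min intervals)
   are sampled, projected onto the P2–P3 plane, and registered rigidly in
   2-D with an annealed Gaussian-mixture (coherent-point-drift style)
   algorithm; the translation is replaced by a center correction so each
   step is a pure rotation, and signed steps are summed into a rotation
   track.
6. **Mapping and refinement.** A test embryo is mapped into the reference
   frame through its intrinsic frame (implicitly aligning P2), refined by
   a 2-D registration at an early fast timepoint (corrects the
   few-degree scatter of the fiducial-derived P2; starting registration
   without this coarse alignment frequently lands in large-rotation local
   optima), then per matched timepoint by a rotation-damped 3-D
   registration that allows free translations but only small rotations.

Alignment quality is quantified by the bidirectional fraction of labeled
voxels within 1 µm of the other embryo's mask, and nerve-ring geometry by
an inter-arm vector-decomposition plane fit that resists the non-planar
stubs near cell bodies better than least squares.

## Worked example

Simulate two embryos sharing a fiducial template and align one onto the
other:

```python
from embryoalign import PipelineConfig, align_embryo
from embryoalign.synthetic import make_cohort

ref, ref_truth, tests, truths = make_cohort(n_test=1, seed=7, noise_free=True)
res = align_embryo(tests[0], ref, PipelineConfig(seed=0))
print(f"offset  : true {truths[0].offset_min:+.1f} min, estimated {res.temporal.offset_min:+.1f} min")
print(f"length  : true ratio {ref_truth.semi_axes_um[0]/truths[0].semi_axes_um[0]:.4f}, "
      f"estimated r_l {res.scale.r_l:.4f}")
print(f"rotation: true {truths[0].cumulative_at(res.test_model.last_index):+.1f} deg, "
      f"estimated {res.rotation_track.total_deg:+.1f} deg")
```

prints (seed 7):

```
offset  : true -7.9 min, estimated -8.0 min
length  : true ratio 0.9712, estimated r_l 0.9765
rotation: true +49.7 deg, estimated +47.6 deg
```

The estimated offset lands on the 2-min acquisition lattice nearest the
true value; the length ratio is recovered to about half a percent; the
accumulated bulk rotation over ~40 registration steps is recovered to
about 2°. The composed per-timepoint transform then places the synthetic
nerve-ring centroid within a small fraction of a micrometer of its
position in the reference.

A CLI mirrors the library (`embryoalign simulate / temporal / axes /
rotations / align / quantify`); every stochastic step is seeded and
re-running with the same inputs reproduces all outputs bit-exactly.

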