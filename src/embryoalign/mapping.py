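"""Mapping test embryos onto the reference coordinate system.

Each embryo gets a time-invariant intrinsic frame (P1 from hull moments,
anterior from fiducial bias, P2/P3 from the fiducial cluster asymmetry)
plus a rotation track canceling bulk rotation during morphogenesis.
Aligning a test embryo to the reference then chains, per timepoint:

  de-rotate (test track) -> test frame coords -> anisotropic scale
  -> early roll refinement -> reference frame coords
  -> re-rotate (reference track) -> per-timepoint damped 3-D refinement

The early refinement corrects the few-degree scatter of the fiducial-
derived P2 axis by 2-D registration of projected clouds at one early fast
timepoint; without the coarse frame alignment first, global registration
frequently settles into large-rotation local optima, so a residual above
``early_warn_deg`` is flagged as a likely alignment failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axes import (
    EmbryoFrame,
    InertiaSummary,
    ScaleFactors,
    anterior_orientation,
    hull_moments,
    long_axis,
    scale_factors,
)
from .bundle import EmbryoBundle
from .errors import AmbiguityError, GeometryError, PipelineError, ValidationError
from .io import LabelVolume
from .registration import (
    CpdParams,
    RigidTransform,
    RotationDamping,
    _rotation_about,
    cpd_rigid,
    cpd_rigid_damped,
)
from .rotation import (
    RotationTrack,
    center_correction,
    sample_fiducial_points,
    track_rotations,
)
from .temporal import TemporalOffset, interpolate_counts, temporal_offset

STAGES = ("none", "long_axis", "indirect", "full")


@dataclass
class PipelineConfig:
    """Parameters and stage toggles for the full alignment pipeline."""

    interpolation_factor: int = 5
    max_offset_min: float = 60.0
    min_overlap_frac: float = 0.25
    axis_window: tuple[int, int] = (15, 30)  # reference timepoints, inclusive
    perp_axes_ref_index: int = 20
    early_refine_ref_index: int | None = None  # default: first matched fast timepoint
    early_use_3d: bool = False
    early_warn_deg: float = 40.0
    final_rotation_cap_deg: float = 10.0
    n_sample: int = 5000
    seed: int = 0
    rotation_stride: int = 1
    # annealing floors sit at the nucleus scale: matching is soft over whole
    # nuclei, which averages out voxel quantization of the segmented blobs
    step_params: CpdParams = field(
        default_factory=lambda: CpdParams(
            initial_width_um=2.5, final_width_um=0.75, width_decay=0.9, max_iterations=80
        )
    )
    early_params: CpdParams = field(
        default_factory=lambda: CpdParams(
            initial_width_um=8.0, final_width_um=0.75, width_decay=0.9, max_iterations=100
        )
    )
    final_params: CpdParams = field(
        default_factory=lambda: CpdParams(
            initial_width_um=5.0, final_width_um=0.75, width_decay=0.9, max_iterations=100,
            damping=RotationDamping(enabled=True, release_width_um=2.0),
        )
    )
    do_temporal: bool = True
    do_scaling: bool = True
    do_rotation_track: bool = True
    do_early_refine: bool = True
    do_final_refine: bool = True


@dataclass(frozen=True)
class Affine:
    """General affine map x -> A x + b (scaling makes composed maps non-rigid)."""

    A: np.ndarray
    b: np.ndarray

    @classmethod
    def identity(cls) -> "Affine":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rigid(cls, t: RigidTransform) -> "Affine":
        return cls(t.rotation.copy(), t.translation_um.copy())

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.A.T + self.b

    def compose(self, other: "Affine") -> "Affine":
        """Apply ``other`` first, then ``self``."""
        return Affine(self.A @ other.A, self.A @ other.b + self.b)

    def matrix4(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.A
        M[:3, 3] = self.b
        return M


@dataclass
class EmbryoModel:
    """Per-embryo derived quantities feeding the alignment chain."""

    bundle: EmbryoBundle
    offset: TemporalOffset
    frame: EmbryoFrame
    summaries: list[InertiaSummary]
    track: RotationTrack
    first_fast: int
    last_index: int

    def cumulative_at(self, t_index: int) -> float:
        k = t_index - (self.first_fast + 1)
        if k < 0 or len(self.track.angles_deg) == 0:
            return 0.0
        k = min(k, len(self.track.angles_deg) - 1)
        return float(self.track.cumulative_deg[k])


@dataclass
class AlignmentResult:
    embryo_id: str
    temporal: TemporalOffset
    scale: ScaleFactors
    coarse_p2_rotation_deg: float
    early_refinement_deg: float
    rotation_track: RotationTrack
    ref_track: RotationTrack
    matched_pairs: list[tuple[int, int]]  # (test index, ref index)
    per_timepoint_refinements: dict[int, RigidTransform]
    qc_flags: dict[str, list] = field(default_factory=dict)
    # internal models kept for transform construction
    test_model: EmbryoModel | None = None
    ref_model: EmbryoModel | None = None

    def ref_index_for(self, t_test: int) -> int:
        for tt, tr in self.matched_pairs:
            if tt == t_test:
                return tr
        raise PipelineError(f"timepoint {t_test} is not matched")

    def transform_at(self, t_test: int, stage: str = "full") -> Affine:
        """Composed test->reference transform for a matched test timepoint."""
        if stage not in STAGES:
            raise ValidationError(f"unknown stage {stage!r}; expected one of {STAGES}")
        if stage == "none":
            return Affine.identity()
        tm, rm = self.test_model, self.ref_model
        t_ref = self.ref_index_for(t_test)
        r_l, r_s = self.scale.r_l, self.scale.r_s
        S = np.diag([r_l, r_s, r_s])

        if stage == "long_axis":
            Bt = _camera_roll_frame(tm.frame).basis
            Br = _camera_roll_frame(rm.frame).basis
            A = Br.T @ S @ Bt
            b = rm.frame.origin_um - A @ tm.frame.origin_um
            return Affine(A, b)

        # indirect / full chain
        derot = _rotation_about(tm.frame.P1, np.deg2rad(-tm.cumulative_at(t_test)))
        roll = _rot1(np.deg2rad(self.early_refinement_deg))
        rerot = _rotation_about(rm.frame.P1, np.deg2rad(rm.cumulative_at(t_ref)))
        A = rerot @ rm.frame.basis.T @ roll @ S @ tm.frame.basis @ derot
        b = rm.frame.origin_um - A @ tm.frame.origin_um
        out = Affine(A, b)
        if stage == "full":
            fine = self.per_timepoint_refinements.get(t_test)
            if fine is None:
                raise PipelineError(f"no final refinement stored for timepoint {t_test}")
            out = Affine.from_rigid(fine).compose(out)
        return out


def _rot1(angle_rad: float) -> np.ndarray:
    """Rotation about the first (P1) axis in frame coordinates."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _camera_roll_frame(frame: EmbryoFrame) -> EmbryoFrame:
    """Frame sharing P1 but with perpendicular axes derived from camera y.

    Used for the 'long axis aligned' ablation stage: the roll about P1 is
    left uncorrected (deterministic but arbitrary).
    """
    p1 = frame.P1
    y = np.array([0.0, 1.0, 0.0])
    p2 = y - (y @ p1) * p1
    n = np.linalg.norm(p2)
    if n < 1e-6:
        y = np.array([0.0, 0.0, 1.0])
        p2 = y - (y @ p1) * p1
        n = np.linalg.norm(p2)
    p2 = p2 / n
    return EmbryoFrame(P1=p1, P2=p2, P3=np.cross(p1, p2), origin_um=frame.origin_um)


# ---------------------------------------------------------------------------
# axis construction


def perpendicular_axes(
    fiducial: LabelVolume, p1: np.ndarray, centroid_um: np.ndarray, eps: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """P2/P3 from the fiducial asymmetry.

    The vector from the mean posterior to the mean anterior fiducial voxel
    position (split at the centroid plane normal to P1) is projected onto
    the plane perpendicular to P1 and normalized to give P2; P3 = P1 x P2.
    """
    p1 = np.asarray(p1, float)
    pts = fiducial.labeled_points_um()
    if len(pts) == 0:
        raise ValidationError("empty fiducial mask")
    coord = (pts - np.asarray(centroid_um, float)) @ p1
    ant = pts[coord > 0]
    post = pts[coord <= 0]
    if len(ant) == 0 or len(post) == 0:
        raise GeometryError("fiducial voxels all on one side of the centroid plane")
    v = ant.mean(axis=0) - post.mean(axis=0)
    v = v - (v @ p1) * p1
    n = np.linalg.norm(v)
    if n < eps:
        raise AmbiguityError("posterior->anterior vector is parallel to P1")
    p2 = v / n
    return p2, np.cross(p1, p2)


def coarse_align(test_frame: EmbryoFrame, ref_frame: EmbryoFrame) -> float:
    """Signed rotation (deg) about P1 bringing test P2 onto reference P2."""
    p1 = ref_frame.P1

    def proj(v):
        w = v - (v @ p1) * p1
        return w / np.linalg.norm(w)

    a = proj(test_frame.P2)
    b = proj(ref_frame.P2)
    return float(np.rad2deg(np.arctan2(np.cross(a, b) @ p1, a @ b)))


# ---------------------------------------------------------------------------
# embryo characterization


def _matched_index(grid, t_ref: int, offset_min: float, ref_grid) -> int:
    """Test timepoint matched to reference timepoint ``t_ref``."""
    return grid.index_near(ref_grid.time_of(t_ref) - offset_min)


def characterize_embryo(
    bundle: EmbryoBundle,
    config: PipelineConfig,
    ref_bundle: EmbryoBundle | None = None,
    ref_counts=None,
) -> EmbryoModel:
    """Temporal offset, intrinsic frame, moment summaries and rotation track.

    With ``ref_bundle`` None the embryo is treated as the reference itself
    (offset 0, windows taken at face value).
    """
    grid = bundle.grid
    is_ref = ref_bundle is None
    ref_grid = grid if is_ref else ref_bundle.grid

    counts = bundle.nuclei.count_series()
    slow = min(grid.slow_count, len(counts))
    raw = type(counts)(counts.times_min[:slow], counts.counts[:slow], 1)
    interp = interpolate_counts(raw, config.interpolation_factor)
    if is_ref or not config.do_temporal:
        offset = TemporalOffset(0.0, 0.0, len(interp))
    else:
        offset = temporal_offset(
            interp, ref_counts, config.max_offset_min, config.min_overlap_frac
        )

    lo, hi = config.axis_window
    window = []
    for tr in range(lo, hi + 1):
        t = tr if is_ref else _matched_index(grid, tr, offset.offset_min, ref_grid)
        if t in bundle.nuclei.timepoints:
            window.append(t)
    if not window:
        raise PipelineError(f"{bundle.embryo_id}: no nuclei in the axis window")
    summaries = [hull_moments(bundle.nuclei.centers(t)) for t in window]
    p1 = long_axis(summaries)
    origin = np.mean([s.centroid_um for s in summaries], axis=0)

    t_perp = (
        config.perp_axes_ref_index
        if is_ref
        else _matched_index(grid, config.perp_axes_ref_index, offset.offset_min, ref_grid)
    )
    fid = bundle.fiducial_at(t_perp)
    sign = anterior_orientation(fid, p1, origin)
    p1 = sign * p1
    p2, p3 = perpendicular_axes(fid, p1, origin)
    frame = EmbryoFrame(P1=p1, P2=p2, P3=p3, origin_um=origin, anterior_sign=1)

    first_fast = grid.slow_count + 1
    last = bundle.last_pretwitch_index
    if config.do_rotation_track and last > first_fast:
        fast_ts = list(range(first_fast, last + 1))
        bundle.require_fiducial(fast_ts)
        masks = [bundle.fiducial[t] for t in fast_ts]
        track = track_rotations(
            masks, frame, config.step_params, config.n_sample,
            seed=config.seed, stride=config.rotation_stride,
        )
    else:
        track = RotationTrack(
            angles_deg=np.zeros(max(last - first_fast, 0)),
            sample_seed=config.seed, n_sample=config.n_sample,
        )
    return EmbryoModel(
        bundle=bundle, offset=offset, frame=frame, summaries=summaries,
        track=track, first_fast=first_fast, last_index=last,
    )


# ---------------------------------------------------------------------------
# refinement steps


def refine_early(
    test_pts: np.ndarray,
    ref_pts: np.ndarray,
    ref_frame: EmbryoFrame,
    params: CpdParams,
    use_3d: bool = False,
    warn_deg: float = 40.0,
) -> tuple[float, bool]:
    """Residual roll about P1 after the coarse frame alignment.

    Both clouds are given in world coordinates with the coarse chain already
    applied to the test cloud.  Default: 2-D registration of (P2, P3)
    projections, center-corrected to a pure rotation about P1.
    """
    if use_3d:
        res = cpd_rigid(test_pts, ref_pts, params)
        axis, ang = res.transform.axis_angle
        angle = float(ang * np.sign(axis @ ref_frame.P1))
    else:
        src = ref_frame.to_frame(test_pts)[:, 1:]
        tgt = ref_frame.to_frame(ref_pts)[:, 1:]
        res = cpd_rigid(src, tgt, params)
        pure = center_correction(res.transform, np.zeros(2))
        angle = pure.angle_deg
    return angle, bool(abs(angle) > warn_deg or res.warning)


def refine_per_timepoint(
    test_cloud: np.ndarray,
    ref_cloud: np.ndarray,
    params: CpdParams,
    rotation_cap_deg: float = 10.0,
) -> tuple[RigidTransform, bool]:
    """Damped 3-D refinement: free translation, small rotation, capped."""
    res = cpd_rigid_damped(test_cloud, ref_cloud, params)
    t = res.transform
    axis, ang = t.axis_angle
    flagged = res.warning
    if ang > rotation_cap_deg:
        # clip the rotation magnitude at the cap, preserve the axis;
        # re-anchor the translation at the cloud centroid
        c = test_cloud.mean(axis=0)
        fixed = t.apply(c[None, :])[0]
        R = _rotation_about(axis, np.deg2rad(rotation_cap_deg))
        t = RigidTransform(R, fixed - R @ c)
        flagged = True
    return t, flagged


# ---------------------------------------------------------------------------
# full pipeline


def _matched_fast_pairs(test_model: EmbryoModel, ref_model: EmbryoModel) -> list[tuple[int, int]]:
    pairs = []
    grid, rgrid = test_model.bundle.grid, ref_model.bundle.grid
    for tt in range(test_model.first_fast, test_model.last_index + 1):
        t_ref = rgrid.index_near(grid.time_of(tt) + test_model.offset.offset_min)
        if ref_model.first_fast <= t_ref <= ref_model.last_index and t_ref in ref_model.bundle.fiducial:
            pairs.append((tt, t_ref))
    return pairs


def align_embryo(
    test_bundle: EmbryoBundle,
    ref_bundle: EmbryoBundle,
    config: PipelineConfig | None = None,
    ref_model: EmbryoModel | None = None,
) -> AlignmentResult:
    """Run the full alignment of one test embryo onto the reference."""
    config = config or PipelineConfig()
    if ref_model is None:
        ref_model = characterize_embryo(ref_bundle, config)
    ref_counts_interp = None
    if config.do_temporal:
        counts = ref_bundle.nuclei.count_series()
        slow = min(ref_bundle.grid.slow_count, len(counts))
        raw = type(counts)(counts.times_min[:slow], counts.counts[:slow], 1)
        ref_counts_interp = interpolate_counts(raw, config.interpolation_factor)
    test_model = characterize_embryo(
        test_bundle, config, ref_bundle=ref_bundle, ref_counts=ref_counts_interp
    )

    if config.do_scaling:
        sf = scale_factors(ref_model.summaries, test_model.summaries)
    else:
        sf = ScaleFactors(1.0, 1.0, 1.0, 1.0)
    coarse = coarse_align(test_model.frame, ref_model.frame)

    pairs = _matched_fast_pairs(test_model, ref_model)
    if not pairs:
        raise PipelineError(
            f"{test_bundle.embryo_id}: no matched fast timepoints with the reference"
        )

    qc: dict[str, list] = {"early_warning": [], "final_cap": [], "registration": []}
    result = AlignmentResult(
        embryo_id=test_bundle.embryo_id,
        temporal=test_model.offset,
        scale=sf,
        coarse_p2_rotation_deg=coarse,
        early_refinement_deg=0.0,
        rotation_track=test_model.track,
        ref_track=ref_model.track,
        matched_pairs=pairs,
        per_timepoint_refinements={},
        qc_flags=qc,
        test_model=test_model,
        ref_model=ref_model,
    )

    if config.do_early_refine:
        if config.early_refine_ref_index is not None:
            t_t, t_r = min(
                pairs, key=lambda p: abs(p[1] - config.early_refine_ref_index)
            )
        else:
            t_t, t_r = pairs[0]
        chain = result.transform_at(t_t, stage="indirect")
        src = sample_fiducial_points(
            test_bundle.fiducial_at(t_t), config.n_sample, config.seed + 101
        )
        tgt = sample_fiducial_points(
            ref_bundle.fiducial_at(t_r), config.n_sample, config.seed + 103
        )
        angle, warn = refine_early(
            chain.apply(src), tgt, ref_model.frame, config.early_params,
            use_3d=config.early_use_3d, warn_deg=config.early_warn_deg,
        )
        result.early_refinement_deg = angle
        if warn:
            qc["early_warning"].append(float(angle))

    if config.do_final_refine:
        for k, (t_t, t_r) in enumerate(pairs):
            chain = result.transform_at(t_t, stage="indirect")
            src = sample_fiducial_points(
                test_bundle.fiducial_at(t_t), config.n_sample, config.seed + 211 + 2 * k
            )
            tgt = sample_fiducial_points(
                ref_bundle.fiducial_at(t_r), config.n_sample, config.seed + 212 + 2 * k
            )
            fine, flagged = refine_per_timepoint(
                chain.apply(src), tgt, config.final_params, config.final_rotation_cap_deg
            )
            result.per_timepoint_refinements[t_t] = fine
            if flagged:
                qc["final_cap"].append(t_t)
    return result


def align_cohort(
    ref_bundle: EmbryoBundle,
    test_bundles: list[EmbryoBundle],
    config: PipelineConfig | None = None,
    keep_going: bool = False,
) -> list[AlignmentResult | None]:
    """Align every test embryo onto the shared reference model."""
    config = config or PipelineConfig()
    ref_model = characterize_embryo(ref_bundle, config)
    out: list[AlignmentResult | None] = []
    for tb in test_bundles:
        try:
            out.append(align_embryo(tb, ref_bundle, config, ref_model=ref_model))
        except PipelineError:
            if not keep_going:
                raise
            out.append(None)
    return out


# ---------------------------------------------------------------------------
# stage-wise overlap (ablation)


def transform_volume(
    volume: LabelVolume, affine: Affine, out_grid=None
) -> LabelVolume:
    """Map a mask through an affine transform onto a (possibly different) grid."""
    grid = out_grid or volume.grid
    pts = affine.apply(volume.labeled_points_um())
    idx = np.round(pts / grid.voxel_size_um - 0.5).astype(int)
    shape = np.array(grid.shape_voxels)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    mask = np.zeros(grid.shape_voxels, dtype=bool)
    mask[tuple(idx[ok].T)] = True
    return LabelVolume(
        grid=grid, channel=volume.channel, timepoint_index=volume.timepoint_index, mask=mask
    )


def overlap_by_stage(
    test_bundle: EmbryoBundle,
    ref_bundle: EmbryoBundle,
    alignment: AlignmentResult,
    channels: tuple[str, ...] = ("fiducial_gfp", "reporter_gfp"),
    radius_um: float = 1.0,
    stages: tuple[str, ...] = STAGES,
) -> dict[str, dict[str, tuple[float, float]]]:
    """Bidirectional overlap per channel under each partial alignment stage.

    Evaluated at the last matched timepoint before twitching.  Returns
    ``{stage: {channel: (frac_test_near_ref, frac_ref_near_test)}}``.
    """
    from .quantify import overlap_fraction

    t_t, t_r = alignment.matched_pairs[-1]
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for stage in stages:
        aff = alignment.transform_at(t_t, stage=stage)
        per_channel = {}
        for ch in channels:
            store_t = test_bundle.fiducial if ch == "fiducial_gfp" else test_bundle.reporter
            store_r = ref_bundle.fiducial if ch == "fiducial_gfp" else ref_bundle.reporter
            if t_t not in store_t or t_r not in store_r:
                raise PipelineError(f"channel {ch} missing at matched pair ({t_t}, {t_r})")
            moved = transform_volume(store_t[t_t], aff, out_grid=ref_bundle.grid)
            per_channel[ch] = overlap_fraction(moved, store_r[t_r], radius_um)
        out[stage] = per_channel
    return out
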