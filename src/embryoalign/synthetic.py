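"""Synthetic embryo movie bundles with known ground truth.

The generator emulates the statistical structure the alignment pipeline
assumes, not embryo biology: an ellipsoidal embryo (default semi-axes
25 x 12.5 x 12.5 um) whose nuclear count grows through two plateaus
(~200-cell and ball stage); an anterior-biased fiducial nucleus cluster
(4-40 nuclei, appearing over time) plus a 4-nucleus posterior-ventral
cluster fixing the perpendicular (P2) reference direction; bulk rotation
about the long axis during morphogenesis with per-step magnitudes drawn
from the observed per-step distribution and rescaled to a drawn total; a
few-percent inter-embryo size jitter; a temporal offset of tens of
minutes; and a reporter channel containing a ring (near 2/3 embryo
length, slightly tilted and off-axis so that roll errors are detectable)
plus cell-body blobs.

Fiducial and reporter *template* positions are shared across a cohort
(the marker labels the same cells in every embryo) and scaled per embryo;
per-embryo realization adds segmentation dropout and small concerted
frame translations.  All randomness is seeded; identical spec + seed give
bit-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .axes import EmbryoFrame
from .bundle import EmbryoBundle
from .errors import ValidationError
from .io import AcquisitionGrid, CountSeries, LabelVolume, NucleiTimeSeries

BASE_LONG_SEMI_AXIS_UM = 25.0
BASE_SHORT_SEMI_AXIS_UM = 12.5

#: default synthetic acquisition grid: coarser voxels than the paper-scale
#: acquisition grid (0.75 vs 0.1625 um) and a shortened fast window, sized
#: for simulation studies; physical extent still holds a full-size embryo.
DEFAULT_SYNTH_GRID = AcquisitionGrid(
    shape_voxels=(78, 46, 46),
    voxel_size_um=0.75,
    slow_interval_min=10.0,
    fast_interval_min=2.0,
    slow_count=20,
    fast_count=55,
)


@dataclass(frozen=True)
class CountCurveParams:
    """Two-plateau template for the nuclear-count curve (template clock, min)."""

    start_count: float = 60.0
    low_plateau_level: float = 194.0
    low_plateau_window_min: tuple[float, float] = (70.0, 118.0)
    high_plateau_level: float = 330.0
    high_plateau_window_min: tuple[float, float] = (156.0, 204.0)
    end_count: float = 350.0
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if not 120.0 < self.low_plateau_level < 220.0:
            raise ValidationError("low plateau level must lie in (120, 220)")
        if not 220.0 < self.high_plateau_level < 350.0:
            raise ValidationError("high plateau level must lie in (220, 350)")
        for lo, hi in (self.low_plateau_window_min, self.high_plateau_window_min):
            if hi - lo <= 30.0:  # > 15 interpolated 2-min points must fit
                raise ValidationError("plateau duration must exceed 30 min")

    def anchors(self) -> tuple[np.ndarray, np.ndarray]:
        l0, l1 = self.low_plateau_window_min
        h0, h1 = self.high_plateau_window_min
        t = np.array([0.0, l0 * 0.45, l0 * 0.8, l0, l1, (l1 + h0) / 2, h0, h1,
                      h1 + 20.0, h1 + 100.0])
        c = np.array([
            self.start_count,
            self.start_count + 0.4 * (self.low_plateau_level - self.start_count),
            self.start_count + 0.85 * (self.low_plateau_level - self.start_count),
            self.low_plateau_level,
            self.low_plateau_level,
            (self.low_plateau_level + self.high_plateau_level) / 2,
            self.high_plateau_level,
            self.high_plateau_level,
            self.high_plateau_level + 0.5 * (self.end_count - self.high_plateau_level),
            self.end_count,
        ])
        return t, c


def count_template(params: CountCurveParams):
    """Deterministic monotone template c(t) through the plateau anchors."""
    from scipy.interpolate import PchipInterpolator

    t, c = params.anchors()
    interp = PchipInterpolator(t, c)

    def f(times):
        times = np.asarray(times, dtype=float)
        out = interp(np.clip(times, t[0], t[-1]))
        return out

    return f


def simulate_count_curve(
    params: CountCurveParams,
    seed: int = 0,
    grid: AcquisitionGrid = DEFAULT_SYNTH_GRID,
    offset_min: float = 0.0,
) -> CountSeries:
    """Raw slow-window count series sampled from the template.

    Counts at acquisition time tau are ``template(tau + offset_min)`` plus
    integer-rounded Gaussian observation noise (sd ``params.noise_sd``).
    """
    rng = np.random.default_rng(seed)
    times = grid.times_min()[: grid.slow_count]
    f = count_template(params)
    counts = f(times + offset_min)
    counts = np.round(counts + rng.normal(0.0, params.noise_sd, size=len(counts)))
    counts = np.maximum(counts, 1.0)
    return CountSeries(times_min=times, counts=counts, interpolation_factor=1)


# ---------------------------------------------------------------------------
# cohort template (shared cell positions)


@dataclass(frozen=True)
class FiducialTemplate:
    """Cohort-shared cell positions, in base-size embryo-local coordinates.

    Local frame: x along the long axis (anterior = +x), y the ventral->dorsal
    direction at roll 0, origin at the embryo center.  Per-embryo coordinates
    are these positions scaled by the embryo's semi-axis ratios.
    """

    anterior_xyz: np.ndarray  # (n_max, 3), appearance order = row order
    posterior_xyz: np.ndarray  # (4, 3)
    ring_center: np.ndarray  # (3,)
    ring_normal: np.ndarray  # unit, close to +x
    ring_radius_um: float
    cell_body_xyz: np.ndarray  # (k, 3)


def make_fiducial_template(
    seed: int = 0,
    n_anterior_max: int = 40,
    ring_radius_um: float = 7.0,
    ring_tilt_deg: float = 10.0,
) -> FiducialTemplate:
    rng = np.random.default_rng(seed)
    L, W = BASE_LONG_SEMI_AXIS_UM, BASE_SHORT_SEMI_AXIS_UM
    # anterior cluster: rejection-sample inside the ellipsoid, x in [0.1L, 0.8L]
    pts = []
    while len(pts) < n_anterior_max:
        p = rng.uniform([-L, -W, -W], [L, W, W])
        if (p[0] / L) ** 2 + (p[1] / W) ** 2 + (p[2] / W) ** 2 > 0.85**2:
            continue
        if not 0.1 * L <= p[0] <= 0.8 * L:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < 3.0:
            continue
        pts.append(p)
    anterior = np.array(pts)
    posterior = np.array([-0.55 * L, -0.55 * W, 0.0]) + rng.normal(0, 1.2, size=(4, 3))
    tilt = np.deg2rad(ring_tilt_deg)
    normal = np.array([np.cos(tilt), np.sin(tilt), 0.0])
    ring_center = np.array([L / 3.0, -1.5, 0.0])
    # cell bodies near the ventral ends of the ring arms
    u = np.array([-np.sin(tilt), np.cos(tilt), 0.0])
    v = np.array([0.0, 0.0, 1.0])
    ang = np.deg2rad([250.0, 290.0])
    bodies = [
        ring_center + 1.4 * ring_radius_um * (np.cos(a) * u + np.sin(a) * v) for a in ang
    ]
    return FiducialTemplate(
        anterior_xyz=anterior,
        posterior_xyz=posterior,
        ring_center=ring_center,
        ring_normal=normal,
        ring_radius_um=ring_radius_um,
        cell_body_xyz=np.array(bodies),
    )


# ---------------------------------------------------------------------------
# per-embryo spec and ground truth


@dataclass
class SyntheticEmbryoSpec:
    seed: int = 0
    long_semi_axis_um: float = BASE_LONG_SEMI_AXIS_UM
    short_semi_axis_um: float = BASE_SHORT_SEMI_AXIS_UM
    length_scale_jitter: float = 0.0  # signed fraction applied to the long semi-axis
    width_scale_jitter: float = 0.0  # signed fraction applied to the short semi-axes
    temporal_offset_min: float = 0.0
    total_rotation_deg: float = 0.0
    step_rotation_mean_deg: float = 1.7
    step_rotation_sd_deg: float = 1.4
    count_params: CountCurveParams = field(default_factory=CountCurveParams)
    twitch_template_min: float = 270.0  # twitch onset on the template clock
    grid: AcquisitionGrid = field(default_factory=lambda: DEFAULT_SYNTH_GRID)
    nucleus_radius_um: float = 1.5
    tilt_deg: float = 0.0  # long-axis tilt away from the camera x-axis
    tilt_azimuth_deg: float = 0.0
    roll0_deg: float = 0.0  # initial (pre-morphogenesis) roll about the long axis
    dropout_prob: float = 0.05
    translation_jitter_sd_um: float = 0.8
    position_noise_sd_um: float = 0.5  # per-embryo fiducial placement noise
    nuclei_table_timepoints: int = 40

    MAX_LENGTH_JITTER = 0.093
    MAX_WIDTH_JITTER = 0.048

    def __post_init__(self) -> None:
        if self.long_semi_axis_um <= 0 or self.short_semi_axis_um <= 0:
            raise ValidationError("semi-axes must be positive")
        if abs(self.length_scale_jitter) > self.MAX_LENGTH_JITTER + 1e-12:
            raise ValidationError(f"length jitter exceeds max {self.MAX_LENGTH_JITTER}")
        if abs(self.width_scale_jitter) > self.MAX_WIDTH_JITTER + 1e-12:
            raise ValidationError(f"width jitter exceeds max {self.MAX_WIDTH_JITTER}")

    @property
    def semi_axes_um(self) -> np.ndarray:
        return np.array([
            self.long_semi_axis_um * (1 + self.length_scale_jitter),
            self.short_semi_axis_um * (1 + self.width_scale_jitter),
            self.short_semi_axis_um * (1 + self.width_scale_jitter),
        ])


def draw_spec(
    rng: np.random.Generator,
    max_offset_min: float = 20.0,
    max_length_jitter: float = 0.05,
    max_width_jitter: float = 0.04,
    total_rotation_mean_deg: float = 34.8,
    total_rotation_sd_deg: float = 47.5,
    noise_free: bool = False,
    **overrides,
) -> SyntheticEmbryoSpec:
    """Draw a random embryo spec under the cohort study conditions."""
    kw = dict(
        seed=int(rng.integers(0, 2**31 - 1)),
        length_scale_jitter=float(rng.uniform(-max_length_jitter, max_length_jitter)),
        width_scale_jitter=float(rng.uniform(-max_width_jitter, max_width_jitter)),
        temporal_offset_min=float(rng.uniform(-max_offset_min, max_offset_min)),
        total_rotation_deg=float(rng.normal(total_rotation_mean_deg, total_rotation_sd_deg)),
        tilt_deg=float(rng.uniform(0.0, 3.0)),
        tilt_azimuth_deg=float(rng.uniform(0.0, 360.0)),
        roll0_deg=float(rng.uniform(0.0, 360.0)),
    )
    if noise_free:
        kw.update(dropout_prob=0.0, translation_jitter_sd_um=0.0, position_noise_sd_um=0.0)
    kw.update(overrides)
    return SyntheticEmbryoSpec(**kw)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    offset_min: float
    semi_axes_um: np.ndarray  # (L, W, W) after jitter
    frame: EmbryoFrame  # true P1/P2/P3 at roll0, origin at embryo center
    roll0_deg: float
    fast_pair_indices: list[tuple[int, int]]  # (t, t+1) pairs carrying rotation steps
    step_angles_deg: np.ndarray  # signed, one per fast pair
    ring_centroid_base: np.ndarray  # base-size local coordinates
    ring_normal_base: np.ndarray
    twitch_time_min: float

    def cumulative_deg(self) -> np.ndarray:
        return np.cumsum(self.step_angles_deg)

    def cumulative_at(self, t_index: int) -> float:
        """Cumulative rotation (deg) accrued by timepoint ``t_index``."""
        total = 0.0
        for (a, b), ang in zip(self.fast_pair_indices, self.step_angles_deg):
            if b <= t_index:
                total += ang
        return total

    def local_to_world(self, pts_base: np.ndarray, t_index: int,
                       base_semi_axes=(BASE_LONG_SEMI_AXIS_UM, BASE_SHORT_SEMI_AXIS_UM)) -> np.ndarray:
        """Map base-template local coordinates to world at a timepoint."""
        scale = self.semi_axes_um / np.array(
            [base_semi_axes[0], base_semi_axes[1], base_semi_axes[1]]
        )
        pts = np.asarray(pts_base, float) * scale
        # frame basis already contains roll0, so only the accrued bulk
        # rotation is applied on top of it
        cum = np.deg2rad(self.cumulative_at(t_index))
        cr, sr = np.cos(cum), np.sin(cum)
        Rx = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
        return (pts @ Rx.T) @ self.frame.basis + self.frame.origin_um


def _rot_x(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _stamp_balls(grid: AcquisitionGrid, centers_um: np.ndarray, radius_um: float) -> np.ndarray:
    """Rasterize a union of balls onto the voxel grid (voxel-center test)."""
    shape = grid.shape_voxels
    vol = np.zeros(shape, dtype=bool)
    h = grid.voxel_size_um
    r_vox = radius_um / h
    for c in np.atleast_2d(centers_um):
        cv = c / h - 0.5  # center in index coordinates
        lo = np.maximum(np.floor(cv - r_vox).astype(int), 0)
        hi = np.minimum(np.ceil(cv + r_vox).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ix, iy, iz = np.meshgrid(
            *[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij"
        )
        d2 = (ix - cv[0]) ** 2 + (iy - cv[1]) ** 2 + (iz - cv[2]) ** 2
        sub = d2 <= r_vox**2
        vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= sub
    return vol


def _hard_sphere_sample(
    rng: np.random.Generator, n: int, semi_axes: np.ndarray, min_dist: float
) -> np.ndarray:
    """Rejection-sample n points in an ellipsoid with a minimum pair distance."""
    pts: list[np.ndarray] = []
    arr = np.empty((0, 3))
    for _ in range(n):
        best, best_d = None, -1.0
        for _try in range(60):
            p = rng.uniform(-semi_axes, semi_axes)
            if np.sum((p / semi_axes) ** 2) > 1.0:
                continue
            d = np.min(np.linalg.norm(arr - p, axis=1)) if len(arr) else np.inf
            if d >= min_dist:
                best = p
                break
            if d > best_d:
                best, best_d = p, d
        if best is None:  # pragma: no cover - extremely unlikely
            best = rng.uniform(-semi_axes, semi_axes) * 0.5
        pts.append(best)
        arr = np.array(pts)
    return arr


def simulate_embryo(
    spec: SyntheticEmbryoSpec,
    template: FiducialTemplate | None = None,
    embryo_id: str = "synthetic",
) -> tuple[EmbryoBundle, GroundTruth]:
    """Generate one movie bundle plus its ground truth.

    Deterministic in (spec, template): the same inputs give bit-identical
    bundles.
    """
    if template is None:
        template = make_fiducial_template(seed=0)
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    center = grid.extent_um / 2.0
    semi = spec.semi_axes_um
    scale = semi / np.array([BASE_LONG_SEMI_AXIS_UM, BASE_SHORT_SEMI_AXIS_UM,
                             BASE_SHORT_SEMI_AXIS_UM])

    # world orientation: long axis tilted off camera-x, then rolled about it
    tilt = np.deg2rad(spec.tilt_deg)
    az = np.deg2rad(spec.tilt_azimuth_deg)
    tilt_axis = np.array([0.0, np.cos(az), np.sin(az)])
    from .registration import _rotation_about  # Rodrigues helper

    R_tilt = _rotation_about(tilt_axis, tilt)
    R0 = R_tilt @ _rot_x(np.deg2rad(spec.roll0_deg))
    # frame basis rows = world directions of local axes at roll0
    frame = EmbryoFrame(
        P1=R0[:, 0], P2=R0[:, 1], P3=R0[:, 2], origin_um=center.copy(), anterior_sign=1
    )

    f_count = count_template(spec.count_params)
    dev = lambda tau: tau + spec.temporal_offset_min  # acquisition -> template clock
    twitch_time = spec.twitch_template_min - spec.temporal_offset_min

    # --- rotation history over fast pairs up to twitching
    first_fast = grid.slow_count + 1
    last_index = min(grid.n_timepoints, grid.index_near(twitch_time))
    pairs = [(t, t + 1) for t in range(first_fast, last_index)]
    mags = np.abs(rng.normal(spec.step_rotation_mean_deg, spec.step_rotation_sd_deg,
                             size=len(pairs)))
    mags = np.maximum(mags, 1e-3)
    if len(pairs) and abs(spec.total_rotation_deg) > 0:
        steps = mags * (spec.total_rotation_deg / mags.sum())
    else:
        steps = np.zeros(len(pairs))

    truth = GroundTruth(
        offset_min=spec.temporal_offset_min,
        semi_axes_um=semi,
        frame=frame,
        roll0_deg=spec.roll0_deg,
        fast_pair_indices=pairs,
        step_angles_deg=steps,
        ring_centroid_base=template.ring_center.copy(),
        ring_normal_base=template.ring_normal.copy(),
        twitch_time_min=twitch_time,
    )

    # --- per-embryo fiducial realization (template + placement noise)
    ant = template.anterior_xyz * scale + rng.normal(
        0, spec.position_noise_sd_um, size=template.anterior_xyz.shape
    )
    post = template.posterior_xyz * scale + rng.normal(
        0, spec.position_noise_sd_um, size=template.posterior_xyz.shape
    )
    n_ant_max = len(ant)

    def n_anterior(t_dev: float) -> int:
        frac = np.clip(t_dev / spec.twitch_template_min, 0.0, 1.0)
        return int(round(4 + (n_ant_max - 4) * frac))

    # --- ring + cell bodies in scaled local coordinates
    theta = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    nrm = template.ring_normal
    u = np.array([-nrm[1], nrm[0], 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(nrm, u)
    circle = template.ring_center + template.ring_radius_um * (
        np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v)
    )
    circle_scaled = circle * scale
    bodies_scaled = template.cell_body_xyz * scale

    def to_world(local_pts: np.ndarray, cum_deg: float, jit: np.ndarray) -> np.ndarray:
        R = R_tilt @ _rot_x(np.deg2rad(spec.roll0_deg + cum_deg))
        return local_pts @ R.T + center + jit

    # --- nuclei table (pan-nuclear channel), slow + early fast timepoints
    n_table = min(spec.nuclei_table_timepoints, grid.n_timepoints)
    rows = []
    jitters: dict[int, np.ndarray] = {}
    cum_by_index: dict[int, float] = {}
    for t in range(1, grid.n_timepoints + 1):
        cum_by_index[t] = truth.cumulative_at(t)
        if t <= grid.slow_count or spec.translation_jitter_sd_um == 0:
            jitters[t] = np.zeros(3)
        else:
            jitters[t] = rng.normal(0, spec.translation_jitter_sd_um, size=3)
    noise_counts = rng.normal(0, spec.count_params.noise_sd, size=n_table)
    for t in range(1, n_table + 1):
        tau = grid.time_of(t)
        n_true = f_count(dev(tau))
        n_obs = max(1, int(round(n_true + noise_counts[t - 1])))
        local = _hard_sphere_sample(rng, n_obs, semi * 0.97, 2 * spec.nucleus_radius_um)
        world = to_world(local, cum_by_index[t], jitters[t])
        world = np.clip(world, 0.4, grid.extent_um - 0.4)
        for p in world:
            rows.append((t, p[0], p[1], p[2], np.nan))
    nuclei = NucleiTimeSeries(
        records=pd.DataFrame(rows, columns=["t", "x_um", "y_um", "z_um", "intensity"]),
        grid=grid,
    )

    # --- fiducial and reporter volumes
    fiducial: dict[int, LabelVolume] = {}
    reporter: dict[int, LabelVolume] = {}
    vol_indices = [t for t in range(grid.slow_count - 2, last_index + 1) if t >= 1]
    for t in vol_indices:
        tau = grid.time_of(t)
        cum = cum_by_index[t]
        jit = jitters[t]
        na = n_anterior(dev(tau))
        pts = np.vstack([ant[:na], post])
        if spec.dropout_prob > 0:
            keep = rng.random(len(pts)) > spec.dropout_prob
            if keep.sum() < 4:
                keep[:] = True
            pts = pts[keep]
        fid_world = to_world(pts, cum, jit)
        fiducial[t] = LabelVolume(
            grid=grid, channel="fiducial_gfp", timepoint_index=t,
            mask=_stamp_balls(grid, fid_world, spec.nucleus_radius_um),
        )
        if t > grid.slow_count:
            ring_world = to_world(circle_scaled, cum, jit)
            body_world = to_world(bodies_scaled, cum, jit)
            mask = _stamp_balls(grid, ring_world, 0.9 * grid.voxel_size_um)
            mask |= _stamp_balls(grid, body_world, 1.3)
            reporter[t] = LabelVolume(
                grid=grid, channel="reporter_gfp", timepoint_index=t, mask=mask
            )

    bundle = EmbryoBundle(
        embryo_id=embryo_id,
        grid=grid,
        nuclei=nuclei,
        fiducial=fiducial,
        reporter=reporter,
        twitch_time_min=twitch_time,
        metadata={"seed": spec.seed, "offset_min": spec.temporal_offset_min},
    )
    return bundle, truth


def make_cohort(
    n_test: int = 5,
    seed: int = 0,
    noise_free: bool = False,
    template_seed: int | None = None,
    **spec_overrides,
) -> tuple[EmbryoBundle, GroundTruth, list[EmbryoBundle], list[GroundTruth]]:
    """Reference embryo + ``n_test`` test embryos sharing one cell template.

    The reference gets zero temporal offset and size jitter (it defines the
    scales); tests draw offsets, jitters and rotation histories from the
    cohort distributions.
    """
    rng = np.random.default_rng(seed)
    template = make_fiducial_template(seed=seed if template_seed is None else template_seed)
    ref_spec = draw_spec(
        rng, noise_free=noise_free,
        temporal_offset_min=0.0, length_scale_jitter=0.0, width_scale_jitter=0.0,
        **spec_overrides,
    )
    ref_bundle, ref_truth = simulate_embryo(ref_spec, template, embryo_id="reference")
    tests, truths = [], []
    for i in range(n_test):
        sp = draw_spec(rng, noise_free=noise_free, **spec_overrides)
        b, gt = simulate_embryo(sp, template, embryo_id=f"test{i:02d}")
        tests.append(b)
        truths.append(gt)
    return ref_bundle, ref_truth, tests, truths
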