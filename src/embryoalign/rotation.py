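"""Tracking bulk embryo rotation about the long axis.

During morphogenesis the whole embryo rotates inside the eggshell about
its long (P1) axis, by variable amounts and direction.  Consecutive fast
timepoints differ only slightly in fiducial expression/segmentation, so
the apparent motion of fiducial voxels between neighbors is attributed to
bulk rotation: voxels are sampled from the fiducial mask, projected onto
the P2-P3 plane, registered in 2-D, and the translation replaced by a
center correction so each step is a pure rotation about the (fixed) frame
center.  Summing the signed per-step angles gives a time-invariant
internal coordinate system.

Sign convention: positive = counterclockwise in the P2-P3 plane, i.e.
counterclockwise about +P1 viewed from the anterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axes import EmbryoFrame
from .errors import ValidationError
from .io import LabelVolume
from .registration import CpdParams, RigidTransform, cpd_rigid


@dataclass
class RotationTrack:
    """Signed per-step and cumulative rotations over the fast-imaging window."""

    angles_deg: np.ndarray  # one per consecutive timepoint pair
    sample_seed: int
    n_sample: int = 5000
    warnings: list[int] = field(default_factory=list)  # step indices with registration warnings

    @property
    def cumulative_deg(self) -> np.ndarray:
        return np.cumsum(self.angles_deg)

    @property
    def total_deg(self) -> float:
        return float(self.cumulative_deg[-1]) if len(self.angles_deg) else 0.0


def sample_fiducial_points(mask: LabelVolume, n: int = 5000, seed: int = 0) -> np.ndarray:
    """Sample up to ``n`` labeled voxel centers uniformly without replacement."""
    pts = mask.labeled_points_um()
    if len(pts) == 0:
        raise ValidationError(f"empty fiducial mask at timepoint {mask.timepoint_index}")
    if len(pts) <= n:
        return pts
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pts), size=n, replace=False)
    return pts[np.sort(idx)]


def project_to_plane(points_um: np.ndarray, frame: EmbryoFrame) -> np.ndarray:
    """(P2, P3) coordinates of points, i.e. projection onto the plane normal to P1."""
    return frame.to_frame(points_um)[:, 1:]


def center_correction(transform: RigidTransform, frame_center: np.ndarray) -> RigidTransform:
    """Replace the translation so ``frame_center`` is a fixed point.

    Fiducial nuclei exhibit small concerted linear movements independent of
    bulk rotation; keeping the frame center fixed discards them, leaving a
    pure rotation about the long axis.
    """
    if transform.dimension != 2:
        raise ValidationError("center correction applies to 2-D transforms")
    c = np.asarray(frame_center, dtype=float)
    R = transform.rotation
    return RigidTransform(R, c - R @ c)


def step_rotation(
    mask_t: LabelVolume,
    mask_t1: LabelVolume,
    frame: EmbryoFrame,
    params: CpdParams | None = None,
    n_sample: int = 5000,
    seed: int = 0,
) -> tuple[float, bool]:
    """Signed bulk-rotation angle (deg) between two consecutive timepoints.

    Samples fiducial voxels from both masks, projects onto the P2-P3 plane,
    registers the earlier cloud onto the later one in 2-D, and applies the
    center correction.  Returns (angle_deg, warning_flag).
    """
    src = project_to_plane(sample_fiducial_points(mask_t, n_sample, seed), frame)
    tgt = project_to_plane(sample_fiducial_points(mask_t1, n_sample, seed + 1), frame)
    if params is None:
        # floor at the nucleus scale so matching is soft over whole nuclei
        params = CpdParams(initial_width_um=2.5, final_width_um=0.75, width_decay=0.9)
    res = cpd_rigid(src, tgt, params)
    center = frame.to_frame(frame.origin_um[None, :])[0, 1:]  # origin in P2-P3 coords
    pure = center_correction(res.transform, center)
    return pure.angle_deg, res.warning


def accumulate(angles_deg, sample_seed: int = 0, n_sample: int = 5000,
               warnings: list[int] | None = None) -> RotationTrack:
    """Build a RotationTrack from per-step signed angles."""
    angles = np.asarray(angles_deg, dtype=float)
    if angles.ndim != 1 or not np.all(np.isfinite(angles)):
        raise ValidationError("angles must be a finite 1-D list")
    return RotationTrack(
        angles_deg=angles, sample_seed=sample_seed, n_sample=n_sample,
        warnings=list(warnings or []),
    )


def track_rotations(
    masks: list[LabelVolume],
    frame: EmbryoFrame,
    params: CpdParams | None = None,
    n_sample: int = 5000,
    seed: int = 0,
    stride: int = 1,
) -> RotationTrack:
    """Rotation track over a list of consecutive fiducial masks.

    With ``stride > 1`` registration skips frames (the per-step angle is
    spread evenly over the skipped steps), trading accuracy for speed.
    """
    if len(masks) < 2:
        raise ValidationError("need at least two timepoints to track rotation")
    angles = np.zeros(len(masks) - 1)
    warns: list[int] = []
    for i in range(0, len(masks) - 1, stride):
        j = min(i + stride, len(masks) - 1)
        ang, warn = step_rotation(masks[i], masks[j], frame, params, n_sample, seed + 2 * i)
        angles[i:j] = ang / (j - i)
        if warn:
            warns.append(i)
    return RotationTrack(angles_deg=angles, sample_seed=seed, n_sample=n_sample, warnings=warns)
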