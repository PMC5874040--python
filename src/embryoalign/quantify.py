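"""Alignment-quality and nerve-ring geometry metrics.

Overlap between two aligned masks is measured bidirectionally as the
fraction of labeled voxels of one mask lying within 1 um (Euclidean, in
physical units, inclusive) of any labeled voxel of the other, via exact
distance transforms.

The nerve-ring plane is fit by a vector-decomposition method rather than
least squares: the traced ring is split into top and bottom arms about a
given center line, inter-arm vectors are averaged into a side-to-side
vector, the residuals (sign-aligned, since they point both ways around
the ring) average into a forward vector, and the plane normal is their
cross product, fixed to a reference hemisphere.  Least squares overfits
the short non-planar stubs near the cell bodies; the inter-arm averaging
does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ValidationError
from .io import LabelVolume


@dataclass
class NeuriteTrace:
    """Ordered polyline along a traced nerve ring, micrometers."""

    points_um: np.ndarray
    embryo_id: str = ""
    timepoint: int = 0

    def __post_init__(self) -> None:
        self.points_um = np.asarray(self.points_um, dtype=float)
        if self.points_um.ndim != 2 or self.points_um.shape[1] != 3:
            raise ValidationError("trace must be (n, 3)")
        if len(self.points_um) < 10:
            raise ValidationError("trace must contain at least 10 points")
        gaps = np.linalg.norm(np.diff(self.points_um, axis=0), axis=1)
        if np.any(gaps >= 5.0):
            raise ValidationError("consecutive trace points must be < 5 um apart")

    @classmethod
    def from_csv(cls, path, embryo_id: str = "", timepoint: int = 0) -> "NeuriteTrace":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df[["x_um", "y_um", "z_um"]].to_numpy(float), embryo_id, timepoint)


@dataclass(frozen=True)
class PlaneFit:
    side_to_side: np.ndarray
    forward: np.ndarray
    out: np.ndarray
    centroid_um: np.ndarray

    def __post_init__(self) -> None:
        for name in ("side_to_side", "forward", "out"):
            v = np.asarray(getattr(self, name), float)
            object.__setattr__(self, name, v / np.linalg.norm(v))
        if abs(self.out @ self.side_to_side) > 1e-9 or abs(self.out @ self.forward) > 1e-9:
            raise ValidationError("out vector must be perpendicular to both plane vectors")


def overlap_fraction(
    test: LabelVolume, ref: LabelVolume, radius_um: float = 1.0
) -> tuple[float, float]:
    """Bidirectional fraction of labeled voxels within ``radius_um`` of the other mask.

    Returns (fraction of test voxels near ref, fraction of ref voxels near
    test).  An empty mask yields fraction 0 for its own direction.
    """
    if test.grid.shape_voxels != ref.grid.shape_voxels or not np.isclose(
        test.grid.voxel_size_um, ref.grid.voxel_size_um
    ):
        raise ValidationError("masks must share the acquisition grid")
    if radius_um <= 0:
        raise ValidationError("radius must be positive")
    h = test.grid.voxel_size_um

    def frac(own: np.ndarray, other: np.ndarray) -> float:
        n = int(own.sum())
        if n == 0:
            return 0.0
        if not other.any():
            return 0.0
        dist = ndimage.distance_transform_edt(~other, sampling=h)
        return float(np.sum(dist[own] <= radius_um + 1e-9) / n)

    return frac(test.mask, ref.mask), frac(ref.mask, test.mask)


def fit_nr_plane(
    trace: NeuriteTrace,
    center_point_um: np.ndarray,
    center_direction: np.ndarray,
    hemisphere: np.ndarray = (1.0, 0.0, 0.0),
    max_pairs: int = 10_000,
) -> PlaneFit:
    """Fit the nerve-ring plane by top/bottom arm vector decomposition.

    ``center_point_um`` and ``center_direction`` define the center line
    through the ring (set from the reference embryo geometry); points are
    split into arms by the sign of their coordinate along the dominant
    direction perpendicular to the line.  ``hemisphere`` fixes the sign of
    the out vector (positive dot product).
    """
    pts = trace.points_um
    c = np.asarray(center_point_um, dtype=float)
    d = np.asarray(center_direction, dtype=float)
    d = d / np.linalg.norm(d)
    rel = pts - c
    perp = rel - np.outer(rel @ d, d)
    # dominant perpendicular direction = split (dorsoventral) axis
    _, _, vt = np.linalg.svd(perp, full_matrices=False)
    split_axis = vt[0]
    coord = perp @ split_axis
    top = pts[coord > 0]
    bot = pts[coord <= 0]
    if len(top) == 0 or len(bot) == 0:
        raise GeometryError("arm split left an empty arm; check the center line")

    ii, jj = np.meshgrid(np.arange(len(top)), np.arange(len(bot)), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    if len(ii) > max_pairs:
        # deterministic stride subsample; averaging is pair-order invariant
        stride = int(np.ceil(len(ii) / max_pairs))
        ii, jj = ii[::stride], jj[::stride]
    vecs = top[ii] - bot[jj]  # bottom -> top
    s = vecs.mean(axis=0)
    ns = np.linalg.norm(s)
    if ns < 1e-9:
        raise GeometryError("degenerate arm geometry: zero side-to-side vector")
    s_hat = s / ns
    resid = vecs - np.outer(vecs @ s_hat, s_hat)
    # residuals point both ways around the ring: sign-align before averaging
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    ref_dir = vt[0]
    signs = np.sign(resid @ ref_dir)
    signs[signs == 0] = 1.0
    f = (resid * signs[:, None]).mean(axis=0)
    nf = np.linalg.norm(f)
    if nf < 1e-9:
        raise GeometryError("degenerate fit: forward vector vanished")
    f_hat = f / nf
    if abs(np.clip(s_hat @ f_hat, -1, 1)) > 0.999:
        raise GeometryError("side-to-side and forward vectors are near parallel")
    out = np.cross(s_hat, f_hat)
    out /= np.linalg.norm(out)
    hemi = np.asarray(hemisphere, dtype=float)
    if out @ hemi < 0:
        out = -out
    return PlaneFit(
        side_to_side=s_hat, forward=f_hat, out=out, centroid_um=pts.mean(axis=0)
    )


def centroid_deviation(positions_um: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Per-embryo distances from the mean position, plus mean and SD.

    ``positions_um`` is (n_embryos, 3), one aligned position per embryo for
    a single named structure.
    """
    P = np.asarray(positions_um, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or len(P) < 2:
        raise ValidationError("need (n>=2, 3) positions")
    mean = P.mean(axis=0)
    dev = np.linalg.norm(P - mean, axis=1)
    return dev, float(dev.mean()), float(dev.std(ddof=1))


def plane_angle_deviation(out_vectors: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Per-embryo angles (deg) from the mean out-vector direction, plus mean/SD."""
    V = np.asarray(out_vectors, dtype=float)
    if V.ndim != 2 or V.shape[1] != 3 or len(V) < 2:
        raise ValidationError("need (n>=2, 3) unit vectors")
    V = V / np.linalg.norm(V, axis=1, keepdims=True)
    mean = V.sum(axis=0)
    n = np.linalg.norm(mean)
    if n < 1e-9:
        raise GeometryError("vectors cancel: mean direction undefined")
    mean /= n
    ang = np.rad2deg(np.arccos(np.clip(V @ mean, -1.0, 1.0)))
    return ang, float(ang.mean()), float(ang.std(ddof=1))
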