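"""Embryo body axes and size from convex-hull moments of inertia.

The embryo body is modeled as the uniform-density solid bounded by the
convex hull of the segmented nuclear centers.  Volume, centroid and the
inertia tensor of that solid are computed *exactly* by decomposing the
hull into tetrahedra against an interior point and using the closed-form
second-moment integrals of a tetrahedron — no voxelization.  The long
(anterior-posterior, P1) axis is the principal axis with the smallest
moment; the anterior direction is fixed by the anterior bias of the
fiducial reporter.

Because moments of inertia of a uniform solid scale as the fifth power of
a spatial scale factor (three powers from the mass, two from the distance
weighting), two embryos can be brought to a common size from their
moments alone.  With ``a`` the long-axis moment and ``b`` the mean of the
two short-axis moments (the early embryo is nearly rotationally symmetric
about its long axis),

    q1 = a_ref / a_test
    q2 = (b_ref - a_ref/2) / (b_test - a_test/2)
    r_l = q1^(-1/5) * q2^(2/5)      (length factor, applied along P1)
    r_s = q1^(3/10) * q2^(-1/10)    (width factor, applied along P2 and P3)

``b - a/2`` isolates the long-axis extent: for a solid of mass m with
principal second moments Sx >> Sy ~ Sz, a = Sy + Sz and b = Sx + (Sy+Sz)/2,
so b - a/2 = Sx.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import AmbiguityError, GeometryError, ValidationError
from .io import LabelVolume


@dataclass(frozen=True)
class InertiaSummary:
    """Centroid, principal moments and axes of the uniform-density hull solid."""

    centroid_um: np.ndarray
    principal_moments: np.ndarray  # ascending, unit density, mass * um^2
    principal_axes: np.ndarray  # rows matched to moments, orthonormal, right-handed
    hull_volume_um3: float

    def __post_init__(self) -> None:
        m = np.asarray(self.principal_moments, float)
        if np.any(np.diff(m) < -1e-9 * max(1.0, m[-1])):
            raise ValidationError("principal moments must be sorted ascending")
        A = np.asarray(self.principal_axes, float)
        if np.abs(A @ A.T - np.eye(3)).max() > 1e-8:
            raise ValidationError("principal axes must be orthonormal")
        if self.hull_volume_um3 <= 0:
            raise ValidationError("hull volume must be positive")

    @property
    def long_axis(self) -> np.ndarray:
        """Axis of the smallest principal moment (unoriented)."""
        return self.principal_axes[0]


@dataclass(frozen=True)
class EmbryoFrame:
    """Embryo-intrinsic orthonormal coordinate system.

    +P1 points anterior; P2/P3 are fixed by the fiducial asymmetry;
    P3 = P1 x P2 (right-handed).
    """

    P1: np.ndarray
    P2: np.ndarray
    P3: np.ndarray
    origin_um: np.ndarray
    anterior_sign: int = 1

    def __post_init__(self) -> None:
        B = self.basis
        if np.abs(B @ B.T - np.eye(3)).max() > 1e-8:
            raise ValidationError("P1, P2, P3 must be orthonormal")
        if abs(np.linalg.det(B) - 1.0) > 1e-8:
            raise ValidationError("frame must be right-handed (det = +1)")
        if self.anterior_sign not in (-1, 1):
            raise ValidationError("anterior_sign must be +/-1")

    @property
    def basis(self) -> np.ndarray:
        """3x3 matrix with rows P1, P2, P3."""
        return np.vstack([self.P1, self.P2, self.P3]).astype(float)

    def to_frame(self, points_um: np.ndarray) -> np.ndarray:
        """World -> frame coordinates (P1, P2, P3 components)."""
        return (np.asarray(points_um, float) - self.origin_um) @ self.basis.T

    def to_world(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.basis + self.origin_um


@dataclass(frozen=True)
class ScaleFactors:
    """Anisotropic factors bringing a test embryo to the reference scale."""

    a_ref: float
    a_test: float
    b_ref: float
    b_test: float

    @property
    def q1(self) -> float:
        return self.a_ref / self.a_test

    @property
    def q2(self) -> float:
        num = self.b_ref - self.a_ref / 2
        den = self.b_test - self.a_test / 2
        if num <= 0 or den <= 0:
            raise GeometryError("b - a/2 must be positive for a genuine solid")
        return num / den

    @property
    def r_l(self) -> float:
        return self.q1 ** (-1 / 5) * self.q2 ** (2 / 5)

    @property
    def r_s(self) -> float:
        return self.q1 ** (3 / 10) * self.q2 ** (-1 / 10)


# ---------------------------------------------------------------------------
# exact hull moments


def _tetra_second_moment(v: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Volume, first moment and second-moment matrix of tetra (0, v1, v2, v3).

    For a tetrahedron with vertices p1..p4 and volume V:
      integral x_i x_j dV = V/20 * (sum_k p_ki p_kj + (sum_k p_ki)(sum_k p_kj))
    Here one vertex is the origin, so the sums run over v1..v3.
    """
    vol = abs(np.linalg.det(v)) / 6.0
    s = v.sum(axis=0)
    first = vol * s / 4.0
    second = vol / 20.0 * (v.T @ v + np.outer(s, s))
    return vol, first, second


def hull_moments(points_um: np.ndarray) -> InertiaSummary:
    """Exact inertia summary of the uniform-density convex hull of points.

    Decomposes the hull into tetrahedra joining each triangular facet to an
    interior point and accumulates closed-form tetrahedron integrals; the
    result is exact up to floating point, with total mass = volume (unit
    density).
    """
    pts = np.asarray(points_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError("points must be (n, 3)")
    if len(pts) < 4:
        raise GeometryError("need at least 4 points for a 3-D hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise GeometryError(f"degenerate (coplanar/collinear) point set: {exc}") from exc
    if hull.volume <= 0:
        raise GeometryError("hull has zero volume (coplanar points)")

    interior = pts[hull.vertices].mean(axis=0)
    V = 0.0
    F = np.zeros(3)
    S = np.zeros((3, 3))
    for simplex in hull.simplices:
        v = pts[simplex] - interior
        vol, first, second = _tetra_second_moment(v)
        V += vol
        F += first
        S += second
    centroid_local = F / V
    centroid = interior + centroid_local
    # shift second moments to the centroid (parallel-axis in matrix form)
    S_c = S - V * np.outer(centroid_local, centroid_local)
    J = np.trace(S_c) * np.eye(3) - S_c
    moments, axes = np.linalg.eigh(J)
    axes = axes.T  # rows
    if np.linalg.det(axes) < 0:
        axes[2] *= -1
    return InertiaSummary(
        centroid_um=centroid,
        principal_moments=moments,
        principal_axes=axes,
        hull_volume_um3=float(V),
    )


def long_axis(summaries: list[InertiaSummary]) -> np.ndarray:
    """Average the smallest-moment axis over a window of timepoints.

    Principal axes carry a sign ambiguity; each axis is sign-aligned to the
    first before averaging, then the mean is renormalized.
    """
    if not summaries:
        raise ValidationError("empty window: no inertia summaries")
    ref = summaries[0].long_axis
    acc = np.zeros(3)
    for s in summaries:
        v = s.long_axis
        acc += v if v @ ref >= 0 else -v
    n = np.linalg.norm(acc)
    if n < 1e-12:
        raise GeometryError("axes cancel: cannot average long axis")
    return acc / n


def anterior_orientation(
    fiducial: LabelVolume, p1: np.ndarray, centroid_um: np.ndarray
) -> int:
    """Resolve the sign of P1 from the anterior bias of the fiducial reporter.

    The fiducial reporter is expressed predominantly in anterior nuclei, so
    the half-space (about the centroid plane normal to P1) containing more
    labeled voxels is anterior.  Returns +1 if +p1 already points anterior,
    -1 if it must be flipped.
    """
    pts = fiducial.labeled_points_um()
    if len(pts) == 0:
        raise ValidationError("empty fiducial mask: cannot orient P1")
    coord = (pts - np.asarray(centroid_um, float)) @ np.asarray(p1, float)
    n_pos = int(np.sum(coord > 0))
    n_neg = int(np.sum(coord < 0))
    if n_pos == n_neg:
        raise AmbiguityError("fiducial mask is balanced across the centroid plane")
    return 1 if n_pos > n_neg else -1


def _window_ab(summaries: list[InertiaSummary]) -> tuple[float, float]:
    a = float(np.mean([s.principal_moments[0] for s in summaries]))
    b = float(np.mean([(s.principal_moments[1] + s.principal_moments[2]) / 2 for s in summaries]))
    return a, b


def scale_factors(
    ref_summaries: list[InertiaSummary], test_summaries: list[InertiaSummary]
) -> ScaleFactors:
    """Length/width factors mapping the test embryo onto the reference scale.

    ``a`` (long-axis moment, the smallest) and ``b`` (mean of the two
    short-axis moments) are averaged over the supplied ball-stage window for
    each embryo before applying the fifth-power-law formulas.
    """
    if not ref_summaries or not test_summaries:
        raise ValidationError("scale windows must be nonempty")
    a_ref, b_ref = _window_ab(ref_summaries)
    a_test, b_test = _window_ab(test_summaries)
    sf = ScaleFactors(a_ref=a_ref, a_test=a_test, b_ref=b_ref, b_test=b_test)
    sf.q2  # raises GeometryError on non-solid input
    return sf


def apply_scaling(
    points_um: np.ndarray, factors: ScaleFactors, frame: EmbryoFrame
) -> np.ndarray:
    """Scale points by r_l along P1 and r_s along P2/P3, about the frame origin."""
    r_l, r_s = factors.r_l, factors.r_s
    if r_l <= 0 or r_s <= 0:
        raise ValidationError("scale factors must be positive")
    coords = frame.to_frame(points_um)
    coords *= np.array([r_l, r_s, r_s])
    return frame.to_world(coords)


def apply_scaling_volume(
    volume: LabelVolume, factors: ScaleFactors, frame: EmbryoFrame
) -> LabelVolume:
    """Nearest-neighbor resample of a mask under the anisotropic scaling."""
    from dataclasses import replace
    from scipy import ndimage

    r = np.array([factors.r_l, factors.r_s, factors.r_s])
    if np.any(r <= 0):
        raise ValidationError("scale factors must be positive")
    grid = volume.grid
    # inverse map: output voxel center -> input voxel center
    B = frame.basis
    shape = grid.shape_voxels
    idx = np.indices(shape).reshape(3, -1).T
    out_pts = grid.voxel_centers_um(idx)
    coords = (out_pts - frame.origin_um) @ B.T
    coords /= r
    in_pts = coords @ B + frame.origin_um
    in_idx = np.round(in_pts / grid.voxel_size_um - 0.5).astype(int)
    ok = np.all((in_idx >= 0) & (in_idx < np.array(shape)), axis=1)
    vals = np.zeros(len(idx), dtype=bool)
    vals[ok] = volume.mask[tuple(in_idx[ok].T)]
    return replace(volume, mask=vals.reshape(shape))
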