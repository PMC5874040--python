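"""Rigid point-set registration.

Two routes are provided: a Gaussian-mixture registration with deterministic
annealing (coherent-point-drift style EM, rigid motion model, uniform
outlier component), in plain and rotation-damped variants, and the Kabsch
closed form for known correspondences.  The EM route has no internal
randomness: given the same clouds and parameters it returns the same
transform.

The rotation-damped variant shrinks each EM iteration's incremental
rotation toward the identity while the annealed Gaussian width is still
large, releasing to full rotations as the width falls below a threshold.
This biases the search toward solutions that match points to *nearby*
points — translations of arbitrary size remain allowed — which avoids
spurious large-rotation local optima when clouds are already roughly
aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import AmbiguityError, ValidationError

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation in 2 or 3 dimensions, ``T(x) = R x + t``."""

    rotation: np.ndarray
    translation_um: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation_um, dtype=float)
        d = R.shape[0]
        if d not in (2, 3) or R.shape != (d, d) or t.shape != (d,):
            raise ValidationError(f"bad rigid transform shapes: R {R.shape}, t {t.shape}")
        if np.abs(R.T @ R - np.eye(d)).max() > 1e-6:
            raise ValidationError("rotation is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValidationError("rotation determinant is not +1 (reflection?)")
        # re-orthonormalize so the group invariants hold to tight tolerance
        u, _, vt = np.linalg.svd(R)
        R = u @ vt
        if np.linalg.det(R) < 0:  # pragma: no cover - excluded by det check above
            u[:, -1] *= -1
            R = u @ vt
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation_um", t)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls, dimension: int) -> "RigidTransform":
        return cls(np.eye(dimension), np.zeros(dimension))

    @classmethod
    def from_angle_2d(cls, angle_deg: float, translation_um=(0.0, 0.0)) -> "RigidTransform":
        a = np.deg2rad(angle_deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        return cls(R, np.asarray(translation_um, float))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, translation_um=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValidationError("zero rotation axis")
        return cls(_rotation_about(axis / n, np.deg2rad(angle_deg)), np.asarray(translation_um, float))

    # -- group operations ---------------------------------------------
    @property
    def dimension(self) -> int:
        return self.rotation.shape[0]

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation_um

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        if self.dimension != other.dimension:
            raise ValidationError("dimension mismatch in compose")
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation_um + self.translation_um,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation_um)

    # -- derived views -------------------------------------------------
    @property
    def angle_deg(self) -> float:
        """Signed rotation angle (2D) or rotation magnitude (3D), degrees."""
        if self.dimension == 2:
            return float(np.rad2deg(np.arctan2(self.rotation[1, 0], self.rotation[0, 0])))
        axis, ang = self.axis_angle
        return float(ang)

    @property
    def axis_angle(self) -> tuple[np.ndarray, float]:
        """(unit axis, angle in degrees) for a 3-D rotation."""
        if self.dimension != 3:
            raise ValidationError("axis_angle is defined for 3-D transforms only")
        R = self.rotation
        cos = np.clip((np.trace(R) - 1) / 2, -1.0, 1.0)
        ang = np.arccos(cos)
        if ang < 1e-12:
            return np.array([1.0, 0.0, 0.0]), 0.0
        w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        nw = np.linalg.norm(w)
        if nw < 1e-12:  # angle ~ pi
            # axis from the dominant column of R + I
            M = R + np.eye(3)
            axis = M[:, np.argmax(np.linalg.norm(M, axis=0))]
            axis = axis / np.linalg.norm(axis)
        else:
            axis = w / nw
        return axis, float(np.rad2deg(ang))


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def _scale_rotation(R: np.ndarray, factor: float) -> np.ndarray:
    """Shrink a rotation toward the identity by multiplying its angle."""
    d = R.shape[0]
    if d == 2:
        ang = np.arctan2(R[1, 0], R[0, 0]) * factor
        return np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    t = RigidTransform(R, np.zeros(3))
    axis, ang = t.axis_angle
    return _rotation_about(axis, np.deg2rad(ang) * factor)


@dataclass(frozen=True)
class RotationDamping:
    """Bias against rotations while the annealed Gaussian width is large."""

    enabled: bool = False
    damping_factor: float = 0.1
    release_width_um: float | None = None  # default: 2x mean NN spacing of target

    def __post_init__(self) -> None:
        if not 0 < self.damping_factor <= 1:
            raise ValidationError("damping_factor must be in (0, 1]")


@dataclass(frozen=True)
class CpdParams:
    """Parameters of the annealed Gaussian-mixture registration."""

    outlier_weight: float = 0.1
    max_iterations: int = 200
    tolerance: float = 1e-6
    initial_width_um: float | None = None  # default: RMS extent of the data
    final_width_um: float | None = None  # default: 0.3x mean NN spacing of target
    width_decay: float = 0.97
    damping: RotationDamping = field(default_factory=RotationDamping)

    def __post_init__(self) -> None:
        if not 0 <= self.outlier_weight < 1:
            raise ValidationError("outlier weight must be in [0, 1)")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be > 0")
        if not 0 < self.width_decay < 1:
            raise ValidationError("width_decay must be in (0, 1)")
        if (
            self.initial_width_um is not None
            and self.final_width_um is not None
            and self.final_width_um > self.initial_width_um
        ):
            raise ValidationError("widths must be decreasing")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    converged: bool
    n_iterations: int
    final_width_um: float
    log_likelihood: float

    @property
    def warning(self) -> bool:
        return not self.converged


def _mean_nn_spacing(points: np.ndarray) -> float:
    if len(points) < 2:
        return 1.0
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return float(np.mean(d[:, 1]))


def cpd_rigid(
    source: np.ndarray,
    target: np.ndarray,
    params: CpdParams | None = None,
) -> RegistrationResult:
    """Register ``source`` onto ``target`` with a rigid transform.

    EM on a Gaussian-mixture correspondence model: source points are mixture
    centroids, target points are data, and a uniform component with weight
    ``outlier_weight`` absorbs unmatched points.  The Gaussian width follows
    a deterministic annealing schedule (geometric decay per iteration down
    to a floor); the M-step solves the weighted orthogonal Procrustes
    problem.  Deterministic: no internal randomness.
    """
    params = params or CpdParams()
    X = np.asarray(target, dtype=float)  # data, (N, D)
    Y = np.asarray(source, dtype=float)  # centroids, (M, D)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValidationError(f"dimension mismatch: source {Y.shape}, target {X.shape}")
    if len(X) == 0 or len(Y) == 0:
        raise ValidationError("point sets must be nonempty")
    D = X.shape[1]
    if D not in (2, 3):
        raise ValidationError("only 2-D and 3-D registration supported")
    N, M = len(X), len(Y)

    R = np.eye(D)
    t = X.mean(axis=0) - Y.mean(axis=0)

    nn = _mean_nn_spacing(X)
    if params.initial_width_um is not None:
        sigma = float(params.initial_width_um)
    else:
        # sigma^2 = mean squared distance over all cross pairs / D (closed form)
        TY = Y @ R.T + t
        sx, sy = X.sum(axis=0), TY.sum(axis=0)
        ss = M * (X**2).sum() + N * (TY**2).sum() - 2 * sx @ sy
        sigma = max(float(np.sqrt(ss / (D * N * M))), 1e-6)
    auto_floor = params.final_width_um is None
    sigma_floor = params.final_width_um if params.final_width_um is not None else 0.3 * nn
    sigma_floor = max(sigma_floor, 1e-6)
    sigma = max(sigma, sigma_floor)
    # with an automatic floor, a final polish phase anneals further toward
    # hard assignment, removing the soft-correspondence bias of the floor
    polish_floor = max(0.05 * nn, 1e-4)
    polishing = False
    release = (
        params.damping.release_width_um if params.damping.release_width_um is not None else 2.0 * nn
    )

    w = params.outlier_weight
    prev_ll = -np.inf
    ll = -np.inf
    converged = False
    it = 0
    from scipy.spatial.distance import cdist

    for it in range(1, params.max_iterations + 1):
        R_old, t_old = R, t
        TY = Y @ R.T + t
        d2 = cdist(TY, X, "sqeuclidean")  # (M, N)
        num = np.exp(-d2 / (2 * sigma**2))
        c = (2 * np.pi * sigma**2) ** (D / 2) * w * M / ((1 - w) * N) if w > 0 else 0.0
        den = num.sum(axis=0) + c
        den = np.where(den <= 0, np.finfo(float).tiny, den)
        P = num / den  # (M, N)
        Np = P.sum()
        if Np < 1e-12:
            break
        ll = float(np.log(den).sum() - N * D / 2 * np.log(2 * np.pi * sigma**2))

        Px = P.sum(axis=1)  # (M,)
        Pn = P.sum(axis=0)  # (N,)
        mu_x = (Pn @ X) / Np
        mu_y = (Px @ Y) / Np
        Xc = X - mu_x
        Yc = Y - mu_y
        A = Xc.T @ (P.T @ Yc)  # (D, D)
        U, _, Vt = np.linalg.svd(A)
        C = np.eye(D)
        C[-1, -1] = np.sign(np.linalg.det(U @ Vt))
        R_new = U @ C @ Vt
        if params.damping.enabled:
            if sigma > release:
                lam = params.damping.damping_factor
            else:
                span = max(release - sigma_floor, 1e-12)
                frac = np.clip((release - sigma) / span, 0.0, 1.0)
                lam = params.damping.damping_factor + (1 - params.damping.damping_factor) * frac
            dR = R_new @ R.T
            R_new = _scale_rotation(dR, lam) @ R
        R = R_new
        t = mu_x - R @ mu_y

        at_floor = sigma <= sigma_floor * (1 + 1e-12)
        param_delta = np.abs(R - R_old).max() + np.abs(t - t_old).max()
        # the log-likelihood is flat near the optimum, so convergence is
        # declared on the transform parameters themselves
        if at_floor and param_delta < 10 * params.tolerance:
            if auto_floor and sigma_floor > polish_floor:
                sigma_floor = polish_floor
                polishing = True
            else:
                converged = True
                break
        prev_ll = ll
        decay = 0.7 if polishing else params.width_decay
        sigma = max(sigma * decay, sigma_floor)

    return RegistrationResult(
        transform=RigidTransform(R, t),
        converged=converged,
        n_iterations=it,
        final_width_um=float(sigma),
        log_likelihood=ll,
    )


def cpd_rigid_damped(
    source: np.ndarray,
    target: np.ndarray,
    params: CpdParams | None = None,
) -> RegistrationResult:
    """Rotation-damped rigid registration (free translations, small rotations)."""
    params = params or CpdParams()
    if not params.damping.enabled:
        params = CpdParams(
            outlier_weight=params.outlier_weight,
            max_iterations=params.max_iterations,
            tolerance=params.tolerance,
            initial_width_um=params.initial_width_um,
            final_width_um=params.final_width_um,
            width_decay=params.width_decay,
            damping=RotationDamping(
                enabled=True,
                damping_factor=params.damping.damping_factor,
                release_width_um=params.damping.release_width_um,
            ),
        )
    return cpd_rigid(source, target, params)


def kabsch(source_matched: np.ndarray, target_matched: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform for corresponded points.

    Exact for noiseless rigid pairs.  In 3-D at least 3 non-collinear
    correspondences are required for a unique answer (2 points leave a
    one-parameter family of rotations about the joining axis); in 2-D at
    least 2 distinct points.
    """
    S = np.asarray(source_matched, dtype=float)
    T = np.asarray(target_matched, dtype=float)
    if S.shape != T.shape or S.ndim != 2:
        raise ValidationError(f"corresponded lists must share shape; got {S.shape} vs {T.shape}")
    D = S.shape[1]
    if D not in (2, 3):
        raise ValidationError("only 2-D and 3-D supported")
    n = len(S)
    if n < D:
        raise AmbiguityError(f"need at least {D} correspondences in {D}-D, got {n}")
    Sc = S - S.mean(axis=0)
    Tc = T - T.mean(axis=0)
    sv = np.linalg.svd(Sc, compute_uv=False)
    scale = max(sv[0], 1.0)
    if D == 3 and (len(sv) < 2 or sv[1] < 1e-9 * scale):
        raise AmbiguityError(
            "source points are collinear: rotation about the joining axis is undetermined "
            "(one-parameter family of solutions)"
        )
    if D == 2 and sv[0] < 1e-12:
        raise AmbiguityError("source points are coincident: rotation is undetermined")
    H = Sc.T @ Tc
    U, _, Vt = np.linalg.svd(H)
    C = np.eye(D)
    C[-1, -1] = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ C @ U.T
    t = T.mean(axis=0) - R @ S.mean(axis=0)
    return RigidTransform(R, t)
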