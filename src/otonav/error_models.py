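"""Statistical models of navigation uncertainty.

Implements the classical point-based-registration error statistics:

* FLE (fiducial localization error) composition in quadrature across
  independent sources (image-space localization, electromagnetic tracking).
* FLE recovery from the measured FRE via <FRE^2> = (1 - 2/N) <FLE^2>.
* The first-order closed-form prediction of the RMS target registration
  error for isotropic FLE,

      <TRE^2(r)> = (<FLE^2>/N) * (1 + (1/3) * sum_k d_k^2 / f_k^2),

  where d_k is the distance of the target from principal axis k of the
  fiducial configuration and f_k the RMS distance of the fiducials from
  that axis.
* First-order propagation of fiducial noise through the rigid fit to a
  full 3x3 TRE covariance at the target, from which chi-square confidence
  ellipses are derived for display in the lateral plane.
* A seeded Monte-Carlo oracle (perturb, refit, measure) used to validate
  both analytic paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core_geometry import (
    DegenerateGeometryError,
    LabeledPointSet,
    ValidationError,
    Vector3,
    as_vector3,
)

__all__ = [
    "FLEModel",
    "FiducialConfiguration",
    "TREPrediction",
    "ConfidenceEllipse",
    "combine_fle",
    "fle_from_fre",
    "predict_tre_rms",
    "predict_tre_covariance",
    "confidence_ellipse",
    "monte_carlo_tre",
    "fit_rigid_batch",
]

_DEGENERACY_TOL = 1e-9


@dataclass(frozen=True)
class FLEModel:
    """Fiducial localization error model.

    ``components`` are independent RMS error sources (mm); the total is
    their root-sum-of-squares. An optional 3x3 covariance (mm^2) describes
    anisotropic noise; its trace must equal ``total_rms**2``.
    """

    components: tuple[tuple[str, float], ...]
    total_rms: float
    covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        rss2 = sum(r**2 for _, r in self.components)
        if abs(rss2 - self.total_rms**2) > 1e-9 * max(rss2, 1.0):
            raise ValidationError("total_rms^2 must equal the sum of squared components")
        if self.covariance is not None:
            C = np.asarray(self.covariance, dtype=float)
            if C.shape != (3, 3) or not np.allclose(C, C.T, atol=1e-12):
                raise ValidationError("FLE covariance must be symmetric 3x3")
            if np.min(np.linalg.eigvalsh(C)) < -1e-12:
                raise ValidationError("FLE covariance must be positive semidefinite")
            if abs(np.trace(C) - self.total_rms**2) > 1e-9 * max(self.total_rms**2, 1.0):
                raise ValidationError("FLE covariance trace must equal total_rms^2")
            object.__setattr__(self, "covariance", C)

    @property
    def isotropic(self) -> bool:
        if self.covariance is None:
            return True
        return np.allclose(
            self.covariance, np.eye(3) * self.total_rms**2 / 3.0, atol=1e-12
        )


def combine_fle(components: Iterable[tuple[str, float]]) -> FLEModel:
    """Combine independent FLE sources in quadrature (root-sum-of-squares)."""
    comps = tuple((str(name), float(rms)) for name, rms in components)
    if not comps:
        raise ValidationError("at least one FLE component is required")
    for name, rms in comps:
        if rms < 0 or not np.isfinite(rms):
            raise ValidationError(f"FLE component {name!r} has invalid rms {rms}")
    total = float(np.sqrt(sum(r**2 for _, r in comps)))
    return FLEModel(components=comps, total_rms=total)


def fle_from_fre(fre_rms: float, n_fiducials: int) -> float:
    """Recover the RMS FLE from the expected FRE: FLE = FRE / sqrt(1 - 2/N)."""
    if n_fiducials < 3:
        raise ValidationError("FLE-from-FRE requires at least 3 fiducials")
    if fre_rms < 0:
        raise ValidationError("FRE must be non-negative")
    return float(fre_rms / np.sqrt(1.0 - 2.0 / n_fiducials))


@dataclass
class FiducialConfiguration:
    """A fiducial configuration with its principal-axis geometry.

    Derived quantities (centroid, orthonormal principal axes, per-axis RMS
    fiducial distances f_k) drive the TRE prediction.
    """

    fiducials: LabeledPointSet
    centroid: Vector3 = field(init=False)
    principal_axes: np.ndarray = field(init=False)  # columns = axes
    f_k: np.ndarray = field(init=False)  # RMS distance from each axis (mm)

    def __post_init__(self) -> None:
        if len(self.fiducials) < 3:
            raise ValidationError("fiducial configuration needs >= 3 markers")
        pts = self.fiducials.points
        self.centroid = pts.mean(axis=0)
        dm = pts - self.centroid
        # principal axes = eigenvectors of the scatter; right-handed basis
        cov = dm.T @ dm / len(pts)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        if np.linalg.det(evecs) < 0:
            evecs[:, 2] *= -1
        self.principal_axes = evecs
        # f_k^2 = mean squared distance from axis k = sum of the other two
        # per-axis second moments
        second_moments = np.clip(evals, 0.0, None)
        self.f_k = np.sqrt(second_moments.sum() - second_moments)

    @property
    def n(self) -> int:
        return len(self.fiducials)

    def axis_distances(self, target: Iterable[float]) -> np.ndarray:
        """Distances d_k of a target from the three principal axes."""
        local = self.principal_axes.T @ (as_vector3(target) - self.centroid)
        sq = local**2
        return np.sqrt(sq.sum() - sq)

    def to_local(self, target: Iterable[float]) -> Vector3:
        return self.principal_axes.T @ (as_vector3(target) - self.centroid)


@dataclass(frozen=True)
class TREPrediction:
    target: Vector3
    tre_rms: float
    d_k: np.ndarray
    covariance: np.ndarray | None = None


def predict_tre_rms(
    config: FiducialConfiguration, target: Iterable[float], fle: FLEModel
) -> TREPrediction:
    """Closed-form first-order RMS TRE prediction for isotropic FLE.

    Requires isotropic FLE (use the covariance path otherwise) and a
    non-collinear configuration whenever the target is off the collinear
    axis.
    """
    if not fle.isotropic:
        raise ValidationError("closed-form TRE prediction requires isotropic FLE")
    target = as_vector3(target, name="target")
    d = config.axis_distances(target)
    f = config.f_k
    scale = float(np.max(f)) or 1.0
    terms = np.zeros(3)
    for k in range(3):
        if f[k] <= _DEGENERACY_TOL * scale:
            if d[k] > 1e-6:
                raise DegenerateGeometryError(
                    "collinear fiducial configuration cannot constrain the target"
                )
            continue  # target on the degenerate axis: rotation there is moot
        terms[k] = d[k] ** 2 / f[k] ** 2
    tre2 = (fle.total_rms**2 / config.n) * (1.0 + terms.sum() / 3.0)
    return TREPrediction(target=target, tre_rms=float(np.sqrt(tre2)), d_k=d)


def predict_tre_covariance(
    config: FiducialConfiguration, target: Iterable[float], fle: FLEModel
) -> np.ndarray:
    """First-order 3x3 TRE covariance at the target (world frame, mm^2).

    Propagates fiducial noise through the least-squares rigid fit: the
    translation error contributes sigma^2/N * I and the rotation error
    contributes [r]_x Cov(dtheta) [r]_x^T with Cov(dtheta) = sigma^2 A^{-1},
    A = diag(N f_k^2) in the principal frame. For isotropic FLE the trace
    equals predict_tre_rms**2.
    """
    target = as_vector3(target, name="target")
    if fle.covariance is not None and not fle.isotropic:
        # anisotropic per-axis variances expressed in the principal frame
        sigma2_axes = np.diag(
            config.principal_axes.T @ fle.covariance @ config.principal_axes
        )
    else:
        sigma2_axes = np.full(3, fle.total_rms**2 / 3.0)

    r_local = config.to_local(target)
    f2 = config.f_k**2
    n = config.n
    scale = float(np.max(f2)) or 1.0
    d = config.axis_distances(target)
    if np.any((f2 <= _DEGENERACY_TOL * scale) & (d > 1e-6)):
        raise DegenerateGeometryError(
            "collinear fiducial configuration cannot constrain the target"
        )

    # Small-rotation covariance about each principal axis. For axis k the
    # restoring moment comes from the fiducial spread about that axis
    # (N * f_k^2) driven by noise transverse to it.
    sigma2_iso = sigma2_axes.mean()  # exact only for isotropic noise
    with np.errstate(divide="ignore"):
        dtheta_var = np.where(f2 > _DEGENERACY_TOL * scale, sigma2_iso / (n * f2), 0.0)
    rx = np.array(
        [
            [0.0, -r_local[2], r_local[1]],
            [r_local[2], 0.0, -r_local[0]],
            [-r_local[1], r_local[0], 0.0],
        ]
    )
    cov_local = np.diag(sigma2_axes) / n + rx @ np.diag(dtheta_var) @ rx.T
    V = config.principal_axes
    return V @ cov_local @ V.T


@dataclass(frozen=True)
class ConfidenceEllipse:
    """A chi-square confidence ellipse of a 2D Gaussian (mm)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]  # (a, b), a >= b
    orientation: float  # radians, direction of the major axis
    level: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorised membership test for (N, 2) points."""
        pts = np.asarray(points, dtype=float) - np.asarray(self.center)
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        u = pts @ np.array([c, s])
        v = pts @ np.array([-s, c])
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def confidence_ellipse(
    cov2d: np.ndarray, level: float = 0.95, center: Sequence[float] = (0.0, 0.0)
) -> ConfidenceEllipse:
    """Chi-square confidence ellipse of a 2x2 covariance.

    Semi-axes are sqrt(chi2_2(level) * lambda_i) along the eigenvectors;
    chi2_2(0.95) = 5.99146...
    """
    C = np.asarray(cov2d, dtype=float)
    if C.shape != (2, 2) or not np.allclose(C, C.T, atol=1e-9):
        raise ValidationError("covariance must be symmetric 2x2")
    if not 0.0 < level < 1.0:
        raise ValidationError("confidence level must lie in (0, 1)")
    evals, evecs = np.linalg.eigh(C)
    if evals[0] < -1e-12 * max(abs(evals[1]), 1.0):
        raise ValidationError("covariance must be positive semidefinite")
    evals = np.clip(evals, 0.0, None)
    k = stats.chi2.ppf(level, df=2)
    a = float(np.sqrt(k * evals[1]))
    b = float(np.sqrt(k * evals[0]))
    major = evecs[:, 1]
    return ConfidenceEllipse(
        center=(float(center[0]), float(center[1])),
        semi_axes=(a, b),
        orientation=float(np.arctan2(major[1], major[0])),
        level=float(level),
    )


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

def fit_rigid_batch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised least-squares rigid fits.

    moving, fixed: (reps, N, 3). Returns rotations (reps, 3, 3) and
    translations (reps, 3) mapping each moving cloud onto its fixed cloud.
    """
    mc = moving.mean(axis=1, keepdims=True)
    fc = fixed.mean(axis=1, keepdims=True)
    H = np.einsum("rni,rnj->rij", moving - mc, fixed - fc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("rji,rkj->rik", Vt, U)))
    D = np.repeat(np.eye(3)[None], len(H), axis=0)
    D[:, 2, 2] = d
    R = np.einsum("rji,rjk,rlk->ril", Vt, D, U)
    t = fc[:, 0, :] - np.einsum("rij,rj->ri", R, mc[:, 0, :])
    return R, t


def monte_carlo_tre(
    config: FiducialConfiguration,
    target: Iterable[float],
    fle: FLEModel,
    reps: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Empirical TRE samples: perturb both point sets, refit, measure.

    The total FLE is split evenly across the two spaces (per-set RMS =
    total/sqrt(2), isotropic per-axis sigma = per-set RMS / sqrt(3)) so the
    combined localization error across a correspondence equals the model's
    total. Returns the (reps, 3) displacement vectors at the target; their
    RMS norm estimates the TRE.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target = as_vector3(target, name="target")
    pts = config.fiducials.points
    n = config.n
    sigma = fle.total_rms / np.sqrt(2.0) / np.sqrt(3.0)  # per-axis, per-set

    if fle.total_rms == 0.0:
        return np.zeros((reps, 3))

    moving = pts[None] + rng.normal(0.0, sigma, size=(reps, n, 3))
    fixed = pts[None] + rng.normal(0.0, sigma, size=(reps, n, 3))
    R, t = fit_rigid_batch(moving, fixed)
    mapped = np.einsum("rij,j->ri", R, target) + t
    return mapped - target[None]


def tre_rms_from_samples(samples: np.ndarray) -> float:
    """RMS of the displacement norms of Monte-Carlo TRE samples."""
    return float(np.sqrt(np.mean(np.sum(np.asarray(samples) ** 2, axis=1))))


__all__.append("tre_rms_from_samples")
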