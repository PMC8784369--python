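"""Paired-point rigid registration of tracked sensor positions to fiducial centroids.

The core fit is the closed-form least-squares rigid alignment (centroid
demeaning followed by SVD of the cross-covariance, with the standard
determinant-sign correction so a reflection is never returned). Unknown
label correspondence is resolved by exhaustive permutation search, which is
exact for the small fiducial counts used in nasopharyngeal registration
(N <= 8).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core_geometry import (
    DegenerateGeometryError,
    LabeledPointSet,
    RigidTransform,
    ValidationError,
)

__all__ = [
    "AmbiguousCorrespondenceError",
    "Correspondence",
    "RegistrationResult",
    "fit_rigid_arrays",
    "fit_rigid",
    "match_correspondence",
]

#: Below this FRE gap (mm) between the best and second-best permutation the
#: pairing is declared ambiguous (symmetric configuration).
DEFAULT_AMBIGUITY_MARGIN_MM = 0.1

_COLLINEARITY_TOL = 1e-8


class AmbiguousCorrespondenceError(ValidationError):
    """Best and runner-up label pairings are indistinguishable by FRE."""


@dataclass(frozen=True)
class Correspondence:
    """A bijective pairing of moving-set labels onto fixed-set labels."""

    mapping: dict[str, str]  # moving label -> fixed label
    residual_rms: float | None = None  # mm, FRE of the winning pairing

    def __post_init__(self) -> None:
        if len(set(self.mapping.values())) != len(self.mapping):
            raise ValidationError("correspondence mapping is not a bijection")
        if len(self.mapping) < 3:
            raise ValidationError("correspondence needs at least 3 pairs")


@dataclass(frozen=True)
class RegistrationResult:
    """Fitted rigid transform with its fiducial registration error.

    ``fre_rms`` is the root-mean-square residual over fiducials, matching the
    <FRE^2> expectation convention; ``fre_rms**2`` equals the mean of the
    squared per-fiducial residuals.
    """

    transform: RigidTransform
    fre_rms: float
    per_fiducial_residuals: list[tuple[str, float]]


def fit_rigid_arrays(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping `moving` onto `fixed`.

    Arrays are (N, 3), row i of each corresponding. Raises
    DegenerateGeometryError for <3 points or a collinear configuration.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValidationError("point arrays must both be (N, 3)")
    n = moving.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >=3 corresponding pairs, got {n}")

    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    dm = moving - mc
    df = fixed - fc

    # Collinearity: rank of the demeaned moving cloud must be >= 2.
    sv = np.linalg.svd(dm, compute_uv=False)
    scale = sv[0] if sv[0] > 0 else 1.0
    if sv[1] <= _COLLINEARITY_TOL * scale:
        raise DegenerateGeometryError("fiducial configuration is collinear")

    H = dm.T @ df
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])  # flip smallest singular direction if reflected
    R = Vt.T @ D @ U.T
    t = fc - R @ mc
    return RigidTransform(R, t)


def _fre(moving: np.ndarray, fixed: np.ndarray, T: RigidTransform) -> tuple[np.ndarray, float]:
    resid = np.linalg.norm(T.apply_many(moving) - fixed, axis=1)
    return resid, float(np.sqrt(np.mean(resid**2)))


def fit_rigid(
    moving: LabeledPointSet,
    fixed: LabeledPointSet,
    mapping: Correspondence | None = None,
) -> RegistrationResult:
    """Fit the rigid transform pairing moving points with fixed points.

    With ``mapping=None``, points are paired by shared labels. The returned
    FRE is the RMS residual over the fitted pairs.
    """
    if mapping is None:
        shared = [l for l in moving.labels if l in fixed.labels]
        pairs = {l: l for l in shared}
    else:
        pairs = mapping.mapping
    if len(pairs) < 3:
        raise DegenerateGeometryError(
            f"need >=3 corresponding pairs, got {len(pairs)}"
        )
    mov_labels = [l for l in moving.labels if l in pairs]
    mov = np.stack([moving[l] for l in mov_labels])
    fix = np.stack([fixed[pairs[l]] for l in mov_labels])

    T = fit_rigid_arrays(mov, fix)
    resid, fre = _fre(mov, fix, T)
    return RegistrationResult(
        transform=T,
        fre_rms=fre,
        per_fiducial_residuals=list(zip(mov_labels, resid.tolist())),
    )


def match_correspondence(
    image_fids: LabeledPointSet,
    patient_fids: LabeledPointSet,
    ambiguity_margin: float = DEFAULT_AMBIGUITY_MARGIN_MM,
) -> Correspondence:
    """Find the label pairing of patient sensors onto image fiducials.

    Exhaustively evaluates every permutation (exact for N <= 8, at most
    40320 closed-form fits) and returns the pairing with minimal FRE.
    Raises AmbiguousCorrespondenceError when the winner beats the runner-up
    by less than `ambiguity_margin` mm of FRE, which signals a symmetric
    fiducial configuration that cannot be paired reliably.
    """
    n_img, n_pat = len(image_fids), len(patient_fids)
    n = min(n_img, n_pat)
    if n < 3:
        raise DegenerateGeometryError("correspondence search needs >=3 points per side")
    if max(n_img, n_pat) > 8:
        raise ValidationError("exhaustive correspondence search supports at most 8 points")

    # Moving = patient sensors. When the sets differ in size, every ordered
    # choice of n points from the larger side is tried; the pairing is a
    # bijection over min(N_image, N_patient) points.
    results: list[tuple[float, tuple[tuple[str, str], ...]]] = []
    if n_pat <= n_img:
        pat_subsets = [tuple(range(n_pat))]
        img_orderings = itertools.permutations(range(n_img), n_pat)
        candidates = ((p, i) for i in img_orderings for p in pat_subsets)
    else:
        img_fixed = tuple(range(n_img))
        candidates = (
            (p, img_fixed) for p in itertools.permutations(range(n_pat), n_img)
        )
    for pat_idx, img_idx in candidates:
        mov_pts = patient_fids.points[list(pat_idx)]
        fixed_pts = image_fids.points[list(img_idx)]
        try:
            T = fit_rigid_arrays(mov_pts, fixed_pts)
        except DegenerateGeometryError:
            continue
        _, fre = _fre(mov_pts, fixed_pts, T)
        pairing = tuple(
            (patient_fids.labels[p], image_fids.labels[i])
            for p, i in zip(pat_idx, img_idx)
        )
        results.append((fre, pairing))

    if not results:
        raise DegenerateGeometryError("no non-degenerate pairing exists")
    results.sort(key=lambda r: r[0])
    best_fre, best_pairing = results[0]
    if len(results) > 1 and results[1][0] - best_fre < ambiguity_margin:
        raise AmbiguousCorrespondenceError(
            f"best ({best_fre:.4f} mm) and second-best ({results[1][0]:.4f} mm) "
            f"pairings differ by less than {ambiguity_margin} mm FRE"
        )
    return Correspondence(mapping=dict(best_pairing), residual_rms=best_fre)
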