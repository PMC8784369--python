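"""Postoperative placement-error decomposition and summary statistics.

The achieved-vs-planned electrode displacement is reported three ways: the
Euclidean distance, the lateral error (2D distance within the plane of the
electrode surface), and the depth error (1D distance along the plane
normal). Summaries are mean +/- sample standard deviation (n-1
denominator). Registration accuracy at bone-implanted check screws is
quantified as the mean distance between the mapped probe touches and the
screw's image-space position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_geometry import (
    LabeledPointSet,
    RigidTransform,
    ValidationError,
    Vector3,
    as_vector3,
)

__all__ = [
    "PlacementError",
    "SummaryStat",
    "placement_error",
    "summarize",
    "screw_tre",
    "round_half_away",
]


@dataclass(frozen=True)
class PlacementError:
    """Euclidean / lateral / depth decomposition of a placement displacement."""

    components: Vector3  # achieved - planned, mm, CT frame
    euclidean: float
    lateral: float
    depth: float
    plane_normal: Vector3


@dataclass(frozen=True)
class SummaryStat:
    mean: float
    sample_std: float  # nan when n < 2
    n: int


def placement_error(
    planned: Iterable[float],
    achieved: Iterable[float],
    plane_normal: Iterable[float],
) -> PlacementError:
    """Decompose achieved-vs-planned displacement about the electrode plane.

    ``plane_normal`` must be unit length: depth is the absolute component
    along it, lateral the norm of the in-plane remainder, so
    lateral^2 + depth^2 = euclidean^2 exactly.
    """
    planned = as_vector3(planned, name="planned")
    achieved = as_vector3(achieved, name="achieved")
    n_hat = as_vector3(plane_normal, name="plane_normal")
    if abs(np.linalg.norm(n_hat) - 1.0) > 1e-9:
        raise ValidationError("plane normal must be unit length")
    delta = achieved - planned
    depth = float(abs(delta @ n_hat))
    lateral_vec = delta - (delta @ n_hat) * n_hat
    return PlacementError(
        components=delta,
        euclidean=float(np.linalg.norm(delta)),
        lateral=float(np.linalg.norm(lateral_vec)),
        depth=depth,
        plane_normal=n_hat,
    )


def summarize(values: Sequence[float]) -> SummaryStat:
    """Arithmetic mean and sample standard deviation (n-1 denominator).

    Missing entries must be excluded by the caller before the call.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty list")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("summarize received non-finite values")
    return SummaryStat(
        mean=float(arr.mean()),
        sample_std=float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
        n=int(arr.size),
    )


def screw_tre(
    probe_touches: Mapping[str, np.ndarray],
    image_screws: LabeledPointSet,
    transform: RigidTransform,
) -> tuple[dict[str, float], SummaryStat]:
    """Measured TRE at check screws touched with a calibrated pointer.

    ``probe_touches`` maps each screw label to one or more patient-space
    touch positions (K, 3). Each touch is mapped through the registration
    transform and compared with the screw's image-space position; the
    screw's TRE is the mean over its touch distances, and the summary is
    taken over screws.
    """
    per_screw: dict[str, float] = {}
    for label, touches in probe_touches.items():
        if label not in image_screws.labels:
            raise ValidationError(f"screw {label!r} missing from the image point set")
        touches = np.asarray(touches, dtype=float).reshape(-1, 3)
        if len(touches) < 1:
            raise ValidationError(f"screw {label!r} has no touches")
        mapped = transform.apply_many(touches)
        dists = np.linalg.norm(mapped - image_screws[label], axis=1)
        per_screw[label] = float(dists.mean())
    if not per_screw:
        raise ValidationError("no screws provided")
    return per_screw, summarize(list(per_screw.values()))


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (report convention; raw doubles kept in JSON).

    Decimal-based so printed halves like 2.565 round up despite binary
    floating point.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
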