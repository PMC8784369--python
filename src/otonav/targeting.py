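"""Targeting-cue geometry for the in-ocular visual display.

The instrument defines a local frame: the z-axis runs longitudinally along
the tool toward the tip ("depth", in/out), and the x-y plane perpendicular
to it carries "lateral" motion. The tip-to-target displacement is
decomposed in this frame and turned into the per-frame cue state shown to
the surgeon:

* in range — a blob offset proportional to the lateral displacement, and a
  circle whose diameter is proportional to |depth|; the circle vanishes at
  zero depth and blinks when the tip has overreached the target
  (depth < 0).
* out of range (lateral distance beyond the configured radius) — the blob
  is replaced by an arrow pointing toward the target and the depth circle
  is drawn at a constant diameter.

All cues are emitted as geometry (pixels, radians, flags), never rasterized,
so the module stays display-agnostic and testable. A dwell-capture
operation stores a target once the tip has remained within a small radius
for a minimum duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_geometry import ValidationError, Vector3, as_vector3

__all__ = [
    "InstrumentPose",
    "Displacement",
    "DisplayParams",
    "CueState",
    "CapturedTarget",
    "NavigationSummary",
    "decompose_displacement",
    "cue_state",
    "dwell_capture",
    "replay_navigation",
]


@dataclass(frozen=True)
class InstrumentPose:
    """Tip position plus a right-handed orthonormal instrument triad.

    ``axes`` columns are (x_hat, y_hat, z_hat); z_hat points tip-forward.
    """

    tip: Vector3
    axes: np.ndarray  # 3x3, columns = x_hat, y_hat, z_hat

    def __post_init__(self) -> None:
        object.__setattr__(self, "tip", as_vector3(self.tip, name="tip"))
        A = np.asarray(self.axes, dtype=float)
        if A.shape != (3, 3) or not np.allclose(A.T @ A, np.eye(3), atol=1e-9):
            raise ValidationError("instrument axes must form an orthonormal triad")
        if np.linalg.det(A) < 0:
            raise ValidationError("instrument triad must be right-handed")
        object.__setattr__(self, "axes", A)

    @property
    def z_hat(self) -> Vector3:
        return self.axes[:, 2]


@dataclass(frozen=True)
class Displacement:
    """Tip-to-target displacement in instrument coordinates.

    ``depth`` is signed: positive when the target lies ahead of the tip
    along +z (tool must advance), negative when the tip has overreached.
    """

    lateral: tuple[float, float]  # mm, instrument x-y
    depth: float  # mm, signed

    @property
    def lateral_norm(self) -> float:
        return float(np.hypot(*self.lateral))

    @property
    def euclidean(self) -> float:
        return float(np.sqrt(self.lateral_norm**2 + self.depth**2))


@dataclass(frozen=True)
class DisplayParams:
    """Display scaling chosen to the surgeon's preference."""

    lateral_scale: float = 20.0  # px per mm
    depth_scale: float = 20.0  # px per mm of |depth| -> circle diameter
    in_range_radius: float = 10.0  # mm of lateral distance
    zero_tolerance: float = 0.05  # mm; below this the depth circle vanishes
    out_of_range_circle_diameter: float = 120.0  # px, constant

    def __post_init__(self) -> None:
        for name in (
            "lateral_scale",
            "depth_scale",
            "in_range_radius",
            "zero_tolerance",
            "out_of_range_circle_diameter",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"display parameter {name} must be positive")


@dataclass(frozen=True)
class CueState:
    """The complete visual-display state for one frame."""

    mode: str  # "in_range" | "out_of_range"
    blob_offset_px: tuple[float, float] | None
    circle_diameter_px: float
    circle_visible: bool
    blink: bool
    arrow_direction: float | None  # radians, only out_of_range

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "blob_offset_px": list(self.blob_offset_px)
            if self.blob_offset_px is not None
            else None,
            "circle_diameter_px": self.circle_diameter_px,
            "circle_visible": self.circle_visible,
            "blink": self.blink,
            "arrow_direction": self.arrow_direction,
        }


def decompose_displacement(pose: InstrumentPose, target: Iterable[float]) -> Displacement:
    """Project the tip-to-target vector onto the instrument frame."""
    delta = as_vector3(target, name="target") - pose.tip
    local = pose.axes.T @ delta
    return Displacement(lateral=(float(local[0]), float(local[1])), depth=float(local[2]))


def cue_state(d: Displacement, params: DisplayParams = DisplayParams()) -> CueState:
    """Derive the per-frame cue geometry from a displacement.

    Pure function: identical inputs give identical outputs. The range
    boundary is a strict inequality (ties count as in range), so the
    contract is deterministic with no hysteresis.
    """
    out_of_range = d.lateral_norm > params.in_range_radius
    circle_visible = abs(d.depth) > params.zero_tolerance
    blink = d.depth < -params.zero_tolerance
    if out_of_range:
        return CueState(
            mode="out_of_range",
            blob_offset_px=None,
            circle_diameter_px=params.out_of_range_circle_diameter,
            circle_visible=circle_visible,
            blink=blink,
            arrow_direction=float(np.arctan2(d.lateral[1], d.lateral[0])),
        )
    return CueState(
        mode="in_range",
        blob_offset_px=(
            params.lateral_scale * d.lateral[0],
            params.lateral_scale * d.lateral[1],
        ),
        circle_diameter_px=params.depth_scale * abs(d.depth) if circle_visible else 0.0,
        circle_visible=circle_visible,
        blink=blink,
        arrow_direction=None,
    )


@dataclass(frozen=True)
class CapturedTarget:
    """A target stored by holding the instrument still (dwell)."""

    position: Vector3
    dwell_start: float
    dwell_end: float
    spread: float  # max distance of window samples from the window mean, mm


def dwell_capture(
    times: Sequence[float],
    positions: np.ndarray,
    stability_radius: float = 1.0,
    dwell_time: float = 2.0,
) -> CapturedTarget | None:
    """Store the first position held stable for at least ``dwell_time``.

    Scans windows in time order; a window qualifies when it spans at least
    ``dwell_time`` seconds and every sample lies within
    ``stability_radius`` of the window mean (two-pass check: mean first,
    then membership). Returns the earliest qualifying window's mean, or
    None if the stream never settles.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    if len(times) != len(positions):
        raise ValidationError("times and positions must have the same length")
    if np.any(np.diff(times) < 0):
        raise ValidationError("stream must be sorted by time")

    n = len(times)
    end = 0
    for start in range(n):
        if end <= start:
            end = start + 1
        while end < n and times[end - 1] - times[start] < dwell_time:
            end += 1
        if times[end - 1] - times[start] < dwell_time:
            return None  # remaining stream too short
        window = positions[start:end]
        mean = window.mean(axis=0)
        dists = np.linalg.norm(window - mean, axis=1)
        if np.all(dists <= stability_radius):
            return CapturedTarget(
                position=mean,
                dwell_start=float(times[start]),
                dwell_end=float(times[end - 1]),
                spread=float(dists.max()),
            )
    return None


@dataclass(frozen=True)
class NavigationSummary:
    final_distance_mm: float
    path_length_cm: float
    duration_s: float


def replay_navigation(
    times: Sequence[float],
    poses: Sequence[InstrumentPose],
    target: Iterable[float],
    params: DisplayParams = DisplayParams(),
) -> tuple[list[CueState], NavigationSummary]:
    """Replay a recorded approach: per-frame cues plus trajectory summary.

    The path length is the sum of consecutive tip distances (reported in
    cm, matching how navigation trajectories are usually quoted); the final
    distance is the Euclidean tip-to-target distance at the last frame.
    """
    if len(poses) == 0:
        raise ValidationError("pose stream is empty")
    if len(times) != len(poses):
        raise ValidationError("times and poses must have the same length")
    target = as_vector3(target, name="target")

    cues = [cue_state(decompose_displacement(p, target), params) for p in poses]
    tips = np.stack([p.tip for p in poses])
    path_mm = float(np.sum(np.linalg.norm(np.diff(tips, axis=0), axis=1))) if len(tips) > 1 else 0.0
    summary = NavigationSummary(
        final_distance_mm=float(np.linalg.norm(tips[-1] - target)),
        path_length_cm=path_mm / 10.0,
        duration_s=float(times[-1] - times[0]),
    )
    return cues, summary
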