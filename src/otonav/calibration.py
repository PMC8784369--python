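"""Pivot calibration of a tracked instrument tip.

While the instrument pivots about a stationary physical point, each tracked
pose (R_i, p_i) satisfies R_i t_tip + p_i = p_pivot for the fixed tip
offset t_tip (sensor frame) and the fixed pivot point p_pivot (tracker
frame). Stacking all poses gives an overdetermined linear system in six
unknowns which is solved in one shot by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_geometry import (
    DegenerateGeometryError,
    ValidationError,
    Vector3,
    quaternion_to_matrix,
)

__all__ = ["PoseSample", "PivotResult", "pivot_calibrate", "read_pose_stream"]

#: Condition-number ceiling of the stacked design matrix; above it the pose
#: set does not constrain all six unknowns (e.g. rotation about one axis only).
MAX_CONDITION_NUMBER = 1e6


@dataclass(frozen=True)
class PoseSample:
    """One tracked pose: timestamp (s), proper rotation, sensor position (mm)."""

    timestamp: float
    rotation: np.ndarray
    sensor_position: Vector3

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValidationError("pose rotation must be orthonormal 3x3")
        if np.linalg.det(R) < 0:
            raise ValidationError("pose rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(
            self, "sensor_position", np.asarray(self.sensor_position, dtype=float)
        )


@dataclass(frozen=True)
class PivotResult:
    tip_offset: Vector3  # sensor frame, mm
    pivot_point: Vector3  # tracker frame, mm
    residual_rms: float  # mm


def pivot_calibrate(samples: list[PoseSample]) -> PivotResult:
    """Estimate the tip offset and pivot point from pivoting poses.

    Solves min || [R_i  -I] [t_tip; p_pivot] + p_i ||^2 over all samples.
    Raises DegenerateGeometryError when the rotations are not diverse
    enough to constrain all six unknowns, naming the unconstrained
    direction.
    """
    if len(samples) < 3:
        raise DegenerateGeometryError("pivot calibration needs >= 3 poses")

    n = len(samples)
    A = np.zeros((3 * n, 6))
    b = np.zeros(3 * n)
    for i, s in enumerate(samples):
        A[3 * i : 3 * i + 3, :3] = s.rotation
        A[3 * i : 3 * i + 3, 3:] = -np.eye(3)
        b[3 * i : 3 * i + 3] = -s.sensor_position

    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] <= 0 or sv[0] / sv[-1] > MAX_CONDITION_NUMBER:
        # identify which direction of the 6-vector is unconstrained
        _, _, Vt = np.linalg.svd(A)
        null = Vt[-1]
        axis = int(np.argmax(np.abs(null[:3])))
        raise DegenerateGeometryError(
            "pose rotations are too uniform: tip-offset component "
            f"{'xyz'[axis]} is unconstrained (condition number "
            f"{sv[0] / max(sv[-1], 1e-300):.2e})"
        )

    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = A @ x - b
    rms = float(np.sqrt(np.mean(np.sum(resid.reshape(-1, 3) ** 2, axis=1))))
    return PivotResult(tip_offset=x[:3], pivot_point=x[3:], residual_rms=rms)


def read_pose_stream(path: str | Path) -> list[PoseSample]:
    """Read a pose-stream CSV with header `t,qw,qx,qy,qz,x,y,z`."""
    df = pd.read_csv(path)
    required = ["t", "qw", "qx", "qy", "qz", "x", "y", "z"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValidationError(f"pose-stream CSV missing columns: {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        samples.append(
            PoseSample(
                timestamp=float(row.t),
                rotation=quaternion_to_matrix(row.qw, row.qx, row.qy, row.qz),
                sensor_position=np.array([row.x, row.y, row.z], dtype=float),
            )
        )
    return samples
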