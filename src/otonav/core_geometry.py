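"""Foundational 3D geometry: vectors, rigid transforms, labeled point sets.

All world coordinates are in millimetres, right-handed, LPS orientation.
Rotations are stored as proper orthonormal 3x3 matrices; quaternions are
accepted at I/O boundaries (tracking streams) and normalised on conversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeometryError",
    "DegenerateGeometryError",
    "ValidationError",
    "Vector3",
    "RigidTransform",
    "LabeledPointSet",
    "as_vector3",
    "quaternion_to_matrix",
]

ORTHONORMALITY_TOL = 1e-9


class GeometryError(ValueError):
    """Base class for geometric validation failures."""


class ValidationError(GeometryError):
    """An input violates a type invariant (non-finite, non-orthonormal, ...)."""


class DegenerateGeometryError(GeometryError):
    """A configuration is too degenerate for the requested operation."""


Vector3 = np.ndarray  # shape (3,), float64, mm


def as_vector3(value: Iterable[float], *, name: str = "vector") -> Vector3:
    """Coerce to a finite float64 vector of length 3."""
    v = np.asarray(value, dtype=float)
    if v.shape != (3,):
        raise ValidationError(f"{name} must have exactly 3 components, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"{name} has non-finite components: {v}")
    return v


def _check_rotation(rotation: np.ndarray, tol: float = ORTHONORMALITY_TOL) -> np.ndarray:
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3):
        raise ValidationError(f"rotation must be 3x3, got {R.shape}")
    if not np.all(np.isfinite(R)):
        raise ValidationError("rotation has non-finite entries")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ValidationError("rotation is not orthonormal within tolerance")
    if np.linalg.det(R) < 0:
        raise ValidationError("rotation has negative determinant (reflection)")
    return R


def quaternion_to_matrix(qw: float, qx: float, qy: float, qz: float) -> np.ndarray:
    """Unit-normalise a (w, x, y, z) quaternion and return its rotation matrix."""
    q = np.array([qw, qx, qy, qz], dtype=float)
    n = np.linalg.norm(q)
    if n == 0 or not np.isfinite(n):
        raise ValidationError("quaternion has zero or non-finite norm")
    w, x, y, z = q / n
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p -> R p + t mapping one frame into another.

    Used for the patient-to-image registration transform and for general
    frame changes. The rotation is validated to be orthonormal with
    determinant +1 — anatomy is never mirrored.
    """

    rotation: np.ndarray
    translation: Vector3

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        object.__setattr__(
            self, "translation", as_vector3(self.translation, name="translation")
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, p: Iterable[float]) -> Vector3:
        """Map a point (mm) through the transform."""
        return self.rotation @ as_vector3(p, name="point") + self.translation

    def apply_many(self, pts: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of points."""
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first, then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    # -- serialisation ----------------------------------------------------

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"homogeneous matrix must be 4x4, got {m.shape}")
        return cls(m[:3, :3], m[:3, 3])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"matrix": self.to_matrix().tolist()}, indent=2) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        data = json.loads(Path(path).read_text())
        return cls.from_matrix(np.asarray(data["matrix"], dtype=float))


def apply_transform(T: RigidTransform, p: Iterable[float]) -> Vector3:
    """Functional alias for :meth:`RigidTransform.apply`."""
    return T.apply(p)


def compose(T1: RigidTransform, T2: RigidTransform) -> RigidTransform:
    """Functional alias: apply T2 first, then T1."""
    return T1.compose(T2)


def invert(T: RigidTransform) -> RigidTransform:
    return T.invert()


@dataclass
class LabeledPointSet:
    """Ordered, uniquely labeled 3D points in a named coordinate frame.

    Holds fiducial centroids (image space), tracked sensor positions
    (patient space), screw check-points, and similar point clouds.
    """

    labels: list[str]
    points: np.ndarray  # (N, 3) mm
    frame: str = "unknown"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != len(self.points):
            raise ValidationError(
                f"{len(self.labels)} labels for {len(self.points)} points"
            )
        if len(self.labels) == 0:
            raise ValidationError("point set must contain at least one point")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("labels must be unique")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("point set contains non-finite positions")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> Vector3:
        try:
            return self.points[self.labels.index(label)]
        except ValueError:
            raise KeyError(label) from None

    @property
    def centroid(self) -> Vector3:
        return self.points.mean(axis=0)

    def reordered(self, labels: Sequence[str]) -> "LabeledPointSet":
        """Return a copy with points listed in the given label order."""
        idx = [self.labels.index(l) for l in labels]
        return LabeledPointSet(list(labels), self.points[idx], frame=self.frame)

    def transformed(self, T: RigidTransform, frame: str | None = None) -> "LabeledPointSet":
        return LabeledPointSet(
            list(self.labels), T.apply_many(self.points), frame=frame or self.frame
        )

    # -- CSV I/O: header `label,x,y,z`, mm --------------------------------

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "label": self.labels,
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "z": self.points[:, 2],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, frame: str = "unknown") -> "LabeledPointSet":
        df = pd.read_csv(path)
        missing = {"label", "x", "y", "z"} - set(df.columns)
        if missing:
            raise ValidationError(f"point-set CSV missing columns: {sorted(missing)}")
        return cls(
            [str(l) for l in df["label"]],
            df[["x", "y", "z"]].to_numpy(dtype=float),
            frame=frame,
        )
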