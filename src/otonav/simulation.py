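"""Synthetic surgical-session generator.

Emulates the statistical structure the navigation system assumes: a
compact nasopharyngeal cluster of four spherical fiducials, a surgical
target (foramen of Luschka / cochlear nucleus region) tens of millimetres
away, skull-implanted check screws, independent isotropic localization
noise in image space (CT fiducial detection) and patient space
(electromagnetic tracking), and simple instrument trajectories. Every
artifact is deterministic for a given seed, so all other modules can be
exercised end-to-end with no external data.

Defaults follow the modelled system: 4 fiducials in a ~25 mm cluster,
target 70 mm from the cluster centroid, 8 screws, image-space FLE
0.1 mm RMS and tracking FLE 0.7 mm RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core_geometry import LabeledPointSet, RigidTransform, ValidationError
from .targeting import InstrumentPose

__all__ = ["SessionSpec", "SyntheticSession", "simulate_session", "write_session"]


@dataclass(frozen=True)
class SessionSpec:
    """Parameters of a synthetic navigation session (lengths in mm)."""

    n_fiducials: int = 4
    cluster_extent: float = 25.0  # diameter of the fiducial cluster
    target_offset: float = 70.0  # distance of the target from the cluster centroid
    n_screws: int = 8
    screw_distance_range: tuple[float, float] = (40.0, 90.0)
    touches_per_screw: int = 3
    fle_image: float = 0.1  # RMS, image space
    fle_emt: float = 0.7  # RMS, patient (tracker) space
    trajectory: str = "straight"  # straight | dwell | excursion
    speed: float = 2.0  # mm/s tip speed along the approach
    sample_rate: float = 20.0  # Hz
    phantom_radius: float = 2.0  # fiducial sphere radius for the phantom volume
    phantom_spacing: tuple[float, float, float] = (0.43, 0.43, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fiducials < 3:
            raise ValidationError("session needs at least 3 fiducials")
        for name in ("cluster_extent", "target_offset", "speed", "sample_rate"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.fle_image < 0 or self.fle_emt < 0:
            raise ValidationError("FLE values must be non-negative")
        if self.target_offset <= self.cluster_extent / 2.0:
            raise ValidationError("target would fall inside the fiducial cluster")
        if self.trajectory not in ("straight", "dwell", "excursion"):
            raise ValidationError(f"unknown trajectory kind {self.trajectory!r}")


@dataclass
class SyntheticSession:
    """All ground-truth and observed artifacts of one synthetic session."""

    spec: SessionSpec
    ground_truth: RigidTransform  # patient -> image
    image_fids_true: LabeledPointSet
    image_fids: LabeledPointSet  # with image-space noise
    patient_fids_true: LabeledPointSet
    patient_fids: LabeledPointSet  # with tracking noise
    image_screws: LabeledPointSet
    patient_screws_true: LabeledPointSet
    probe_touches: dict[str, np.ndarray]  # patient space, noisy
    target: np.ndarray  # image space, mm
    pose_times: np.ndarray
    poses: list[InstrumentPose]  # image space
    phantom_params: dict


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _cluster_points(rng: np.random.Generator, n: int, extent: float) -> np.ndarray:
    """Well-spread points in a sphere of the given diameter.

    Rejection-sampled so no two markers sit closer than a third of the
    extent and the configuration is never near-collinear — mirroring a
    stent that spreads its markers through the nasopharynx.
    """
    radius = extent / 2.0
    for _ in range(1000):
        pts = rng.uniform(-radius, radius, size=(n, 3))
        pts = pts[np.linalg.norm(pts, axis=1) <= radius]
        if len(pts) < n:
            continue
        pts = pts[:n]
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        if np.min(d[np.triu_indices(n, 1)]) < extent / 3.0 / np.sqrt(n):
            continue
        sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if sv[1] < 0.05 * extent:
            continue
        return pts
    raise ValidationError("could not draw a well-spread fiducial cluster")


def _approach_tips(spec: SessionSpec, target: np.ndarray, approach: np.ndarray,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Tip positions over time for the requested trajectory kind."""
    dt = 1.0 / spec.sample_rate
    if spec.trajectory == "dwell":
        times = np.arange(0.0, 4.0 + dt / 2, dt)
        tips = target[None] + rng.normal(0.0, 0.2, size=(len(times), 3))
        return times, tips
    if spec.trajectory == "straight":
        start = target - 10.0 * approach
    else:  # excursion: start outside the lateral range, swing in
        lateral_dir = _random_unit(rng)
        lateral_dir -= (lateral_dir @ approach) * approach
        lateral_dir /= np.linalg.norm(lateral_dir)
        start = target - 10.0 * approach + 15.0 * lateral_dir
    duration = np.linalg.norm(target - start) / spec.speed
    n_frames = int(np.ceil(duration * spec.sample_rate)) + 1
    times = np.linspace(0.0, duration, n_frames)
    frac = times / duration
    tips = start[None] + frac[:, None] * (target - start)[None]
    return times, tips


def simulate_session(spec: SessionSpec) -> SyntheticSession:
    """Generate a full synthetic session; deterministic for spec.seed."""
    rng = np.random.default_rng(spec.seed)

    fid_labels = [f"F{i + 1}" for i in range(spec.n_fiducials)]
    cluster_center = rng.uniform(-20.0, 20.0, size=3)
    image_fid_pts = cluster_center + _cluster_points(
        rng, spec.n_fiducials, spec.cluster_extent
    )
    centroid = image_fid_pts.mean(axis=0)
    approach = _random_unit(rng)
    target = centroid + spec.target_offset * approach

    screw_labels = [f"T{i + 1}" for i in range(spec.n_screws)]
    lo, hi = spec.screw_distance_range
    screw_pts = np.stack(
        [centroid + rng.uniform(lo, hi) * _random_unit(rng) for _ in range(spec.n_screws)]
    ) if spec.n_screws else np.zeros((0, 3))

    # ground truth patient -> image transform; patient space is the tracker frame
    T = RigidTransform(_random_rotation(rng), rng.uniform(-200.0, 200.0, size=3))
    T_inv = T.invert()
    patient_fid_pts = T_inv.apply_many(image_fid_pts)
    patient_screw_pts = T_inv.apply_many(screw_pts) if spec.n_screws else screw_pts

    sigma_img = spec.fle_image / np.sqrt(3.0)
    sigma_emt = spec.fle_emt / np.sqrt(3.0)
    image_noisy = image_fid_pts + rng.normal(0.0, sigma_img, size=image_fid_pts.shape)
    patient_noisy = patient_fid_pts + rng.normal(0.0, sigma_emt, size=patient_fid_pts.shape)

    touches = {
        label: patient_screw_pts[i]
        + rng.normal(0.0, sigma_emt, size=(spec.touches_per_screw, 3))
        for i, label in enumerate(screw_labels)
    }

    times, tips = _approach_tips(spec, target, approach, rng)
    # instrument z-axis along the approach direction; x, y complete the triad
    z_hat = approach
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ z_hat) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x_hat = np.cross(ref, z_hat)
    x_hat /= np.linalg.norm(x_hat)
    y_hat = np.cross(z_hat, x_hat)
    axes = np.column_stack([x_hat, y_hat, z_hat])
    poses = [InstrumentPose(tip=t, axes=axes) for t in tips]

    phantom_params = {
        "centers": image_fid_pts,
        "radius": spec.phantom_radius,
        "spacing": spec.phantom_spacing,
        "noise_sigma": 0.0,
        "seed": spec.seed,
    }

    return SyntheticSession(
        spec=spec,
        ground_truth=T,
        image_fids_true=LabeledPointSet(fid_labels, image_fid_pts, frame="image"),
        image_fids=LabeledPointSet(fid_labels, image_noisy, frame="image"),
        patient_fids_true=LabeledPointSet(fid_labels, patient_fid_pts, frame="patient"),
        patient_fids=LabeledPointSet(fid_labels, patient_noisy, frame="patient"),
        image_screws=LabeledPointSet(screw_labels, screw_pts, frame="image")
        if spec.n_screws
        else None,
        patient_screws_true=LabeledPointSet(screw_labels, patient_screw_pts, frame="patient")
        if spec.n_screws
        else None,
        probe_touches=touches,
        target=target,
        pose_times=times,
        poses=poses,
        phantom_params=phantom_params,
    )


def write_session(session: SyntheticSession, outdir: str | Path) -> None:
    """Write every session artifact in the toolkit's standard file formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    session.image_fids.to_csv(out / "image_fids.csv")
    session.patient_fids.to_csv(out / "patient_fids.csv")
    session.image_fids_true.to_csv(out / "image_fids_true.csv")
    if session.image_screws is not None:
        session.image_screws.to_csv(out / "image_screws.csv")
        rows = []
        for label, pts in session.probe_touches.items():
            for p in np.atleast_2d(pts):
                rows.append({"label": label, "x": p[0], "y": p[1], "z": p[2]})
        pd.DataFrame(rows).to_csv(out / "probe_touches.csv", index=False)
    session.ground_truth.to_json(out / "ground_truth_transform.json")
    np.savetxt(out / "target.csv", session.target[None], delimiter=",",
               header="x,y,z", comments="")
    rows = []
    for t, pose in zip(session.pose_times, session.poses):
        q = Rotation.from_matrix(pose.axes).as_quat()  # x, y, z, w
        rows.append(
            {
                "t": t,
                "qw": q[3], "qx": q[0], "qy": q[1], "qz": q[2],
                "x": pose.tip[0], "y": pose.tip[1], "z": pose.tip[2],
            }
        )
    pd.DataFrame(rows).to_csv(out / "poses.csv", index=False)
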