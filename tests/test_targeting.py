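import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from otonav import (
    DisplayParams,
    Displacement,
    InstrumentPose,
    ValidationError,
    cue_state,
    decompose_displacement,
    dwell_capture,
    replay_navigation,
)
from conftest import random_rotation


def axis_aligned_pose(tip=(0.0, 0.0, 0.0)):
    return InstrumentPose(tip=np.asarray(tip, dtype=float), axes=np.eye(3))


class TestDecomposition:
    def test_target_at_tip_is_zero(self):
        d = decompose_displacement(axis_aligned_pose(), [0.0, 0.0, 0.0])
        assert d.lateral == (0.0, 0.0) and d.depth == 0.0

    def test_axis_aligned_example(self):
        d = decompose_displacement(axis_aligned_pose(), [3.0, 4.0, 5.0])
        assert d.lateral == pytest.approx((3.0, 4.0))
        assert d.depth == pytest.approx(5.0)
        assert d.lateral_norm == pytest.approx(5.0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_pythagorean_identity(self, seed):
        rng = np.random.default_rng(seed)
        pose = InstrumentPose(tip=rng.uniform(-100, 100, 3), axes=random_rotation(rng))
        target = rng.uniform(-100, 100, 3)
        d = decompose_displacement(pose, target)
        delta = np.linalg.norm(target - pose.tip)
        assert d.lateral_norm**2 + d.depth**2 == pytest.approx(delta**2, abs=1e-9)

    def test_joint_world_rotation_invariance(self, rng):
        pose = InstrumentPose(tip=rng.uniform(-50, 50, 3), axes=random_rotation(rng))
        target = rng.uniform(-50, 50, 3)
        base = decompose_displacement(pose, target)
        R = random_rotation(rng)
        rotated = InstrumentPose(tip=R @ pose.tip, axes=R @ pose.axes)
        moved = decompose_displacement(rotated, R @ target)
        assert moved.lateral == pytest.approx(base.lateral, abs=1e-9)
        assert moved.depth == pytest.approx(base.depth, abs=1e-9)

    def test_invalid_triad_rejected(self):
        with pytest.raises(ValidationError):
            InstrumentPose(tip=np.zeros(3), axes=np.eye(3) * 2)
        left_handed = np.eye(3)[:, [1, 0, 2]]
        with pytest.raises(ValidationError):
            InstrumentPose(tip=np.zeros(3), axes=left_handed)


class TestCueState:
    params = DisplayParams(lateral_scale=10.0, depth_scale=10.0, in_range_radius=5.0,
                           zero_tolerance=0.05, out_of_range_circle_diameter=100.0)

    def test_on_target_cues_overlap_and_circle_vanishes(self):
        c = cue_state(Displacement(lateral=(0.0, 0.0), depth=0.0), self.params)
        assert c.mode == "in_range"
        assert c.blob_offset_px == (0.0, 0.0)
        assert not c.circle_visible and not c.blink
        assert c.circle_diameter_px == 0.0

    def test_overreach_blinks(self):
        c = cue_state(Displacement(lateral=(0.0, 0.0), depth=-2.0), self.params)
        assert c.blink and c.circle_visible
        assert c.circle_diameter_px == pytest.approx(20.0)

    def test_ahead_does_not_blink(self):
        c = cue_state(Displacement(lateral=(1.0, 0.0), depth=2.0), self.params)
        assert not c.blink
        assert c.circle_diameter_px == pytest.approx(20.0)

    def test_out_of_range_arrow_and_constant_circle(self):
        lat = (0.0, 5.0 + 1e-6)
        c = cue_state(Displacement(lateral=lat, depth=3.0), self.params)
        assert c.mode == "out_of_range"
        assert c.blob_offset_px is None
        assert c.circle_diameter_px == 100.0
        assert c.arrow_direction == pytest.approx(np.pi / 2)

    def test_boundary_tie_counts_as_in_range(self):
        c = cue_state(Displacement(lateral=(5.0, 0.0), depth=0.0), self.params)
        assert c.mode == "in_range"

    def test_circle_diameter_proportional_to_depth(self):
        full = cue_state(Displacement((0.0, 0.0), 4.0), self.params)
        half = cue_state(Displacement((0.0, 0.0), 2.0), self.params)
        assert full.circle_diameter_px == pytest.approx(2 * half.circle_diameter_px)

    def test_pure_function(self):
        d = Displacement(lateral=(1.0, 2.0), depth=-0.5)
        assert cue_state(d, self.params) == cue_state(d, self.params)


class TestDwellCapture:
    def test_constant_position_captured(self):
        times = np.arange(0.0, 3.0, 0.1)
        pos = np.tile([1.0, 2.0, 3.0], (len(times), 1))
        cap = dwell_capture(times, pos, stability_radius=1.0, dwell_time=2.0)
        assert cap is not None
        assert np.allclose(cap.position, [1, 2, 3])
        assert cap.spread == 0.0

    def test_continuous_drift_never_captures(self):
        times = np.arange(0.0, 6.0, 0.05)
        pos = np.outer(times * 5.0, [1.0, 0.0, 0.0])  # 5 mm/s
        assert dwell_capture(times, pos, stability_radius=1.0, dwell_time=2.0) is None

    def test_noisy_hold_captures_near_true_point(self):
        rng = np.random.default_rng(123)
        times = np.arange(0.0, 4.0, 0.05)
        true = np.array([10.0, -5.0, 30.0])
        pos = true + rng.normal(0, 0.2, (len(times), 3))
        cap = dwell_capture(times, pos, stability_radius=1.0, dwell_time=2.0)
        assert cap is not None
        assert np.linalg.norm(cap.position - true) < 0.1

    def test_unsorted_stream_rejected(self):
        with pytest.raises(ValidationError):
            dwell_capture([1.0, 0.5], np.zeros((2, 3)))


class TestReplayNavigation:
    def test_stationary_stream_has_zero_path(self):
        poses = [axis_aligned_pose((0, 0, 0)), axis_aligned_pose((0, 0, 0))]
        cues, summary = replay_navigation([0.0, 0.1], poses, [0.0, 0.0, 5.0])
        assert summary.path_length_cm == 0.0
        assert summary.duration_s == pytest.approx(0.1)

    def test_straight_approach_path_length_and_shrinking_circle(self):
        # 10 mm straight approach along +z sampled at 10 Hz
        times = np.arange(0.0, 1.01, 0.1)
        poses = [axis_aligned_pose((0.0, 0.0, z)) for z in np.linspace(0.0, 10.0, len(times))]
        cues, summary = replay_navigation(times, poses, [0.0, 0.0, 10.0])
        assert summary.path_length_cm == pytest.approx(1.0)
        assert summary.final_distance_mm == pytest.approx(0.0, abs=1e-12)
        diameters = [c.circle_diameter_px for c in cues]
        assert all(a > b for a, b in zip(diameters[:-1], diameters[1:]))

    def test_range_boundary_crossed_exactly_once(self):
        params = DisplayParams(in_range_radius=5.0)
        times = np.arange(0.0, 2.0, 0.1)
        xs = np.linspace(12.0, 0.0, len(times))  # lateral approach from outside
        poses = [axis_aligned_pose((x, 0.0, -10.0)) for x in xs]
        cues, _ = replay_navigation(times, poses, [0.0, 0.0, 0.0], params)
        modes = [c.mode for c in cues]
        switches = sum(a != b for a, b in zip(modes[:-1], modes[1:]))
        assert modes[0] == "out_of_range" and modes[-1] == "in_range"
        assert switches == 1

    def test_empty_stream_rejected(self):
        with pytest.raises(ValidationError):
            replay_navigation([], [], [0.0, 0.0, 0.0])
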