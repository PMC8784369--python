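import numpy as np
import pytest

from otonav import (
    DegenerateGeometryError,
    FiducialConfiguration,
    LabeledPointSet,
    ValidationError,
    combine_fle,
    confidence_ellipse,
    fle_from_fre,
    monte_carlo_tre,
    predict_tre_covariance,
    predict_tre_rms,
    tre_rms_from_samples,
)
from otonav.error_models import FLEModel
from conftest import random_rigid


def random_config(rng, n, extent=25.0):
    while True:
        pts = rng.uniform(-extent / 2, extent / 2, (n, 3))
        sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if sv[1] > 0.1 * extent:
            return FiducialConfiguration(
                LabeledPointSet([f"F{i}" for i in range(n)], pts)
            )


class TestFLEComposition:
    @pytest.mark.parametrize(
        "components, expected",
        [
            ([("image", 0.1), ("emt", 0.7)], 0.7071067811865476),
            ([("single", 0.5)], 0.5),
            ([("a", 3.0), ("b", 4.0)], 5.0),
        ],
    )
    def test_root_sum_of_squares(self, components, expected):
        assert combine_fle(components).total_rms == pytest.approx(expected, abs=1e-12)

    def test_negative_component_rejected(self):
        with pytest.raises(ValidationError):
            combine_fle([("bad", -0.1)])

    def test_inconsistent_total_rejected(self):
        with pytest.raises(ValidationError):
            FLEModel(components=(("a", 1.0),), total_rms=2.0)


class TestFLEFromFRE:
    def test_known_values(self):
        assert fle_from_fre(0.5, 4) == pytest.approx(0.7071067811865476, abs=1e-9)
        assert fle_from_fre(0.0, 6) == 0.0

    def test_too_few_fiducials(self):
        with pytest.raises(ValidationError):
            fle_from_fre(0.5, 2)

    def test_monte_carlo_round_trip(self, rng):
        """Simulated FRE at known FLE inverts back to the FLE within 2%."""
        from otonav.error_models import fit_rigid_batch

        fle_true, n, reps = 1.0, 6, 50_000
        cfg = random_config(rng, n)
        fixed = np.repeat(cfg.fiducials.points[None], reps, axis=0)
        moving = fixed + rng.normal(0, fle_true / np.sqrt(3), fixed.shape)
        R, t = fit_rigid_batch(moving, fixed)
        mapped = np.einsum("rij,rnj->rni", R, moving) + t[:, None, :]
        fre_rms = np.sqrt(np.mean(np.sum((mapped - fixed) ** 2, axis=2)))
        assert fle_from_fre(fre_rms, n) == pytest.approx(fle_true, rel=0.02)


class TestPredictTRE:
    def test_centroid_target_is_fle_over_sqrt_n(self, rng):
        cfg = random_config(rng, 5)
        fle = combine_fle([("total", 0.8)])
        pred = predict_tre_rms(cfg, cfg.centroid, fle)
        assert pred.tre_rms == pytest.approx(0.8 / np.sqrt(5), abs=1e-9)

    def test_zero_fle_gives_zero_tre(self, rng):
        cfg = random_config(rng, 4)
        pred = predict_tre_rms(cfg, cfg.centroid + [10, 0, 0], combine_fle([("z", 0.0)]))
        assert pred.tre_rms == 0.0

    def test_collinear_configuration_raises(self):
        line = LabeledPointSet(list("abcd"), np.outer(np.arange(4.0), [1.0, 0, 0]))
        cfg = FiducialConfiguration(line)
        with pytest.raises(DegenerateGeometryError):
            predict_tre_rms(cfg, [0.0, 50.0, 0.0], combine_fle([("x", 0.5)]))

    def test_analytic_matches_monte_carlo_for_distant_target(self, rng):
        """4 markers in a ~25 mm cluster, target 70 mm out: closed form vs MC."""
        cfg = random_config(rng, 4)
        fle = combine_fle([("image", 0.1), ("emt", 0.7)])
        target = cfg.centroid + 70.0 * np.array([0.6, 0.64, 0.48]) / 1.0
        pred = predict_tre_rms(cfg, target, fle)
        samples = monte_carlo_tre(cfg, target, fle, reps=100_000, seed=7)
        assert tre_rms_from_samples(samples) == pytest.approx(pred.tre_rms, rel=0.03)

    def test_invariant_under_global_rigid_motion(self, rng):
        cfg = random_config(rng, 6)
        target = cfg.centroid + [30.0, -20.0, 10.0]
        fle = combine_fle([("t", 0.7)])
        base = predict_tre_rms(cfg, target, fle).tre_rms
        T = random_rigid(rng)
        moved_cfg = FiducialConfiguration(cfg.fiducials.transformed(T))
        moved = predict_tre_rms(moved_cfg, T.apply(target), fle).tre_rms
        assert moved == pytest.approx(base, rel=1e-9)


class TestTRECovariance:
    def test_centroid_isotropy(self, rng):
        cfg = random_config(rng, 4)
        fle = combine_fle([("t", 0.6)])
        cov = predict_tre_covariance(cfg, cfg.centroid, fle)
        assert np.allclose(cov, np.eye(3) * 0.6**2 / (3 * 4), atol=1e-12)

    def test_trace_equals_analytic_rms_squared(self, rng):
        for n in (4, 6, 8):
            cfg = random_config(rng, n)
            fle = combine_fle([("t", 0.7071)])
            target = cfg.centroid + rng.uniform(-80, 80, 3)
            cov = predict_tre_covariance(cfg, target, fle)
            pred = predict_tre_rms(cfg, target, fle)
            assert np.trace(cov) == pytest.approx(pred.tre_rms**2, rel=1e-6)
            assert np.min(np.linalg.eigvalsh(cov)) >= -1e-12

    def test_matches_empirical_covariance(self, rng):
        cfg = random_config(rng, 4)
        fle = combine_fle([("image", 0.1), ("emt", 0.7)])
        target = cfg.centroid + [50.0, 30.0, -20.0]
        cov = predict_tre_covariance(cfg, target, fle)
        samples = monte_carlo_tre(cfg, target, fle, reps=100_000, seed=11)
        emp = (samples.T @ samples) / len(samples)
        assert np.linalg.norm(emp - cov) / np.linalg.norm(cov) < 0.05


class TestConfidenceEllipse:
    def test_isotropic_gives_circle(self):
        ell = confidence_ellipse(np.eye(2) * 4.0, level=0.95)
        r = 2.0 * np.sqrt(5.991464547107979)
        assert ell.semi_axes[0] == pytest.approx(r, abs=1e-9)
        assert ell.semi_axes[1] == pytest.approx(r, abs=1e-9)

    def test_diagonal_covariance(self):
        ell = confidence_ellipse(np.diag([4.0, 1.0]), level=0.95)
        k = np.sqrt(5.991464547107979)
        assert ell.semi_axes == pytest.approx((2 * k, 1 * k), abs=1e-9)
        # major axis along x
        assert abs(np.cos(ell.orientation)) == pytest.approx(1.0, abs=1e-9)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValidationError):
            confidence_ellipse(np.array([[1.0, 2.0], [2.0, 1.0]]), level=0.95)  # not PSD
        with pytest.raises(ValidationError):
            confidence_ellipse(np.eye(2), level=1.5)

    def test_coverage_matches_level(self, rng):
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        ell = confidence_ellipse(cov, level=0.95)
        samples = rng.multivariate_normal([0, 0], cov, size=100_000)
        assert ell.contains(samples).mean() == pytest.approx(0.95, abs=0.005)


class TestMonteCarloTRE:
    def test_zero_fle_gives_zero_samples(self, rng):
        cfg = random_config(rng, 4)
        s = monte_carlo_tre(cfg, cfg.centroid + [30, 0, 0], combine_fle([("z", 0.0)]),
                            reps=100, seed=1)
        assert np.all(s == 0)

    def test_same_seed_reproduces_samples(self, rng):
        cfg = random_config(rng, 4)
        fle = combine_fle([("t", 0.7)])
        target = cfg.centroid + [40, 0, 0]
        a = monte_carlo_tre(cfg, target, fle, reps=500, seed=9)
        b = monte_carlo_tre(cfg, target, fle, reps=500, seed=9)
        assert np.array_equal(a, b)

    def test_rms_grows_with_target_distance(self, rng):
        cfg = random_config(rng, 4)
        fle = combine_fle([("t", 0.7)])
        direction = np.array([1.0, 0.0, 0.0])
        rms = [
            tre_rms_from_samples(
                monte_carlo_tre(cfg, cfg.centroid + d * direction, fle,
                                reps=20_000, seed=3)
            )
            for d in (0.0, 25.0, 50.0, 100.0)
        ]
        assert all(a < b for a, b in zip(rms, rms[1:]))
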