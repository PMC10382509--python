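import numpy as np
import pytest

from normsynth import (
    RunConfig,
    Sample,
    build_report,
    covariance_ci_coverage,
    eigenvalue_compare,
    ks_battery,
    ks_normality,
    mardia_test,
    median_heuristic,
    mmd_critical_value,
    mmd_test,
    random_projection_test,
)
from normsynth.data import rng_stream
from normsynth.evaluate import EvaluationReport, make_projections
from normsynth.pca import SyntheticPopulation


def brute_force_mmd(a, b, sigma):
    """Triple-loop unbiased MMD^2 oracle."""
    def k(u, v):
        return np.exp(-np.sum((u - v) ** 2) / (2 * sigma * sigma))
    m, n = len(a), len(b)
    s_a = sum(k(a[i], a[j]) for i in range(m) for j in range(m) if i != j)
    s_b = sum(k(b[i], b[j]) for i in range(n) for j in range(n) if i != j)
    s_ab = sum(k(a[i], b[j]) for i in range(m) for j in range(n))
    return s_a / (m * (m - 1)) + s_b / (n * (n - 1)) - 2 * s_ab / (m * n)


def brute_force_mardia(values):
    """Double-loop Mahalanobis oracle for Mardia's b1 and b2."""
    n, d = values.shape
    centered = values - values.mean(axis=0)
    s_inv = np.linalg.inv(centered.T @ centered / n)
    b1 = 0.0
    for i in range(n):
        for j in range(n):
            b1 += float(centered[i] @ s_inv @ centered[j]) ** 3
    b2 = sum(float(centered[i] @ s_inv @ centered[i]) ** 2 for i in range(n))
    return b1 / n**2, b2 / n


class TestKsNormality:
    def test_null_rarely_rejected(self):
        rng = rng_stream(1, "null")
        rejects = sum(ks_normality(rng.standard_normal(667)).reject for _ in range(200))
        assert rejects <= 2  # conservative with estimated parameters

    def test_power_against_exponential(self):
        rng = rng_stream(1, "alt")
        rejects = sum(ks_normality(rng.exponential(size=667)).reject for _ in range(100))
        assert rejects >= 99

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.ones(100))


class TestMedianHeuristic:
    def test_enumerated_distances(self):
        a = Sample([[0.0], [1.0]], ["v"])
        b = Sample([[3.0], [3.0]], ["v"])
        # pooled {0,1,3,3}: nonzero distances {1,3,2,3,2} -> median 2
        assert median_heuristic(a, b) == pytest.approx(2.0)

    def test_homogeneous_scaling(self, rng):
        a = rng.standard_normal((15, 3))
        b = rng.standard_normal((10, 3))
        s = median_heuristic(Sample(a, list("abc")), Sample(b, list("abc")))
        s5 = median_heuristic(Sample(5 * a, list("abc")), Sample(5 * b, list("abc")))
        assert s5 == pytest.approx(5 * s, rel=1e-12)

    def test_identical_rows_rejected(self):
        s = Sample(np.ones((5, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            median_heuristic(s, s)


class TestMmd:
    def test_matches_brute_force(self, rng):
        for _ in range(5):
            a = rng.standard_normal((rng.integers(5, 30), 3))
            b = rng.standard_normal((rng.integers(5, 30), 3)) + 0.5
            sa, sb = Sample(a, list("abc")), Sample(b, list("abc"))
            sigma = median_heuristic(sa, sb)
            res = mmd_test(sa, sb, sigma=sigma)
            assert res.mmd_u2 == pytest.approx(brute_force_mmd(a, b, sigma), abs=1e-12)

    def test_identical_point_sets_algebraic_identity(self, rng):
        a = rng.standard_normal((20, 2))
        s = Sample(a, ["a", "b"])
        res = mmd_test(s, s)
        from scipy.spatial.distance import cdist
        kaa = np.exp(-cdist(a, a, "sqeuclidean") / (2 * res.kernel_sigma**2))
        abar = (kaa.sum() - 20) / (20 * 19)
        assert res.mmd_u2 == pytest.approx(2 * (abar - 1) / 20, abs=1e-12)
        assert res.mmd_u2 <= 0

    def test_critical_value_at_667(self):
        assert mmd_critical_value(667, 0.05, 1.0) == pytest.approx(0.26807, abs=5e-6)

    def test_null_acceptance_rate(self):
        rng = rng_stream(2, "mmdnull")
        chol = np.linalg.cholesky(0.5 * np.eye(10) + 0.5)
        accepts = 0
        for _ in range(50):
            a = Sample(rng.standard_normal((200, 10)) @ chol.T, [f"v{i}" for i in range(10)])
            b = Sample(rng.standard_normal((200, 10)) @ chol.T, [f"v{i}" for i in range(10)])
            accepts += mmd_test(a, b).accept
        assert accepts == 50  # bound is conservative under the null

    def test_dimension_mismatch(self, rng):
        a = Sample(rng.standard_normal((10, 2)), ["a", "b"])
        b = Sample(rng.standard_normal((10, 3)), ["a", "b", "c"])
        with pytest.raises(ValueError):
            mmd_test(a, b)


class TestRandomProjection:
    def test_unit_norm_and_reuse(self, rng):
        u = make_projections(4, 50, rng)
        assert np.allclose(np.linalg.norm(u, axis=1), 1.0, atol=1e-12)
        cfg = RunConfig(seed=0, n_projections=50)
        w = Sample(rng.standard_normal((300, 4)), list("abcd"))
        r1 = random_projection_test(w, 0.05, cfg, projections=u)
        r2 = random_projection_test(w, 0.05, cfg, projections=u)
        assert r1.non_reject_pct == r2.non_reject_pct

    def test_one_dimensional_battery_degenerate(self, rng):
        cfg = RunConfig(seed=0, n_projections=30)
        w = Sample(rng.standard_normal((100, 1)), ["a"])
        res = random_projection_test(w, 0.05, cfg, rng=rng)
        assert np.allclose(np.abs(res.projections), 1.0)
        assert res.non_reject_pct in (0.0, 100.0)

    def test_mvn_scores_high_exponential_low(self):
        rng = rng_stream(3, "proj")
        cfg = RunConfig(seed=3, n_projections=400)
        u = make_projections(10, 400, rng)
        mvn = Sample(rng.standard_normal((667, 10)), [f"v{i}" for i in range(10)])
        expo = Sample(rng.exponential(size=(667, 10)), [f"v{i}" for i in range(10)])
        p_mvn = random_projection_test(mvn, 0.05, cfg, projections=u).non_reject_pct
        p_exp = random_projection_test(expo, 0.05, cfg, projections=u).non_reject_pct
        assert p_mvn >= 95
        assert p_exp < p_mvn - 20


class TestMardia:
    def test_matches_brute_force(self, rng):
        for n, d in ((20, 2), (40, 3), (50, 5)):
            vals = rng.standard_normal((n, d))
            res = mardia_test(Sample(vals, [f"v{i}" for i in range(d)]))
            b1, b2 = brute_force_mardia(vals)
            assert res.b1 == pytest.approx(b1, abs=1e-10)
            assert res.b2 == pytest.approx(b2, abs=1e-10)

    def test_kurtosis_centering_constant(self):
        # E[b2] -> d(d+2) under multivariate normality
        rng = rng_stream(4, "kurt")
        vals = rng.standard_normal((20_000, 10))
        res = mardia_test(Sample(vals, [f"v{i}" for i in range(10)]))
        assert res.b2 == pytest.approx(120.0, rel=0.02)

    def test_skewed_sample_rejected(self):
        rng = rng_stream(4, "skew")
        vals = np.exp(rng.standard_normal((667, 4)))
        res = mardia_test(Sample(vals, list("abcd")))
        assert res.p_skew < 1e-4

    def test_degenerate_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            mardia_test(Sample(rng.standard_normal((3, 5)), list("abcde")))


def _population_from(rng, n, d, scale=None):
    vals = rng.standard_normal((n, d))
    if scale is not None:
        vals = vals * scale
    return SyntheticPopulation(x=vals, y=vals.copy(), t=vals.copy(),
                               names=[f"v{i}" for i in range(d)])


class TestCovCoverage:
    def test_matched_population_covers(self):
        rng = rng_stream(5, "cov")
        sample = Sample(rng.standard_normal((200, 3)), list("abc"))
        sp = _population_from(rng, 30_000, 3)
        cfg = RunConfig(seed=5, n_eval_reps=60)
        res = covariance_ci_coverage(sample, sp, cfg, rng, reps=30)
        assert res.coverage_pct.min() >= 90.0

    def test_variance_mismatch_detected(self):
        rng = rng_stream(5, "cov2")
        sample = Sample(rng.standard_normal((200, 2)), ["a", "b"])
        sp = _population_from(rng, 30_000, 2, scale=np.array([np.sqrt(2.0), 1.0]))
        cfg = RunConfig(seed=5, n_eval_reps=60)
        res = covariance_ci_coverage(sample, sp, cfg, rng, reps=30)
        assert res.coverage_pct[0, 0] <= 5.0
        assert res.coverage_pct[1, 1] >= 90.0

    def test_single_rep_degenerate(self):
        rng = rng_stream(5, "cov3")
        sample = Sample(rng.standard_normal((50, 2)), ["a", "b"])
        sp = _population_from(rng, 5_000, 2)
        cfg = RunConfig(seed=5, n_eval_reps=20)
        res = covariance_ci_coverage(sample, sp, cfg, rng, reps=1)
        assert set(np.unique(res.coverage_pct)) <= {0.0, 100.0}


class TestEigenvalueCompare:
    def test_identical_samples_give_unit_ratios(self, rng):
        y = Sample(rng.standard_normal((300, 4)), list("abcd"), "Y")
        res = eigenvalue_compare(y, y, "sample/syn")
        assert np.allclose(res.eigen_test, res.eigen_ref, rtol=1e-10)
        assert np.allclose(res.p_values, 1.0)

    def test_ratio_one_point_five_rejected_at_667(self, rng):
        y = Sample(rng.standard_normal((667, 3)), list("abc"), "Y")
        scaled = Sample(y.values * np.sqrt(1.5), list("abc"), "Y")
        res = eigenvalue_compare(y, scaled, "sample/syn")
        assert np.all(res.p_values < 0.05)

    def test_directions_swap_donor(self, rng):
        y1 = Sample(rng.standard_normal((300, 3)), list("abc"), "Y")
        y2 = Sample(rng.standard_normal((300, 3)), list("abc"), "Y")
        r12 = eigenvalue_compare(y1, y2, "sample/syn")
        r21 = eigenvalue_compare(y1, y2, "syn/sample")
        assert not np.allclose(r12.eigen_ref, r21.eigen_ref)

    def test_unknown_direction_rejected(self, rng):
        y = Sample(rng.standard_normal((50, 2)), ["a", "b"], "Y")
        with pytest.raises(ValueError):
            eigenvalue_compare(y, y, "bogus")


class TestKsBattery:
    def test_null_population_scores_high(self):
        rng = rng_stream(6, "ksb")
        sample = Sample(rng.standard_normal((300, 2)), ["a", "b"])
        sp = _population_from(rng, 30_000, 2)
        cfg = RunConfig(seed=6, n_eval_reps=100)
        pct = ks_battery(sample, sp, cfg, rng)
        assert np.all(pct >= 90)

    def test_shifted_population_scores_zero(self):
        rng = rng_stream(6, "ksb2")
        sample = Sample(rng.standard_normal((300, 1)), ["a"])
        vals = rng.standard_normal((30_000, 1)) + 1.0
        sp = SyntheticPopulation(x=vals, y=vals.copy(), t=vals.copy(), names=["a"])
        cfg = RunConfig(seed=6, n_eval_reps=100)
        assert ks_battery(sample, sp, cfg, rng)[0] <= 1.0

    def test_alpha_near_one_rejects_everything(self):
        rng = rng_stream(6, "ksb3")
        sample = Sample(rng.standard_normal((300, 1)), ["a"])
        sp = _population_from(rng, 10_000, 1)
        cfg = RunConfig(seed=6, n_eval_reps=50, alpha=0.999999)
        assert ks_battery(sample, sp, cfg, rng)[0] == 0.0


class TestReport:
    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_report(RunConfig(seed=0))

    def test_json_round_trip(self):
        cfg = RunConfig(seed=1)
        rep = build_report(cfg, mmd_y_accept_pct=100.0, projection_y_sample_pct=97.0,
                           ks_x_pct=np.array([99.0, 98.0]))
        back = EvaluationReport.from_json(rep.to_json())
        assert back.latent_normal is True
        assert back.blocks["ks_x_pct"] == [99.0, 98.0]

    def test_verdict_gating(self):
        cfg = RunConfig(seed=1)
        good = build_report(cfg, mmd_y_accept_pct=99.0, projection_y_sample_pct=95.0)
        bad = build_report(cfg, mmd_y_accept_pct=99.0, projection_y_sample_pct=60.0)
        assert good.latent_normal and not bad.latent_normal
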