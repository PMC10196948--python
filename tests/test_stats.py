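import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from subgrad import (
    AlignedGradientStack,
    GradientParams,
    GaussianSummary,
    ParcellationMap,
    PipelineError,
    avg_space_roi_mean_stat,
    bhattacharyya_distance,
    bhattacharyya_permutation,
    cohens_d,
    expansion_test,
    fit_clinical_model,
    fit_gaussian2d,
    flip_to_ipsi_contra,
    global_variance,
    group_average_gradient,
    multivariate_dispersion,
    permutation_test,
    roi_stats,
    stability_analysis,
    subject_roi_clouds,
    zscore_to_controls,
)


def make_stack(tensor, groups=None, ids=None):
    n = tensor.shape[0]
    return AlignedGradientStack(
        tensor=np.asarray(tensor, float),
        subject_ids=ids or [f"s{i}" for i in range(n)],
        groups=groups or ["control"] * n,
        batches=["p1"] * n,
    )


@pytest.fixture()
def simple_parcellation():
    # 6 voxels: one bilateral ROI of 3 voxels per side
    return ParcellationMap(
        roi=np.array(["hippocampus"] * 6, dtype=object),
        hemisphere=np.array(["L", "L", "L", "R", "R", "R"], dtype=object),
    )


class TestRoiStats:
    def test_constant_roi(self, simple_parcellation):
        tensor = np.full((1, 6, 2), 3.5)
        df = roi_stats(make_stack(tensor), simple_parcellation)
        assert (df["mean"] == 3.5).all()
        assert (df["variance"] == 0).all()

    def test_hand_computed_mean_variance(self, simple_parcellation):
        tensor = np.zeros((1, 6, 2))
        tensor[0, :3, 0] = [1.0, 2.0, 3.0]
        df = roi_stats(make_stack(tensor), simple_parcellation)
        row = df[(df.side == "L") & (df.gradient == 1)].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["variance"] == pytest.approx(1.0)  # unbiased, n-1

    def test_scaling_law(self, simple_parcellation, rng):
        tensor = rng.standard_normal((3, 6, 2))
        df1 = roi_stats(make_stack(tensor), simple_parcellation)
        df2 = roi_stats(make_stack(2 * tensor), simple_parcellation)
        np.testing.assert_allclose(df2["mean"], 2 * df1["mean"])
        np.testing.assert_allclose(df2["variance"], 4 * df1["variance"])


class TestGlobalVariance:
    def test_constant_gradient_zero(self):
        gv = global_variance(make_stack(np.ones((2, 10, 1))), 1)
        np.testing.assert_array_equal(gv.to_numpy(), 0.0)

    def test_two_point_hand_case(self):
        tensor = np.zeros((1, 2, 1))
        tensor[0, :, 0] = [-1.0, 1.0]
        assert global_variance(make_stack(tensor), 1).iloc[0] == pytest.approx(2.0)


class TestExpansionTest:
    def test_identical_groups(self, rng):
        x = rng.standard_normal(30)
        res = expansion_test(x, x.copy())
        assert res.cohens_d == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)

    def test_large_sample_effect_size_converges(self):
        rng = np.random.default_rng(42)
        res = expansion_test(rng.normal(1, 1, 1000), rng.normal(0, 1, 1000))
        assert abs(res.cohens_d - 1.0) < 0.1

    def test_bonferroni_factor(self, rng):
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 20)
        r1 = expansion_test(x, y, bonferroni=1)
        r2 = expansion_test(x, y, bonferroni=2)
        assert r2.p_corrected == pytest.approx(min(1.0, 2 * r1.p_value))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(PipelineError):
            expansion_test([1.0], [1.0, 2.0])


class TestFlip:
    @staticmethod
    def frame():
        return pd.DataFrame(
            {
                "subject_id": ["p1", "p1", "p2", "p2", "c1", "c1"],
                "group": ["L-TLE"] * 2 + ["R-TLE"] * 2 + ["control"] * 2,
                "roi": ["hippocampus"] * 6,
                "side": ["L", "R"] * 3,
                "gradient": [1] * 6,
                "mean": np.arange(6.0),
                "variance": np.ones(6),
            }
        )

    def test_left_patient_left_roi_becomes_ipsi(self):
        out = flip_to_ipsi_contra(self.frame(), {"p1": "L", "p2": "R"})
        assert list(out["side"][:2]) == ["ipsi", "contra"]  # L-TLE
        assert list(out["side"][2:4]) == ["contra", "ipsi"]  # R-TLE
        assert list(out["side"][4:]) == ["L", "R"]  # controls untouched

    def test_involution(self):
        lat = {"p1": "L", "p2": "R"}
        once = flip_to_ipsi_contra(self.frame(), lat)
        twice = flip_to_ipsi_contra(once, lat)
        pd.testing.assert_frame_equal(twice, self.frame())

    def test_missing_laterality_rejected(self):
        with pytest.raises(PipelineError, match="p2"):
            flip_to_ipsi_contra(self.frame(), {"p1": "L"})


class TestGroupAverage:
    def test_single_subject_identity(self, rng):
        tensor = rng.standard_normal((3, 8, 2))
        avg = group_average_gradient(make_stack(tensor), [1])
        np.testing.assert_array_equal(avg, tensor[1])

    def test_cancellation(self):
        tensor = np.stack([np.ones((5, 2)), -np.ones((5, 2))])
        avg = group_average_gradient(make_stack(tensor), [0, 1])
        np.testing.assert_array_equal(avg, 0.0)

    def test_by_subject_id(self, rng):
        tensor = rng.standard_normal((3, 8, 2))
        stack = make_stack(tensor, ids=["a", "b", "c"])
        np.testing.assert_array_equal(group_average_gradient(stack, ["c"]), tensor[2])

    def test_empty_group_rejected(self, rng):
        with pytest.raises(PipelineError, match="empty"):
            group_average_gradient(make_stack(rng.standard_normal((2, 4, 1))), [])


class TestPermutation:
    def test_extreme_observation_minimal_p(self):
        # groups so far apart that no shuffle reproduces the observed split
        stat = lambda a, b: float(np.mean(a) - np.mean(b))
        a = [100.0 + 0.1 * i for i in range(8)]
        b = [0.1 * i for i in range(8)]
        res = permutation_test(stat, a, b, n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_null_sample_length_and_determinism(self, rng):
        a, b = list(rng.normal(0, 1, 6)), list(rng.normal(0, 1, 6))
        stat = lambda x, y: float(np.mean(x) - np.mean(y))
        r1 = permutation_test(stat, a, b, n_perm=50, seed=3)
        r2 = permutation_test(stat, a, b, n_perm=50, seed=3)
        assert r1.null_sample.size == 50
        np.testing.assert_array_equal(r1.null_sample, r2.null_sample)
        assert 0 < r1.p_value <= 1

    def test_calibration_under_exchangeability(self):
        # p-values approximately uniform when the groups share a distribution
        rng = np.random.default_rng(7)
        stat = lambda x, y: float(np.mean(x) - np.mean(y))
        pvals = []
        for i in range(200):
            a = list(rng.normal(0, 1, 8))
            b = list(rng.normal(0, 1, 8))
            pvals.append(permutation_test(stat, a, b, n_perm=99, seed=i).p_value)
        rate = np.mean(np.array(pvals) < 0.05)
        assert 0.01 <= rate <= 0.10

    def test_small_groups_rejected(self):
        with pytest.raises(PipelineError):
            permutation_test(lambda a, b: 0.0, [1.0], [2.0, 3.0])


class TestZScore:
    @staticmethod
    def stats_frames():
        ctrl = pd.DataFrame(
            {
                "subject_id": [f"c{i}" for i in range(4)] * 2,
                "group": ["control"] * 8,
                "roi": ["hippocampus"] * 8,
                "side": ["L"] * 4 + ["R"] * 4,
                "gradient": [1] * 8,
                "mean": [8.0, 9.0, 11.0, 12.0] + [0.0, 1.0, 3.0, 4.0],
                "variance": [1.0, 2.0, 2.0, 3.0] * 2,
            }
        )
        pat = pd.DataFrame(
            {
                "subject_id": ["p1", "p1"],
                "group": ["L-TLE"] * 2,
                "roi": ["hippocampus"] * 2,
                "side": ["L", "R"],
                "gradient": [1, 1],
                "mean": [14.0, 6.0],
                "variance": [2.0, 2.0],
            }
        )
        return pat, ctrl

    def test_hand_computed_z(self):
        pat, ctrl = self.stats_frames()
        out = zscore_to_controls(pat, ctrl)
        # control left means: mean 10, sd ~1.826; patient left mean 14 -> z ~ 2.19
        sd = np.std([8, 9, 11, 12], ddof=1)
        assert out["z_mean"].iloc[0] == pytest.approx((14 - 10) / sd)

    def test_side_matched_reference(self):
        pat, ctrl = self.stats_frames()
        out = zscore_to_controls(pat, ctrl)
        # right ROI referenced to control RIGHT (mean 2), not left (mean 10)
        sd = np.std([0, 1, 3, 4], ddof=1)
        assert out["z_mean"].iloc[1] == pytest.approx((6 - 2) / sd)

    def test_patient_at_control_mean_is_zero(self):
        pat, ctrl = self.stats_frames()
        pat.loc[0, "mean"] = 10.0
        out = zscore_to_controls(pat, ctrl)
        assert out["z_mean"].iloc[0] == pytest.approx(0.0)

    def test_zero_control_sd_rejected(self):
        pat, ctrl = self.stats_frames()
        ctrl["variance"] = 1.0
        with pytest.raises(PipelineError, match="SD"):
            zscore_to_controls(pat, ctrl)


class TestGaussianAndBhattacharyya:
    def test_two_point_midpoint(self):
        g = fit_gaussian2d([0.0, 2.0], [0.0, 4.0])
        np.testing.assert_allclose(g.mu, [1.0, 2.0])

    def test_collinear_cloud_flagged_singular(self):
        x = np.linspace(0, 1, 20)
        assert fit_gaussian2d(x, 2 * x).singular

    def test_large_sample_convergence(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10000, 2))
        g = fit_gaussian2d(X[:, 0], X[:, 1])
        assert np.all(np.abs(g.mu) < 0.05)
        assert np.all(np.abs(g.sigma - np.eye(2)) < 0.05)

    def test_identical_distributions_zero_distance(self):
        g = GaussianSummary(mu=[1.0, 2.0], sigma=[[2.0, 0.3], [0.3, 1.0]])
        assert bhattacharyya_distance(g, g) == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_closed_form(self):
        p = GaussianSummary(mu=[0.0, 0.0], sigma=np.eye(2))
        q = GaussianSummary(mu=[1.0, 0.0], sigma=np.eye(2))
        assert bhattacharyya_distance(p, q) == pytest.approx(0.125, abs=1e-12)

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_symmetry_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        def rand_gauss():
            A = rng.standard_normal((2, 2))
            return GaussianSummary(mu=rng.standard_normal(2), sigma=A @ A.T + 0.1 * np.eye(2))
        p, q = rand_gauss(), rand_gauss()
        d_pq = bhattacharyya_distance(p, q)
        assert d_pq >= 0
        assert d_pq == pytest.approx(bhattacharyya_distance(q, p), rel=1e-10)

    def test_permutation_identical_groups_distance_zero(self, rng):
        cloud = rng.standard_normal((15, 2))
        items = [{"L": cloud, "R": cloud} for _ in range(4)]
        res = bhattacharyya_permutation(items, list(items), n_perm=99, seed=0)
        assert res.observed == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)


class TestDispersion:
    def test_identical_points_zero(self):
        assert multivariate_dispersion(np.ones((10, 3))) == 0.0

    def test_univariate_equivalence_n_denominator(self):
        assert multivariate_dispersion(np.array([-1.0, 1.0])) == pytest.approx(1.0)

    def test_rotation_invariance(self, rng):
        X = rng.standard_normal((40, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        centered = X - X.mean(axis=0)
        assert multivariate_dispersion(centered @ R) == pytest.approx(
            multivariate_dispersion(centered)
        )


class TestClinicalModel:
    @staticmethod
    def covariates(n=20, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "laterality": rng.choice(["L", "R"], n),
                "mts": rng.integers(0, 2, n),
                "btcs": rng.integers(0, 2, n),
                "duration_years": rng.uniform(1, 30, n),
            }
        )

    def test_constant_response(self):
        cov = self.covariates()
        fit = fit_clinical_model(np.full(20, 4.2), cov)
        assert fit.coefficients["const"] == pytest.approx(4.2)
        for term in ("laterality", "mts", "btcs", "duration"):
            assert fit.coefficients[term] == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_recovery(self):
        cov = self.covariates()
        lat = (cov["laterality"] == "R").astype(float)
        y = (
            1.0
            + 0.5 * lat
            - 0.3 * cov["mts"]
            + 0.2 * cov["btcs"]
            + 0.01 * cov["duration_years"]
        )
        fit = fit_clinical_model(y.to_numpy(), cov)
        assert fit.coefficients["const"] == pytest.approx(1.0, abs=1e-10)
        assert fit.coefficients["laterality"] == pytest.approx(0.5, abs=1e-10)
        assert fit.coefficients["mts"] == pytest.approx(-0.3, abs=1e-10)
        assert fit.coefficients["btcs"] == pytest.approx(0.2, abs=1e-10)
        assert fit.coefficients["duration"] == pytest.approx(0.01, abs=1e-10)

    def test_bonferroni_times_four(self, rng):
        cov = self.covariates()
        fit = fit_clinical_model(rng.standard_normal(20), cov)
        for term in ("laterality", "mts", "btcs", "duration"):
            assert fit.p_corrected[term] == pytest.approx(min(1.0, 4 * fit.p_values[term]))

    def test_single_laterality_rejected(self):
        cov = self.covariates()
        cov["laterality"] = "L"
        with pytest.raises(PipelineError, match="laterality"):
            fit_clinical_model(np.arange(20.0), cov)

    def test_coupled_duration_associates_with_expansion(self):
        # duration->expansion coupling in the generator surfaces as a
        # positive association between disease duration and gradient-1
        # global variance across patients
        from scipy.stats import spearmanr

        from subgrad import SimulationConfig, generate_cohort
        from subgrad.pipeline import compute_stack

        rs = []
        for seed in (0, 1, 2):
            cfg = SimulationConfig(
                seed=seed,
                n_control=2,
                n_ltle=20,
                n_rtle=20,
                expansion_factor=1.0,
                hippocampus_shift=0.0,
                duration_expansion_coupling=0.02,
            )
            cohort = generate_cohort(cfg)
            stack, _ = compute_stack(cohort.recordings, GradientParams(n_components=20))
            g = np.asarray(stack.groups, dtype=object)
            gv = global_variance(stack, 1).to_numpy()
            pat = cohort.covariates[cohort.covariates.group != "control"]
            rs.append(spearmanr(pat["duration_years"], gv[g != "control"]).statistic)
        assert sum(r > 0 for r in rs) >= 2
        assert np.mean(rs) > 0.05


class TestStability:
    def test_matrix_shape_symmetry_and_diagonal(self, tiny_cohort):
        res = stability_analysis(tiny_cohort.recordings, params=GradientParams(n_components=10))
        assert len(res.variants) == 15
        assert res.matrices.shape == (2, 15, 15)
        assert not res.failed
        for g in range(2):
            np.testing.assert_allclose(np.diagonal(res.matrices[g]), 1.0)
            np.testing.assert_allclose(res.matrices[g], res.matrices[g].T)
            assert np.all(res.matrices[g] >= 0)
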