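"""Cohort statistics: gated tests, Mann-Whitney oracle, BH step-up, symptom
normalization, correlations, cosine-similarity heterogeneity, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuronorm.core import RoiSchema
from neuronorm.stats import (bh_adjust, bootstrap_median_diff_ci,
                             category_proportions, correlate_symptoms,
                             gated_group_test, heterogeneity_cs,
                             mann_whitney_u, normalize_symptoms)


class TestGatedTest:
    def test_gaussian_groups_take_t_branch(self):
        rng = np.random.default_rng(1)
        res = gated_group_test(rng.normal(0, 1, 50), rng.normal(0.2, 1, 50))
        assert res.test == "t"

    def test_skewed_group_takes_mann_whitney_branch(self):
        rng = np.random.default_rng(2)
        res = gated_group_test(rng.lognormal(0, 1.5, 60), rng.normal(0, 1, 60))
        assert res.test == "mann-whitney"

    def test_identical_samples_null_centre(self):
        a = np.arange(30, dtype=float)
        res = gated_group_test(a, a.copy())
        assert res.p > 0.9
        if res.test == "mann-whitney":
            assert res.statistic == pytest.approx(30 * 30 / 2)  # U at its null mean
        else:
            assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_constant_group_falls_back_with_note(self):
        res = gated_group_test(np.ones(10), np.arange(10, dtype=float))
        assert res.test == "mann-whitney"
        assert "constant" in res.note

    def test_type_i_error_near_alpha_under_null(self):
        """Both branches together keep the false-positive rate near 5%."""
        rng = np.random.default_rng(3)
        hits = sum(gated_group_test(rng.normal(size=25), rng.normal(size=25)).p < 0.05
                   for _ in range(400))
        rate = hits / 400
        assert 0.02 <= rate <= 0.09  # Monte-Carlo tolerance


class TestMannWhitney:
    def test_all_pairs_favor_first_group(self):
        u, _ = mann_whitney_u([3, 4], [1, 2])
        assert u == 4.0

    def test_no_pairs_favor_first_group(self):
        u, _ = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 20), min_size=3, max_size=7),
           st.lists(st.integers(0, 20), min_size=3, max_size=7))
    def test_matches_brute_force_pair_count(self, a, b):
        """U equals exhaustive pair counting with half-credit ties."""
        a, b = np.array(a, float), np.array(b, float)
        u, _ = mann_whitney_u(a, b)
        oracle = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert u == pytest.approx(oracle)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    @pytest.mark.parametrize("pvals,expected", [
        ([0.5], [0.5]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ])
    def test_degenerate_inputs(self, pvals, expected):
        np.testing.assert_allclose(bh_adjust(pvals), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_never_below_raw_and_order_preserving(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestSymptomNormalization:
    def test_endpoints_map_to_0_and_1_before_z(self):
        raw = np.array([0.0, 15.0, 30.0])
        unit = (raw - 0.0) / 30.0
        got = normalize_symptoms(raw, 0.0, 30.0)
        # the z-step is affine, so relative spacing of endpoints is preserved
        np.testing.assert_allclose(got, (unit - unit.mean()) / unit.std())
        assert got[0] == got.min() and got[-1] == got.max()

    def test_z_step_gives_mean0_sd1(self):
        rng = np.random.default_rng(4)
        got = normalize_symptoms(rng.uniform(10, 90, 200), 0, 100)
        assert got.mean() == pytest.approx(0.0, abs=1e-12)
        assert got.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError, match="range"):
            normalize_symptoms([5.0, 31.0], 0.0, 30.0)

    def test_inverted_scale_rejected(self):
        with pytest.raises(ValueError):
            normalize_symptoms([1.0], 10.0, 0.0)


class TestCorrelateSymptoms:
    def test_identical_vectors_give_rho_1(self):
        rng = np.random.default_rng(5)
        dev = rng.lognormal(0, 1, (40, 2))
        out = correlate_symptoms(dev, dev[:, 0], roi_names=["a", "b"])
        assert out.loc[0, "coefficient"] == pytest.approx(1.0)

    def test_null_association_small_coefficients(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(40):
            dev = rng.normal(size=(200, 1))
            sym = rng.normal(size=200)
            out = correlate_symptoms(dev, sym)
            hits += abs(out.loc[0, "coefficient"]) < 0.2
        assert hits >= 38  # |rho| < 0.2 in >= 95% of runs

    def test_monotone_nonlinear_link_prefers_spearman(self):
        """With skewed symptoms the Spearman branch fires, and captures a
        monotone nonlinear association perfectly."""
        x = np.linspace(0.1, 4.0, 50)
        sym = np.exp(3 * x)  # heavily skewed -> Shapiro fails -> spearman
        out = correlate_symptoms(x[:, None], sym)
        assert out.loc[0, "type"] == "spearman"
        assert out.loc[0, "coefficient"] == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        out = correlate_symptoms(np.ones((10, 1)), np.arange(10, dtype=float))
        assert out.loc[0, "note"] == "zero variance"
        assert np.isnan(out.loc[0, "coefficient"])


@pytest.fixture()
def tiny_schema():
    return RoiSchema(
        names=("f1", "f2", "t1", "v1"),
        group={"f1": "frontal", "f2": "frontal", "t1": "temporal",
               "v1": "ventricles"},
        cortical={"f1": True, "f2": True, "t1": True, "v1": False})


class TestHeterogeneity:
    def test_identical_rows_cs_1(self, tiny_schema):
        x = np.tile([1.0, 2.0, 3.0, 4.0], (5, 1))
        res = {r.region_group: r for r in heterogeneity_cs(x, tiny_schema)}
        assert res["all"].mean_cs == pytest.approx(1.0)
        assert res["all"].n_pairs == 10

    def test_orthogonal_rows_cs_0(self, tiny_schema):
        x = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
        res = {r.region_group: r for r in heterogeneity_cs(x, tiny_schema)}
        assert res["all"].mean_cs == pytest.approx(0.0)

    def test_matches_double_loop_oracle(self, tiny_schema):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(4, 4))
        res = {r.region_group: r for r in heterogeneity_cs(x, tiny_schema)}
        sims = []
        for i in range(4):
            for j in range(i + 1, 4):
                sims.append(x[i] @ x[j] / (np.linalg.norm(x[i]) * np.linalg.norm(x[j])))
        assert res["all"].mean_cs == pytest.approx(np.mean(sims))
        assert res["all"].sd_cs == pytest.approx(np.std(sims, ddof=1))
        # frontal subgroup uses only the first two columns
        sub = []
        for i in range(4):
            for j in range(i + 1, 4):
                a, b = x[i, :2], x[j, :2]
                sub.append(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        assert res["frontal"].mean_cs == pytest.approx(np.mean(sub))

    def test_scale_invariance(self, tiny_schema):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(6, 4))
        y = x.copy()
        y[2] *= 7.3  # positive rescaling of one participant
        a = heterogeneity_cs(x, tiny_schema)[0].mean_cs
        b = heterogeneity_cs(y, tiny_schema)[0].mean_cs
        assert a == pytest.approx(b)

    def test_zero_vector_pair_skipped_and_counted(self, tiny_schema):
        x = np.array([[1.0, 1, 1, 1], [0.0, 0, 0, 0], [1.0, 2, 3, 4]])
        res = heterogeneity_cs(x, tiny_schema)[0]
        assert res.n_skipped == 2  # both pairs involving the zero row
        assert np.isfinite(res.mean_cs)


class TestBootstrap:
    def test_same_seed_identical_ci(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 40), rng.normal(0, 1, 40)
        r1 = bootstrap_median_diff_ci(a, b, reps=200, seed=5)
        r2 = bootstrap_median_diff_ci(a, b, reps=200, seed=5)
        assert r1 == r2

    def test_null_coverage(self):
        """CI covers 0 in roughly 95% of same-distribution replications."""
        rng = np.random.default_rng(10)
        cover = 0
        reps = 60
        for i in range(reps):
            a, b = rng.normal(0, 1, 40), rng.normal(0, 1, 40)
            _, (lo, hi) = bootstrap_median_diff_ci(a, b, reps=300, seed=i)
            cover += lo <= 0 <= hi
        assert cover / reps >= 0.85

    def test_shift_detected(self):
        rng = np.random.default_rng(11)
        a = rng.normal(2, 1, 100)
        b = rng.normal(0, 1, 100)
        est, (lo, hi) = bootstrap_median_diff_ci(a, b, reps=500, seed=0)
        assert lo > 0 and est == pytest.approx(2.0, abs=0.6)


class TestCategoryProportions:
    def test_all_one_category(self):
        out = category_proportions(["High"] * 4)
        assert out.loc["all", "High"] == pytest.approx(1.0)

    def test_half_and_half_and_sums(self):
        out = category_proportions(["Low", "Low", "High", "Medium"],
                                   groups=["g1", "g1", "g2", "g2"])
        assert out.loc["g1", "Low"] == pytest.approx(0.5 * 2)  # 2 of 2 in g1
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)
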