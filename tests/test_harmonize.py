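"""ComBat and the IQM-based correction predictor: injected-effect recovery,
diffuse-prior limit, covariate preservation, unseen-scanner harmonization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neuronorm import compute_relative_volumes
from neuronorm.core import Cohort
from neuronorm.harmonize import (apply_combat, apply_harmonizer, fit_combat,
                                 fit_harmonizer)
from neuronorm.simulate import SimConfig, simulate_cohort


def _gauss_batches(n_per=300, k=8, shift=None, scale=None, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per, k))
    b = rng.normal(0.0, 1.0, size=(n_per, k))
    if shift is not None:
        b = b + shift
    if scale is not None:
        b = b * scale
    x = np.vstack([a, b])
    batch = np.array(["A"] * n_per + ["B"] * n_per)
    return x, batch


class TestCombat:
    def test_null_batches_give_small_corrections(self):
        x, batch = _gauss_batches(seed=1)
        model = fit_combat(x, batch)
        assert np.abs(model.gamma_star).max() < 0.15
        assert np.abs(model.delta_star - 1.0).max() < 0.2
        corrected = apply_combat(model, x, batch)
        assert np.abs(corrected - x).mean() < 0.1

    def test_injected_additive_shift_removed(self):
        """A constant batch offset c is equalized to within 5% of c."""
        c = 1.3
        shift = np.zeros(8)
        shift[3] = c
        x, batch = _gauss_batches(shift=shift, seed=2)
        model = fit_combat(x, batch)
        corrected = apply_combat(model, x, batch)
        gap_before = x[batch == "B", 3].mean() - x[batch == "A", 3].mean()
        gap_after = corrected[batch == "B", 3].mean() - corrected[batch == "A", 3].mean()
        assert abs(gap_before) > 0.9 * c
        assert abs(gap_after) < 0.05 * c

    def test_diffuse_prior_limit_matches_moment_oracle(self):
        """Without EB shrinkage the batch effects are the plain per-batch
        location/scale moments of the standardized data (computed here from
        first principles); with mild heterogeneity the EB estimates stay
        close to that oracle."""
        x, batch = _gauss_batches(shift=np.full(8, 0.8), scale=1.4, seed=3)
        no_eb = fit_combat(x, batch, eb=False)
        # oracle: balanced batches -> grand mean is the overall mean; pooled
        # variance is the mean squared residual around the batch means
        grand = x.mean(axis=0)
        resid = np.vstack([x[batch == b] - x[batch == b].mean(axis=0)
                           for b in ("A", "B")])
        var_pooled = (resid ** 2).mean(axis=0)
        np.testing.assert_allclose(no_eb.grand_mean, grand, atol=1e-10)
        np.testing.assert_allclose(no_eb.var_pooled, var_pooled, atol=1e-10)
        stand = (x - grand) / np.sqrt(var_pooled)
        for i, b in enumerate(("A", "B")):
            np.testing.assert_allclose(no_eb.gamma_star[i],
                                       stand[batch == b].mean(axis=0), atol=1e-10)
            np.testing.assert_allclose(no_eb.delta_star[i],
                                       stand[batch == b].var(axis=0, ddof=1), atol=1e-10)
        eb = fit_combat(x, batch, eb=True)
        # shrinkage is mild here: EB close to the oracle
        np.testing.assert_allclose(eb.gamma_star, no_eb.gamma_star, atol=0.1)
        np.testing.assert_allclose(eb.delta_star, no_eb.delta_star, rtol=0.25)

    def test_identity_when_no_batch_effect_parameters(self):
        x, batch = _gauss_batches(n_per=50, seed=4)
        model = fit_combat(x, batch)
        model.gamma_star[:] = 0.0
        model.delta_star[:] = 1.0
        np.testing.assert_allclose(apply_combat(model, x, batch), x, atol=1e-10)

    def test_refit_on_corrected_data_is_a_fixed_point(self):
        x, batch = _gauss_batches(shift=np.full(8, 1.0), seed=5)
        corrected = apply_combat(fit_combat(x, batch), x, batch)
        refit = fit_combat(corrected, batch)
        assert np.abs(refit.gamma_star).max() < 0.05

    def test_covariate_slope_preserved(self):
        """The age effect must survive harmonization."""
        rng = np.random.default_rng(6)
        n = 300
        age = rng.uniform(20, 80, 2 * n)
        batch = np.array(["A"] * n + ["B"] * n)
        slope = 0.05
        y = (slope * age[:, None] + rng.normal(0, 1, (2 * n, 4))
             + np.where(batch == "B", 2.0, 0.0)[:, None])
        cov = pd.DataFrame({"age": age})
        model = fit_combat(y, batch, cov)
        corrected = apply_combat(model, y, batch, cov)
        for j in range(4):
            before = sps.linregress(age, y[:, j]).slope
            after = sps.linregress(age, corrected[:, j]).slope
            assert abs(after - slope) < 0.01
            assert abs(after - before) < 0.02

    def test_unseen_batch_rejected_with_pointer(self):
        x, batch = _gauss_batches(n_per=50, seed=7)
        model = fit_combat(x, batch)
        with pytest.raises(KeyError, match="unseen"):
            apply_combat(model, x[:5], np.array(["C"] * 5))

    def test_single_batch_warns(self):
        rng = np.random.default_rng(8)
        with pytest.warns(UserWarning, match="single batch"):
            fit_combat(rng.normal(size=(30, 4)), np.array(["A"] * 30))


@pytest.fixture(scope="module")
def harmonizer_setup():
    """Four simulated scanners with IQM-linked effects; the scanner whose
    latent quality is interior to the others is held out as 'unseen' and the
    harmonizer trained on the remaining three."""
    cohort, truth = simulate_cohort(SimConfig(
        n_per_scanner=(150, 150, 150, 150), seed=31, scanner_effect_sd=1.0,
        scanner_quality=(-3.0, 0.0, 3.0, 2.0)))
    rel = compute_relative_volumes(cohort)
    unseen_idx = 3  # quality 2 (a 2-sigma shift), interior to [-3, 3]
    unseen_name = cohort.data["scanner"].unique()[unseen_idx]
    is_unseen = (rel.data["scanner"] == unseen_name).to_numpy()
    train, unseen = rel.subset(~is_unseen), rel.subset(is_unseen)
    cov = pd.DataFrame({"age": train.data["age"].astype(float),
                        "sex": train.sex_codes().astype(float)})
    combat = fit_combat(train.volumes.to_numpy(),
                        train.data["scanner"].to_numpy(), cov)
    model = fit_harmonizer(train, combat, ("age", "sex"), n_estimators=60, seed=0)
    return train, unseen, unseen_idx, truth, combat, model


class TestHarmonizer:
    def test_null_effects_predict_near_zero_corrections(self):
        cohort, _ = simulate_cohort(SimConfig(
            n_per_scanner=(80, 80), seed=32, scanner_effect_sd=0.0,
            scanner_scale_sd=0.0))
        rel = compute_relative_volumes(cohort)
        cov = pd.DataFrame({"sex": rel.sex_codes().astype(float)})
        combat = fit_combat(rel.volumes.to_numpy(),
                            rel.data["scanner"].to_numpy(), cov)
        model = fit_harmonizer(rel, combat, ("sex",), n_estimators=40, seed=0)
        _, noise = simulate_cohort(SimConfig(n_per_scanner=(80, 80), seed=32))
        # corrections should be tiny relative to the within-scanner noise
        assert np.abs(model.mean_correction).max() < noise.noise_sd.mean() * 0.5

    def test_approximates_combat_on_training_rows(self, harmonizer_setup):
        rel, _, _, truth, combat, model = harmonizer_setup
        cov = pd.DataFrame({"age": rel.data["age"].astype(float),
                            "sex": rel.sex_codes().astype(float)})
        raw = rel.volumes.to_numpy()
        target = apply_combat(combat, raw, rel.data["scanner"].to_numpy(), cov)
        approx, _ = apply_harmonizer(model, rel)
        # ROIs with a real injected additive effect
        affected = np.abs(truth.scanner_additive).max(axis=0) > truth.noise_sd
        assert affected.sum() > 5
        rmse_nh = np.sqrt(((approx.volumes.to_numpy() - target) ** 2).mean(axis=0))
        rmse_raw = np.sqrt(((raw - target) ** 2).mean(axis=0))
        assert (rmse_nh[affected] < 0.5 * rmse_raw[affected]).mean() > 0.9

    def test_unseen_scanner_gap_halved(self, harmonizer_setup):
        """A held-out scanner with interpolating IQMs gets its batch-mean gap
        reduced by at least half on the strongly affected ROIs."""
        train, unseen, unseen_idx, truth, combat, model = harmonizer_setup
        harmonized, _ = apply_harmonizer(model, unseen)
        # reference healthy mean from the corrected training data
        train_harm, _ = apply_harmonizer(model, train)
        ref = train_harm.volumes.to_numpy().mean(axis=0)
        affected = np.abs(truth.scanner_additive[unseen_idx]) > 1.5 * truth.noise_sd
        assert affected.sum() >= 3
        gap_before = np.abs(unseen.volumes.to_numpy().mean(axis=0) - ref)
        gap_after = np.abs(harmonized.volumes.to_numpy().mean(axis=0) - ref)
        reduction = 1 - gap_after[affected] / gap_before[affected]
        assert np.median(reduction) >= 0.5

    def test_pure_function_of_predictors(self, harmonizer_setup):
        """Permuting scanner labels at apply time changes nothing."""
        rel, *_, model = harmonizer_setup
        sub = rel.subset(np.arange(len(rel)) < 60)
        shuffled = sub.data.copy()
        shuffled["scanner"] = np.random.default_rng(0).permutation(
            shuffled["scanner"].to_numpy())
        out_a, _ = apply_harmonizer(model, sub)
        out_b, _ = apply_harmonizer(model, Cohort(sub.schema, shuffled, "relative"))
        np.testing.assert_array_equal(out_a.volumes.to_numpy(),
                                      out_b.volumes.to_numpy())

    def test_deterministic_on_repeat(self, harmonizer_setup):
        rel, *_, model = harmonizer_setup
        sub = rel.subset(np.arange(len(rel)) < 40)
        a, _ = apply_harmonizer(model, sub)
        b, _ = apply_harmonizer(model, sub)
        np.testing.assert_array_equal(a.volumes.to_numpy(), b.volumes.to_numpy())

    def test_out_of_range_iqm_flagged_but_corrected(self, harmonizer_setup):
        rel, *_, model = harmonizer_setup
        sub = rel.subset(np.arange(len(rel)) < 10)
        data = sub.data.copy()
        hi = model.iqm_ranges.loc["iqm_snr", "max"]
        data.loc[0, "iqm_snr"] = hi * 1.2 + 1.0
        out, report = apply_harmonizer(model, Cohort(sub.schema, data, "relative"))
        assert bool(report.loc[0, "out_of_range"])
        assert "iqm_snr" in report.loc[0, "offending_iqms"]
        assert not report.loc[1:, "out_of_range"].any()
        assert np.isfinite(out.volumes.to_numpy()).all()

    def test_covariate_variants_distinct(self, harmonizer_setup):
        rel, _, _, _, combat, model_agesex = harmonizer_setup
        cov = pd.DataFrame({"sex": rel.sex_codes().astype(float)})
        combat_sex = fit_combat(rel.volumes.to_numpy(),
                                rel.data["scanner"].to_numpy(), cov)
        model_sex = fit_harmonizer(rel, combat_sex, ("sex",),
                                   n_estimators=20, seed=0)
        assert model_agesex.covariate_set == ("age", "sex")
        assert model_sex.covariate_set == ("sex",)
        assert "age" in model_agesex.predictor_names
        assert "age" not in model_sex.predictor_names

    def test_missing_iqm_column_rejected(self, harmonizer_setup):
        rel, *_, model = harmonizer_setup
        sub = rel.subset(np.arange(len(rel)) < 5)
        data = sub.data.drop(columns=["iqm_snr"])
        with pytest.raises(KeyError):
            apply_harmonizer(model, Cohort(sub.schema, data, "relative"))
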