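import numpy as np
import pandas as pd
import pytest

from glycoce import synth_data
from glycoce.glyco_chem import feature_table
from glycoce.modeling import (
    ancova,
    fit_trendline,
    lasso_path,
    pearson,
    select_features,
    test_slope_homogeneity,
)


@pytest.fixture(scope="module")
def cohort():
    species = synth_data.sample_species(300, seed=1)
    return feature_table(species)


class TestTrendline:
    def test_exact_line(self):
        mz = np.linspace(600, 2000, 20)
        ce = 0.0607 * mz + 13.57
        fit = fit_trendline(mz, ce, "byonic")
        assert fit.slope == pytest.approx(0.0607, abs=1e-12)
        assert fit.intercept == pytest.approx(13.57, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_duplicated_points(self):
        mz = np.array([600.0, 600.0, 2000.0, 2000.0])
        ce = np.array([50.0, 50.0, 135.0, 135.0])
        fit = fit_trendline(mz, ce)
        assert fit.slope == pytest.approx((135 - 50) / 1400)
        assert fit.intercept == pytest.approx(50 - fit.slope * 600)

    def test_parameter_recovery(self, cohort):
        rng = np.random.default_rng(1)
        persona = synth_data.PEPTIDE_CENTRIC
        mz = cohort["mz"].to_numpy()[:200]
        ce = persona.intercept + persona.slope_mz * mz + rng.normal(0, 2.0, 200)
        fit = fit_trendline(mz, ce)
        assert fit.slope == pytest.approx(persona.slope_mz, rel=0.10)

    def test_degenerate_mz(self):
        with pytest.raises(ValueError):
            fit_trendline([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_trendline([1, 2], [1, 2])


class TestSlopeHomogeneity:
    def test_null_calibrated(self, cohort):
        mz = cohort["mz"].to_numpy()[:120]
        group = (cohort["n_sialic"].to_numpy()[:120] > 0).astype(str)
        rng = np.random.default_rng(11)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            y = 13.57 + 0.0607 * mz + rng.normal(0, 2.5, len(mz))
            _, p = test_slope_homogeneity(y, group, mz, is_factor=True)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sims <= 0.09

    def test_power_on_separated_slopes(self, cohort):
        mz = cohort["mz"].to_numpy()[:120]
        group = (cohort["n_sialic"].to_numpy()[:120] > 0).astype(str)
        rng = np.random.default_rng(12)
        rejections = 0
        for _ in range(100):
            slope = np.where(group == "True", 0.0607 * 1.3, 0.0607)
            y = 13.57 + slope * mz + rng.normal(0, 2.5, len(mz))
            _, p = test_slope_homogeneity(y, group, mz, is_factor=True)
            rejections += p < 0.05
        assert rejections / 100 > 0.9

    def test_single_level_factor_rejected(self):
        mz = np.linspace(600, 2000, 30)
        y = 0.06 * mz + np.sin(mz)
        with pytest.raises(ValueError):
            test_slope_homogeneity(y, np.array(["a"] * 30), mz, is_factor=True)

    def test_sparse_levels_merged_with_warning(self):
        mz = np.linspace(600, 2000, 30)
        y = 0.06 * mz + np.sin(mz)
        factor = np.array(["a"] * 28 + ["b", "c"])  # two singletons -> "other"
        with pytest.warns(UserWarning, match="other"):
            _, p = test_slope_homogeneity(y, factor, mz, is_factor=True)
        assert np.isfinite(p)


class TestAncova:
    def test_exact_null_covariate(self):
        rng = np.random.default_rng(0)
        mz = np.linspace(600, 2000, 50)
        h = rng.normal(0, 8, 50)
        y = 13.57 + 0.0607 * mz  # exactly linear in mz only
        result = ancova(y, h, mz, is_factor=False)
        assert result.coefficients["covariate"] == pytest.approx(0.0, abs=1e-9)
        assert result.covariate_p == pytest.approx(1.0)

    def test_continuous_effect_detected(self, cohort):
        rng = np.random.default_rng(5)
        mz = cohort["mz"].to_numpy()[:150]
        h = cohort["hydrophobicity"].to_numpy()[:150]
        y = 13.57 + 0.0607 * mz + 0.4 * h + rng.normal(0, 2.0, 150)
        result = ancova(y, h, mz, is_factor=False)
        assert result.covariate_p < 1e-6
        assert result.coefficients["covariate"] == pytest.approx(0.4, abs=0.1)

    def test_categorical_contrasts_reference(self, cohort):
        rng = np.random.default_rng(6)
        mz = cohort["mz"].to_numpy()[:200]
        mp = np.clip(cohort["mobile_protons"].to_numpy()[:200], 0, 2)
        y = 13.57 + 0.0607 * mz - 3.0 * mp + rng.normal(0, 2.0, 200)
        result = ancova(y, mp.astype(int).astype(str), mz, reference_level="0",
                        is_factor=True)
        assert result.reference_level == "0"
        assert set(result.contrasts) == {"1", "2"}
        est1, p1 = result.contrasts["1"]
        est2, p2 = result.contrasts["2"]
        assert est1 == pytest.approx(-3.0, abs=1.0)
        assert est2 == pytest.approx(-6.0, abs=1.5)
        assert p1 < 0.01 and p2 < 0.01

    def test_mobile_proton_power(self, cohort):
        # strong glycan-persona mobile-proton effect is detected reliably
        rng = np.random.default_rng(7)
        mz = cohort["mz"].to_numpy()[:150]
        mp = np.clip(cohort["mobile_protons"].to_numpy()[:150], 0, 2).astype(int).astype(str)
        persona = synth_data.GLYCAN_CENTRIC
        hits = 0
        for _ in range(50):
            y = (persona.intercept + persona.slope_mz * mz
                 + persona.coef_mobile_protons * mp.astype(float)
                 + rng.normal(0, persona.optimum_noise_sd, 150))
            result = ancova(y, mp, mz, reference_level="0", is_factor=True)
            hits += all(p < 0.05 for _, p in result.contrasts.values())
        assert hits / 50 >= 0.9

    def test_reduces_to_trendline_when_constant_variable(self, cohort):
        mz = cohort["mz"].to_numpy()[:50]
        rng = np.random.default_rng(8)
        y = 13.57 + 0.0607 * mz + rng.normal(0, 1.0, 50)
        with pytest.raises(ValueError):
            ancova(y, np.full(50, 3.0), mz, is_factor=False)
        trend = fit_trendline(mz, y)
        # with a constant variable the model is the plain trendline
        assert trend.slope == pytest.approx(
            np.polyfit(mz, y, 1)[0], abs=1e-9)


class TestLassoPath:
    def _data(self, cohort, seed=0, noise=3.0):
        rng = np.random.default_rng(seed)
        X = cohort[["mz", "hydrophobicity", "charge", "glycan_mass", "n_fucose",
                    "peptide_length"]]
        y = (13.57 + 0.0607 * X["mz"] + 0.4 * X["hydrophobicity"]
             - 4.0 * X["charge"] - 0.008 * X["glycan_mass"]
             + rng.normal(0, noise, len(X)))
        return X, y.to_numpy()

    def test_zero_penalty_equals_ols(self, cohort):
        X, y = self._data(cohort)
        path = lasso_path(X, y, penalties=[0.0])
        Xmat = np.column_stack([np.ones(len(X)), X.to_numpy()])
        beta = np.linalg.lstsq(Xmat, y, rcond=None)[0]
        np.testing.assert_allclose(
            path.coefficients.iloc[:, 0].to_numpy(), beta[1:], atol=1e-6)

    def test_above_max_penalty_all_zero(self, cohort):
        X, y = self._data(cohort)
        Xs = (X - X.mean()) / X.std(ddof=0)
        lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / len(y)
        path = lasso_path(X, y, penalties=[lam_max * 1.01])
        assert np.all(path.coefficients.to_numpy() == 0.0)

    def test_active_set_shrinks_with_penalty(self, cohort):
        X, y = self._data(cohort)
        path = lasso_path(X, y)
        n_active = [(np.abs(path.coefficients[lam]) > 1e-12).sum()
                    for lam in sorted(path.penalties)]
        # non-increasing as penalty grows (iterate from small to large penalty)
        assert all(b <= a + 1 for a, b in zip(n_active, n_active[1:]))

    def test_constant_feature_dropped(self, cohort):
        X, y = self._data(cohort)
        X = X.assign(const=1.0)
        with pytest.warns(UserWarning, match="const"):
            path = lasso_path(X, y)
        assert "const" not in path.feature_names


class TestSelectFeatures:
    def test_selection_recovers_truth(self, cohort):
        rng = np.random.default_rng(3)
        cols = ["mz", "peptide_mass", "glycan_mass", "hydrophobicity", "charge",
                "mobile_protons", "n_sialic", "n_fucose", "n_antennae",
                "glycosite_position_fraction", "peptide_length"]
        X = cohort[cols]
        y = (13.57 + 0.0607 * X["mz"] + 0.4 * X["hydrophobicity"]
             - 4.0 * X["charge"] - 0.008 * X["glycan_mass"]
             + rng.normal(0, 3.0, len(X))).to_numpy()
        path = lasso_path(X, y)
        selected = set(select_features(path, 0.01))
        assert selected in ({"mz", "hydrophobicity", "charge", "glycan_mass"},
                            {"mz", "hydrophobicity", "mobile_protons", "glycan_mass"})

    def test_pure_noise_selects_nothing(self, cohort):
        rng = np.random.default_rng(4)
        X = cohort[["mz", "hydrophobicity", "charge", "glycan_mass"]].iloc[:300]
        y = rng.normal(0, 1.0, len(X))
        path = lasso_path(X, y)
        selected = select_features(path, 0.02)
        assert len(selected) <= 1

    def test_delta_zero_gives_full_active_set(self, cohort):
        X, y = TestLassoPath()._data(cohort)
        path = lasso_path(X, y)
        selected = select_features(path, 0.0)
        smallest_penalty = min(path.penalties)
        full_active = {f for f in path.feature_names
                       if abs(path.coefficients.loc[f, smallest_penalty]) > 1e-12}
        assert set(selected).issubset(full_active)
        assert len(selected) >= 4

    def test_monotone_in_delta(self, cohort):
        X, y = TestLassoPath()._data(cohort)
        path = lasso_path(X, y)
        sizes = [len(select_features(path, d)) for d in (0.0, 0.005, 0.01, 0.05, 0.2)]
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_charge_vs_mobile_protons_cohort(self, cohort):
        r = pearson(cohort["charge"], cohort["mobile_protons"])
        assert 0.5 <= r <= 0.9
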