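"""Growth/reproduction/mortality fitting: exact recoveries, AIC
selection, and the time-to-length transformation."""

import numpy as np
import pandas as pd
import pytest

from idopspm import (
    GrowthParams,
    fit_growth,
    fit_mortality,
    fit_reproduction,
    growth_increments,
    select_growth_model,
    time_to_length,
)
from idopspm.fitting import REARING_COLUMNS, validate_rearing_table
from idopspm.process_models import growth_rate


def _table(rows):
    return pd.DataFrame(rows, columns=list(REARING_COLUMNS))


def _row(iid, week, length, alive=True, sex="f", offspring=np.nan):
    return dict(
        individual_id=iid, species="s", treatment="reference", sex=sex,
        week=week, length_mm=length, alive=alive, offspring_count=offspring,
    )


class TestGrowthIncrements:
    def test_midpoint_and_rate_arithmetic(self):
        tbl = _table([_row("a", 0, 4.0), _row("a", 1, 6.0)])
        inc = growth_increments(tbl)
        assert len(inc) == 1
        assert inc.loc[0, "l_mid"] == pytest.approx(5.0)
        assert inc.loc[0, "dldt"] == pytest.approx(2.0 / 7.0)

    def test_missing_moult_produces_no_pair(self):
        tbl = _table([_row("a", 0, 4.0), _row("a", 1, np.nan), _row("a", 2, 6.0)])
        inc = growth_increments(tbl)
        # the gap spans two weeks: one pair over 14 days
        assert len(inc) == 1
        assert inc.loc[0, "dldt"] == pytest.approx(2.0 / 14.0)

    def test_single_observation_individuals_skipped(self):
        tbl = _table([_row("a", 0, 4.0), _row("b", 0, 3.0), _row("b", 1, 4.0)])
        inc = growth_increments(tbl)
        assert set(inc["individual_id"]) == {"b"}

    def test_constant_length_gives_zero_rate(self):
        tbl = _table([_row("a", w, 10.0) for w in range(3)])
        assert np.all(growth_increments(tbl)["dldt"] == 0.0)

    def test_schema_validation(self):
        with pytest.raises(ValueError, match="missing columns"):
            validate_rearing_table(pd.DataFrame({"week": [1]}))


def _pairs_from(gp, l_values, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    y = growth_rate(l_values, gp) + rng.normal(0, noise_sd, len(l_values))
    return pd.DataFrame({"l_mid": l_values, "dldt": y})


class TestFitGrowth:
    truth = GrowthParams(variant="G2", rho=0.05, l_max=15.0)

    def test_noiseless_recovery_is_exact(self):
        pairs = _pairs_from(self.truth, np.linspace(1, 14.5, 60))
        fit = fit_growth(pairs, "G2")
        assert fit.params["rho"] == pytest.approx(0.05, abs=1e-6)
        assert fit.params["l_max"] == pytest.approx(15.0, abs=1e-4)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_within_three_ses(self):
        pairs = _pairs_from(self.truth, np.linspace(1, 14.5, 200), noise_sd=0.01, seed=3)
        fit = fit_growth(pairs, "G2")
        assert abs(fit.params["rho"] - 0.05) <= 3 * fit.ses["rho"]

    def test_reference_l_max_is_fixed_exactly(self):
        pairs = _pairs_from(self.truth, np.linspace(1, 14.5, 60), noise_sd=0.005)
        fit = fit_growth(pairs, "G3", l_max_ref=15.0)
        assert fit.params["l_max"] == 15.0
        assert fit.ses["l_max"] == 0.0

    def test_g3_requires_reference_length(self):
        pairs = _pairs_from(self.truth, np.linspace(1, 14.5, 10))
        with pytest.raises(ValueError, match="l_max_ref"):
            fit_growth(pairs, "G3")

    def test_gaussian_aic_penalizes_parameters(self):
        from idopspm.fitting import gaussian_aic

        # equal RSS: the 2-parameter model must beat the 4-parameter one
        assert gaussian_aic(1.0, 100, 2) < gaussian_aic(1.0, 100, 4)


class TestSelectGrowthModel:
    def test_logistic_family_selected_on_logistic_data(self):
        truth = GrowthParams(variant="G2", rho=0.05, l_max=15.0)
        pairs = _pairs_from(truth, np.linspace(1, 14.8, 150), noise_sd=0.003, seed=1)
        best, fits = select_growth_model(pairs, l_max_ref=15.0, seed=1)
        assert best.model_tag in ("G2", "G3")
        assert set(fits) == {"G1", "G2", "G3", "G4", "G5"}

    def test_size_dependent_family_selected_when_true(self):
        truth = GrowthParams(
            variant="G4", rho_j=0.005, rho_a=0.08, l_crit=4.0, beta=3.0, l_max=12.0
        )
        pairs = _pairs_from(truth, np.linspace(0.5, 11.8, 300), noise_sd=0.003, seed=2)
        best, _ = select_growth_model(pairs, seed=2)
        assert best.model_tag in ("G4", "G5")


class TestTimeToLength:
    def test_logistic_closed_form(self):
        gp = GrowthParams(variant="G2", rho=0.05, l_max=15.0)
        t = 40.0
        expected = 15.0 / (1 + ((15.0 - 2.0) / 2.0) * np.exp(-0.05 * t))
        assert time_to_length(t, gp) == pytest.approx(expected, rel=1e-12)
        assert time_to_length(0.0, gp) == pytest.approx(2.0)

    def test_von_bertalanffy_closed_form(self):
        gp = GrowthParams(variant="G1", rho=0.1, l_max=20.0)
        assert time_to_length(10.0, gp) == pytest.approx(20.0 - 18.0 * np.e**-1, rel=1e-12)

    def test_size_dependent_numeric_solution_matches_reduced_logistic(self):
        # with rho_j = rho_a, G4 collapses to plain logistic growth
        g4 = GrowthParams(variant="G4", rho_j=0.05, rho_a=0.05, l_crit=4.0, beta=2.0, l_max=15.0)
        g2 = GrowthParams(variant="G2", rho=0.05, l_max=15.0)
        t = np.linspace(0, 100, 11)
        assert np.allclose(time_to_length(t, g4), time_to_length(t, g2), rtol=1e-6)


class TestFitReproduction:
    truth_growth = GrowthParams(variant="G2", rho=0.032, l_max=9.7)

    def _brood_table(self, f_max=5.46, l_r=8.43, sigma_r=0.8, scale=1.0, seed=0):
        from idopspm.process_models import fecundity, ReproductionParams

        rng = np.random.default_rng(seed)
        rp = ReproductionParams(f_max=f_max, l_r=l_r, sigma_r=sigma_r)
        rows = []
        for i in range(40):
            for w in range(22):
                l = time_to_length(7.0 * w, self.truth_growth)
                rows.append(
                    _row(f"f{i}", w, l, offspring=scale * rng.poisson(fecundity(l, rp)))
                )
        return _table(rows)

    def test_parameter_recovery_within_three_ses(self):
        tbl = self._brood_table(seed=5)
        fit = fit_reproduction(tbl, self.truth_growth)
        for name, truth in (("f_max", 5.46), ("l_r", 8.43), ("sigma_r", 0.8)):
            assert abs(fit.params[name] - truth) <= 3 * fit.ses[name], name

    def test_amplitude_linear_in_counts(self):
        t1 = self._brood_table(seed=6)
        t2 = t1.copy()
        t2["offspring_count"] = 2.0 * t2["offspring_count"]
        f1 = fit_reproduction(t1, self.truth_growth)
        f2 = fit_reproduction(t2, self.truth_growth)
        # the variance-weighting floor for near-zero means breaks exact
        # scale equivariance; 1 % is the observed residual effect
        assert f2.params["f_max"] == pytest.approx(2 * f1.params["f_max"], rel=1e-2)
        assert f2.params["l_r"] == pytest.approx(f1.params["l_r"], rel=1e-3)
        assert f2.params["sigma_r"] == pytest.approx(f1.params["sigma_r"], rel=1e-2)

    def test_all_zero_broods_flagged(self):
        tbl = _table([_row("a", w, 5.0, offspring=0.0) for w in range(21)])
        fit = fit_reproduction(tbl, self.truth_growth)
        assert fit.params["f_max"] == 0.0
        assert "all_zero_broods" in fit.flags


class TestFitMortality:
    growth = GrowthParams(variant="G2", rho=0.032, l_max=9.7)

    def _cohort_table(self, weekly_survival):
        rows = []
        n = 72.0
        for w in range(22):
            alive = int(round(n * weekly_survival**w))
            for i in range(72):
                rows.append(_row(f"i{i}", w, 5.0, alive=i < alive))
        return _table(rows)

    def test_constant_weekly_survival_closed_form(self):
        s = 0.96
        fit = fit_mortality(self._cohort_table(s), self.growth)
        assert fit.params["mu"] == pytest.approx(-np.log(s) / 7.0, rel=0.02)

    def test_no_deaths_hits_lower_boundary(self):
        fit = fit_mortality(self._cohort_table(1.0), self.growth)
        assert fit.params["mu"] <= 1e-4

    def test_recovery_on_synthetic_cohort(self, ref_params):
        from idopspm import SynthConfig, generate_rearing_experiment

        truth = ref_params["granulosa"]
        tbl = generate_rearing_experiment(SynthConfig(truth=truth, rng_seed=11))
        fit = fit_mortality(tbl[tbl.sex == "f"], truth.female.growth)
        assert abs(fit.params["mu"] - 5.7e-3) <= 3 * fit.ses["mu"]
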