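"""Unit and property tests of the individual-level rate kernels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from idopspm import (
    GrowthParams,
    LengthGrid,
    PredationParams,
    ReproductionParams,
)
from idopspm.process_models import (
    birth_source,
    cannibalism_rate,
    fecundity,
    growth_rate,
    intraguild_rate,
    mortality_rate,
    terrestrial_rate,
    vulnerability,
    volume_weighted_vulnerability,
)


class TestGrowthRate:
    @pytest.mark.parametrize(
        "l, kwargs, expected",
        [
            # logistic growth vanishes at the maximal length
            (16.8, dict(variant="G2", rho=8.8e-2, l_max=16.8), 0.0),
            # half the maximal length: rho * l/2 * 1/2
            (8.4, dict(variant="G2", rho=8.8e-2, l_max=16.8), 0.3696),
            # von Bertalanffy at birth length zero
            (0.0, dict(variant="G1", rho=0.1, l_max=20.0), 2.0),
        ],
    )
    def test_pointwise_values(self, l, kwargs, expected):
        assert growth_rate(l, GrowthParams(**kwargs)) == pytest.approx(expected)

    def test_size_dependent_rate_saturates_to_adult_rate(self):
        gp = GrowthParams(
            variant="G4", rho_j=0.01, rho_a=0.08, l_crit=3.8, beta=2.0, l_max=1e6
        )
        l = 200.0  # far above l_crit, far below l_max
        implied_rho = growth_rate(l, gp) / (l * (1 - l / gp.l_max))
        assert implied_rho == pytest.approx(gp.rho_a, rel=1e-6)

    def test_negative_only_beyond_l_max(self):
        gp = GrowthParams(variant="G2", rho=0.05, l_max=10.0)
        l = np.linspace(0, 12, 200)
        g = growth_rate(l, gp)
        assert np.all(g[l <= 10.0] >= 0.0)
        assert np.all(g[l > 10.0] < 0.0)

    def test_unknown_variant_is_configuration_error(self):
        with pytest.raises(ValueError):
            GrowthParams(variant="G9", rho=0.1, l_max=10.0)

    def test_g4_requires_shape_parameters(self):
        with pytest.raises(ValueError):
            GrowthParams(variant="G4", rho_j=0.01, rho_a=0.08, l_max=10.0)


class TestMortality:
    def test_basic_and_senile_branches(self):
        from idopspm import MortalityParams

        mp = MortalityParams(mu=6.4e-4, mu_s=1.28e-3, delta_s=2.0)
        assert mortality_rate(5.0, mp, l_max=16.8) == pytest.approx(6.4e-4)
        assert mortality_rate(16.0, mp, l_max=16.8) == pytest.approx(1.28e-3)

    def test_senile_window_off_by_default(self):
        from idopspm import MortalityParams

        mp = MortalityParams(mu=1e-3)
        l = np.linspace(0, 16.7, 50)
        assert np.allclose(mortality_rate(l, mp, l_max=16.8), 1e-3)


class TestReproduction:
    rp = ReproductionParams(f_max=21.0, l_r=16.3, sigma_r=0.39)

    def test_fecundity_integrates_to_amplitude(self):
        total, _ = quad(lambda l: fecundity(l, self.rp), 0, 40)
        assert total == pytest.approx(21.0, rel=1e-6)

    def test_fecundity_symmetric_with_peak_at_l_r(self):
        assert fecundity(16.3 + 0.3, self.rp) == pytest.approx(
            fecundity(16.3 - 0.3, self.rp)
        )
        peak = 21.0 / (0.39 * np.sqrt(2 * np.pi))
        assert fecundity(16.3, self.rp) == pytest.approx(peak)
        assert peak == pytest.approx(21.48, abs=0.01)

    def test_birth_source_conserves_total_birth_rate(self, grid):
        u_f = np.exp(-0.5 * ((grid.centers - 14.0) / 2.0) ** 2)
        r = birth_source(u_f, self.rp, grid)
        b = fecundity(grid.centers, self.rp)
        total_per_day = np.trapezoid(b * u_f, grid.centers) / 7.0
        assert np.sum(r) * grid.dl == pytest.approx(total_per_day, rel=1e-6)

    def test_birth_source_zero_for_empty_population(self, grid):
        assert np.all(birth_source(np.zeros(grid.n_cells), self.rp, grid) == 0.0)

    def test_birth_source_rejects_negative_density(self, grid):
        u = np.zeros(grid.n_cells)
        u[5] = -1.0
        with pytest.raises(ValueError):
            birth_source(u, self.rp, grid)

    def test_point_mass_mother_yields_peak_rate(self, grid):
        # unit point mass at l_r: B equals b(l_r) (per week) within
        # quadrature error of the single-cell representation
        u_f = np.zeros(grid.n_cells)
        i = np.argmin(np.abs(grid.centers - 16.3))
        u_f[i] = 1.0 / grid.dl
        r = birth_source(u_f, self.rp, grid)
        assert np.sum(r) * grid.dl * 7.0 == pytest.approx(
            fecundity(grid.centers[i], self.rp), rel=1e-6
        )


class TestVulnerability:
    pp = PredationParams(lambda_min=15.0, delta_min=1.0, lambda_u=25.0, s_range=20.0)

    @pytest.mark.parametrize(
        "lam, Lam, expected",
        [
            (3.0, 15.0, 0.0),  # predator not above the minimum size
            (14.5, 15.2, 0.0),  # predator not enough larger than prey
            (5.0, 17.0, 0.65),  # on the linear ramp: (17-5+1)/20
            (5.0, 30.0, 1.0),  # above lambda_u: ramp evaluated at 25, capped
        ],
    )
    def test_branches(self, lam, Lam, expected):
        assert vulnerability(lam, Lam, self.pp) == pytest.approx(expected)

    @settings(max_examples=200, derandomize=True)
    @given(
        lam=st.floats(0.0, 40.0),
        Lam=st.floats(0.0, 60.0),
        delta_min=st.floats(0.0, 5.0),
        s_range=st.floats(0.5, 30.0),
    )
    def test_bounded_in_unit_interval(self, lam, Lam, delta_min, s_range):
        pp = PredationParams(
            lambda_min=10.0, delta_min=delta_min, lambda_u=25.0, s_range=s_range
        )
        a = float(vulnerability(lam, Lam, pp))
        assert 0.0 <= a <= 1.0

    def test_nondecreasing_in_predator_length_on_ramp(self):
        pp = PredationParams(lambda_min=10.0, delta_min=1.0, lambda_u=30.0, s_range=15.0)
        lam = 8.0
        Lams = np.linspace(lam + pp.delta_min + 1e-6, pp.lambda_u, 300)
        a = vulnerability(np.full_like(Lams, lam), Lams, pp)
        assert np.all(np.diff(a) >= -1e-12)


class TestPredationKernels:
    pp = PredationParams(
        upsilon=0.3, upsilon_ig=0.2, tau=0.1,
        lambda_min=15.0, delta_min=2.0, lambda_u=25.0, s_range=10.0, l_p=12.0,
    )

    def _point_masses(self, grid, spec):
        u = np.zeros(grid.n_cells)
        for l, mass in spec:
            u[np.argmin(np.abs(grid.centers - l))] += mass / grid.dl
        return u

    def test_no_predators_below_minimum_size(self, grid):
        u = self._point_masses(grid, [(5.0, 1.0), (12.0, 2.0)])
        rate = cannibalism_rate(grid.centers, u, np.zeros_like(u), self.pp, grid)
        assert np.all(rate == 0.0)

    def test_volume_weighted_two_point_masses(self, grid):
        # predators at 10 mm (alpha = 0 for all prey: below lambda_min) and
        # 20 mm (alpha = 1 for small prey); equal abundance
        u = self._point_masses(grid, [(10.0, 1.0), (20.0, 1.0)])
        l10 = grid.centers[np.argmin(np.abs(grid.centers - 10.0))]
        l20 = grid.centers[np.argmin(np.abs(grid.centers - 20.0))]
        rate = cannibalism_rate(np.array([2.0]), u, np.zeros_like(u), self.pp, grid)
        expected = self.pp.upsilon * l20**3 / (l10**3 + l20**3)
        assert rate[0] == pytest.approx(expected, rel=1e-12)

    def test_degree_zero_homogeneity(self, grid):
        rng = np.random.default_rng(0)
        u_f = rng.random(grid.n_cells)
        u_m = rng.random(grid.n_cells)
        r1 = cannibalism_rate(grid.centers, u_f, u_m, self.pp, grid)
        r2 = cannibalism_rate(grid.centers, 37.5 * u_f, 37.5 * u_m, self.pp, grid)
        assert np.allclose(r1, r2, rtol=1e-12)

    def test_empty_population_returns_zero(self, grid):
        z = np.zeros(grid.n_cells)
        assert np.all(cannibalism_rate(grid.centers, z, z, self.pp, grid) == 0.0)

    def test_intraguild_pooled_degenerates_to_cannibalism(self, grid):
        rng = np.random.default_rng(1)
        u_f, u_m = rng.random(grid.n_cells), rng.random(grid.n_cells)
        z = np.zeros(grid.n_cells)
        pooled = intraguild_rate(
            grid.centers, (u_f, u_m), (z, z), self.pp, grid, pool="both"
        )
        cann = cannibalism_rate(grid.centers, u_f, u_m, self.pp, grid)
        assert np.allclose(pooled, cann * self.pp.upsilon_ig / self.pp.upsilon)

    def test_intraguild_cross_pool_vanishes_without_other_species(self, grid):
        rng = np.random.default_rng(2)
        u_f, u_m = rng.random(grid.n_cells), rng.random(grid.n_cells)
        z = np.zeros(grid.n_cells)
        assert np.all(
            intraguild_rate(grid.centers, (u_f, u_m), (z, z), self.pp, grid) == 0.0
        )

    def test_prey_above_all_predators_is_safe(self, grid):
        u = self._point_masses(grid, [(20.0, 1.0)])
        z = np.zeros(grid.n_cells)
        rate = intraguild_rate(
            np.array([19.0]), (z, z), (u, z), self.pp, grid
        )
        assert rate[0] == 0.0  # 20 <= 19 + delta_min

    def test_terrestrial_threshold_inclusive(self):
        assert terrestrial_rate(11.999, self.pp) == 0.0
        assert terrestrial_rate(12.0, self.pp) == pytest.approx(self.pp.tau)
        pp0 = PredationParams(tau=0.0, l_p=12.0)
        assert terrestrial_rate(30.0, pp0) == 0.0
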