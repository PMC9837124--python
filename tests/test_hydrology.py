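"""Unit tests for the single-column water balance: profile
classification, retention curves, conductivity, pedo-transfer, potential
ET, the daily step and the WTD / near-surface diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from peatfire.hydrology import (
    ColumnState,
    DailyForcing,
    HydrologyError,
    InvalidProfileError,
    RetentionFitError,
    SoilColumn,
    SoilLayer,
    classify_profile,
    diagnose_wtd,
    fit_retention,
    k_unsat,
    near_surface_moisture,
    pedotransfer_ksat,
    potential_et,
    psi_of_theta,
    step_day,
    theta_of_psi,
)
from conftest import make_column, make_layer


def forcing(precip=0.0, tair=27.0, radiation=18.0, rh=80.0, wind=2.0):
    return DailyForcing(date=None, precip=precip, tair=tair,
                        radiation=radiation, rh=rh, wind=wind)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TestClassifyProfile:
    def _column(self, om_by_layer, thickness=0.1):
        layers = tuple(make_layer(om_fraction=om, thickness=thickness)
                       for om in om_by_layer)
        return SoilColumn(layers=layers)

    def test_uniform_peat_to_depth_is_peatland(self):
        assert classify_profile(self._column([0.70] * 10)) == "peatland_grid"

    def test_om_below_threshold_is_non_peatland(self):
        assert classify_profile(self._column([0.60] * 10)) == "non_peatland_grid"

    def test_peat_shallower_than_03m_is_non_peatland(self):
        # peat only in the top 0.2 m, mineral below
        om = [0.70, 0.70] + [0.50] * 8
        assert classify_profile(self._column(om)) == "non_peatland_grid"

    def test_exactly_03m_of_peat_qualifies(self):
        om = [0.70, 0.70, 0.70] + [0.50] * 7
        assert classify_profile(self._column(om)) == "peatland_grid"

    def test_empty_profile_raises(self):
        with pytest.raises(InvalidProfileError):
            SoilColumn(layers=())

    def test_total_shallower_than_requirement_is_non_peatland(self):
        assert classify_profile(self._column([0.9, 0.9], thickness=0.1)) \
            == "non_peatland_grid"


# ---------------------------------------------------------------------------
# retention / conductivity
# ---------------------------------------------------------------------------

class TestRetention:
    def test_saturation_limit(self, mineral_layer):
        assert theta_of_psi(mineral_layer, 0.0) == pytest.approx(mineral_layer.theta_s)

    def test_dry_asymptote(self, mineral_layer):
        assert theta_of_psi(mineral_layer, 1e9) == pytest.approx(
            mineral_layer.theta_r, abs=1e-4)

    def test_closed_form_value(self):
        # theta_r=0.1, theta_s=0.8, alpha=2, n=2, psi=0.5:
        # 0.1 + 0.7 * (1 + (2*0.5)^2)^(-1/2) = 0.1 + 0.7/sqrt(2)
        layer = make_layer(theta_r=0.1, theta_s=0.8, vg_alpha=2.0, vg_n=2.0)
        assert theta_of_psi(layer, 0.5) == pytest.approx(0.1 + 0.7 / np.sqrt(2), rel=1e-12)

    def test_negative_suction_rejected(self, mineral_layer):
        with pytest.raises(HydrologyError):
            theta_of_psi(mineral_layer, -0.1)

    def test_strictly_decreasing(self, peat_layer):
        psis = np.linspace(0.0, 5.0, 50)
        thetas = [theta_of_psi(peat_layer, p) for p in psis]
        assert np.all(np.diff(thetas) < 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        theta_r=st.floats(0.01, 0.2),
        porosity_gap=st.floats(0.2, 0.7),
        alpha=st.floats(0.5, 10.0),
        n=st.floats(1.1, 3.0),
        se=st.floats(0.01, 0.99),
    )
    def test_round_trip(self, theta_r, porosity_gap, alpha, n, se):
        layer = make_layer(theta_r=theta_r, theta_s=theta_r + porosity_gap,
                           vg_alpha=alpha, vg_n=n)
        theta = theta_r + se * porosity_gap
        assert theta_of_psi(layer, psi_of_theta(layer, theta)) \
            == pytest.approx(theta, abs=1e-8)


class TestConductivity:
    def test_saturated_limit(self, peat_layer):
        assert k_unsat(peat_layer, peat_layer.theta_s) == pytest.approx(peat_layer.ksat)

    def test_residual_limit(self, peat_layer):
        assert k_unsat(peat_layer, peat_layer.theta_r) == pytest.approx(0.0)

    def test_out_of_range_rejected(self, peat_layer):
        with pytest.raises(HydrologyError):
            k_unsat(peat_layer, peat_layer.theta_s + 0.05)

    def test_monotone_in_theta(self, mineral_layer):
        thetas = np.linspace(mineral_layer.theta_r, mineral_layer.theta_s, 40)
        ks = [k_unsat(mineral_layer, t) for t in thetas]
        assert np.all(np.diff(ks) >= 0)

    @pytest.mark.parametrize("se", [0.3, 0.5, 0.8])
    def test_matches_mualem_quadrature(self, mineral_layer, se):
        """Closed form equals numeric evaluation of the Mualem integral
        k/ksat = sqrt(Se) * (int_0^Se dx/psi(x) / int_0^1 dx/psi(x))^2,
        integrated in the substituted variable u = x^(1/m) where the
        integrand m*u^(m-1+1/n)*(1-u)^(-1/n) has a mild endpoint
        singularity that quadrature resolves."""
        lay = mineral_layer
        n = lay.vg_n
        m = 1.0 - 1.0 / n

        def integrand(u):
            return m * u ** (m - 1.0 + 1.0 / n) * (1.0 - u) ** (-1.0 / n)

        num, _ = quad(integrand, 0, se ** (1.0 / m), limit=200)
        den, _ = quad(integrand, 0, 1, limit=200)
        expected = lay.ksat * np.sqrt(se) * (num / den) ** 2
        theta = lay.theta_r + se * (lay.theta_s - lay.theta_r)
        assert k_unsat(lay, theta) == pytest.approx(expected, rel=1e-4)


class TestFitRetention:
    PARAMS = (0.08, 0.82, 3.0, 1.5)

    def _samples(self, psis, noise=0.0, rng=None):
        layer = make_layer(theta_r=self.PARAMS[0], theta_s=self.PARAMS[1],
                           vg_alpha=self.PARAMS[2], vg_n=self.PARAMS[3])
        thetas = np.array([theta_of_psi(layer, p) for p in psis])
        if noise:
            thetas = thetas + rng.normal(0.0, noise * thetas)
        return list(zip(psis, thetas))

    def test_noise_free_recovery_within_1pct(self):
        psis = np.concatenate([[0.0], np.logspace(-2, 2.2, 14)])
        fitted = fit_retention(self._samples(psis))
        for got, want in zip(fitted, self.PARAMS):
            assert got == pytest.approx(want, rel=0.01)

    def test_underdetermined_rejected(self):
        with pytest.raises(RetentionFitError):
            fit_retention(self._samples([0.0, 0.5, 5.0]))

    def test_degenerate_rejected(self):
        with pytest.raises(RetentionFitError):
            fit_retention([(p, 0.4) for p in [0.0, 0.1, 1.0, 10.0]])

    def test_noisy_recovery_within_10pct_over_100_seeds(self):
        psis = np.concatenate([[0.0], np.logspace(-2, 2.2, 11)])
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fitted = fit_retention(self._samples(psis, noise=0.01, rng=rng))
            errs.append([abs(g - w) / w for g, w in zip(fitted, self.PARAMS)])
        # mean relative error per parameter stays within 10%
        assert np.mean(errs, axis=0).max() < 0.10


class TestPedotransfer:
    def test_monotone_decreasing_in_bulk_density(self):
        assert pedotransfer_ksat(0.08, 0.9, True) > pedotransfer_ksat(0.20, 0.9, True)
        assert pedotransfer_ksat(1.1, 0.05, False) > pedotransfer_ksat(1.5, 0.05, False)

    def test_deterministic(self):
        assert pedotransfer_ksat(0.1, 0.9, True) == pedotransfer_ksat(0.1, 0.9, True)

    def test_default_peat_formula(self):
        # 10^(2.2 - 14*0.1) = 10^0.8, inside the clamp range
        assert pedotransfer_ksat(0.1, 0.9, True) == pytest.approx(10 ** 0.8)

    def test_clamped_to_range(self):
        assert pedotransfer_ksat(0.5, 0.9, True) == pytest.approx(0.001)
        assert pedotransfer_ksat(0.01, 0.9, True) == pytest.approx(50.0)

    def test_nonpositive_bd_rejected(self):
        with pytest.raises(HydrologyError):
            pedotransfer_ksat(0.0, 0.9, True)


class TestPotentialET:
    def test_no_demand(self):
        assert potential_et(forcing(radiation=0.0, rh=100.0, wind=0.0), 1.0) \
            == pytest.approx(0.0, abs=1e-9)

    def test_linear_in_coefficient(self):
        f = forcing()
        assert potential_et(f, 1.6) == pytest.approx(2 * potential_et(f, 0.8))

    def test_reference_day_matches_hand_value(self):
        # T=25 C, RH=70%, Rs=20 MJ/m2/d, u2=2 m/s; hand-evaluated
        # Penman-Monteith with Rn = 0.77*Rs - 2 gives 4.70 mm/d
        f = forcing(tair=25.0, radiation=20.0, rh=70.0, wind=2.0)
        assert potential_et(f, 1.0) * 1000 == pytest.approx(4.70, rel=0.02)

    def test_bad_humidity_rejected(self):
        with pytest.raises(HydrologyError):
            potential_et(forcing(rh=130.0), 1.0)


# ---------------------------------------------------------------------------
# daily step and diagnostics
# ---------------------------------------------------------------------------

def equilibrium_state(column: SoilColumn) -> ColumnState:
    """Theta at field capacity above wtdx, saturated below; litter at its
    field capacity: an exact fixed point under zero forcing."""
    from peatfire.engine import ColumnBatch

    batch = ColumnBatch.from_columns([column])
    theta = batch.theta_fc[0].copy()
    tops = batch.depth_bot[0] - batch.thick[0]
    theta[tops >= column.wtdx] = batch.theta_s[0][tops >= column.wtdx]
    return ColumnState(theta=theta, wtd=column.wtdx)


class TestStepDay:
    def test_equilibrium_is_fixed_point(self):
        column = make_column(wtdx=0.5)
        state = equilibrium_state(column)
        new, ledger = step_day(column, state, forcing(radiation=0.0, rh=100.0, wind=0.0))
        assert np.allclose(new.theta, state.theta, atol=1e-12)
        for term in (ledger.precip, ledger.et_actual, ledger.lateral_flux,
                     ledger.runoff, ledger.delta_storage):
            assert term == pytest.approx(0.0, abs=1e-12)

    def test_rain_only_goes_to_storage(self):
        # dry column, boundary at the column base -> wtd == wtdx, no
        # lateral flow, no runoff: 20 mm of rain is all storage gain
        column = make_column(n_layers=10, thickness=0.1, wtdx=1.0)
        batch_theta = np.full(10, 0.2)
        state = ColumnState(theta=batch_theta, wtd=1.0)
        new, ledger = step_day(column, state, forcing(precip=20.0, radiation=0.0,
                                                      rh=100.0, wind=0.0))
        assert ledger.delta_storage == pytest.approx(0.020, abs=1e-9)
        assert ledger.lateral_flux == pytest.approx(0.0, abs=1e-12)
        assert ledger.runoff == pytest.approx(0.0)

    def test_negative_precip_rejected(self):
        column = make_column()
        state = equilibrium_state(column)
        with pytest.raises(HydrologyError):
            step_day(column, state, forcing(precip=-1.0))

    def test_ledger_closes_for_wet_day(self):
        column = make_column(wtdx=0.3)
        state = equilibrium_state(column)
        _, ledger = step_day(column, state, forcing(precip=35.0))
        assert abs(ledger.residual) < 1e-9

    def test_substep_refinement(self):
        """Halving the internal sub-step (24 vs 48) changes the WTD after
        a rainy fortnight by less than the configured refinement
        tolerance (numerical convergence of the explicit scheme)."""
        from peatfire.orchestration import RunConfig

        tol = RunConfig().substep_refinement_tol_m
        column = make_column(wtdx=0.8)
        rng = np.random.default_rng(7)
        rain = rng.gamma(0.9, 12.0, 14) * (rng.random(14) < 0.5)
        coarse = equilibrium_state(column)
        fine = equilibrium_state(column)
        for p in rain:
            coarse, _ = step_day(column, coarse, forcing(precip=p), sub_steps=24)
            fine, _ = step_day(column, fine, forcing(precip=p), sub_steps=48)
        assert abs(coarse.wtd - fine.wtd) < tol

    def test_lateral_sign_follows_boundary_gradient(self):
        # boundary deeper than the water table -> discharge (positive)
        column = make_column(wtdx=0.9)
        state = equilibrium_state(make_column(wtdx=0.5))  # water table at 0.5
        _, ledger = step_day(column, state, forcing(radiation=0.0, rh=100.0, wind=0.0))
        assert ledger.lateral_flux > 0
        # boundary shallower -> recharge (negative)
        column2 = make_column(wtdx=0.1)
        state2 = equilibrium_state(make_column(wtdx=0.5))
        _, ledger2 = step_day(column2, state2, forcing(radiation=0.0, rh=100.0, wind=0.0))
        assert ledger2.lateral_flux < 0


class TestDiagnoseWtd:
    def test_fully_saturated_is_zero(self):
        column = make_column()
        state = ColumnState(theta=np.full(10, column.layers[0].theta_s))
        assert diagnose_wtd(column, state) == 0.0

    def test_ponded_is_zero(self):
        column = make_column()
        state = ColumnState(theta=np.full(10, 0.2), ponded=0.01)
        assert diagnose_wtd(column, state) == 0.0

    def test_saturated_from_06m_down(self):
        column = make_column(n_layers=10, thickness=0.1)
        from peatfire.engine import ColumnBatch

        fc = ColumnBatch.from_columns([column]).theta_fc[0]
        theta = fc.copy()  # at field capacity: zero interpolated saturation
        theta[6:] = column.layers[0].theta_s
        assert diagnose_wtd(column, ColumnState(theta=theta)) == pytest.approx(0.6)

    def test_no_saturation_caps_at_total_depth(self):
        column = make_column(n_layers=10, thickness=0.1)
        state = ColumnState(theta=np.full(10, 0.1))
        assert diagnose_wtd(column, state) == pytest.approx(column.total_depth)

    def test_layers_below_diagnosed_wtd_are_saturated(self):
        column = make_column(n_layers=8, thickness=0.1)
        rng = np.random.default_rng(0)
        theta = rng.uniform(0.06, 0.45, 8)
        theta[5:] = column.layers[0].theta_s
        wtd = diagnose_wtd(column, ColumnState(theta=theta))
        depths_top = np.arange(8) * 0.1
        below = depths_top >= wtd
        assert np.all(theta[below] >= 0.999 * column.layers[0].theta_s)


class TestNearSurfaceMoisture:
    def test_uniform(self):
        column = make_column(n_layers=3, thickness=0.03)
        state = ColumnState(theta=np.full(3, 0.5), litter_theta=0.5)
        assert near_surface_moisture(column, state) == pytest.approx(0.5)

    def test_weighted_mean(self):
        column = make_column(n_layers=3, thickness=0.03)
        state = ColumnState(theta=np.array([0.5, 0.8, 0.1]), litter_theta=0.2)
        expected = (0.02 * 0.2 + 0.03 * 0.5 + 0.03 * 0.8) / 0.08
        assert near_surface_moisture(column, state) == pytest.approx(expected)

    def test_bounded_by_extrema(self):
        column = make_column(n_layers=4, thickness=0.03)
        rng = np.random.default_rng(1)
        for _ in range(50):
            vals = rng.uniform(0.05, 0.45, 3)
            state = ColumnState(theta=np.array([vals[1], vals[2], 0.3, 0.3]),
                                litter_theta=vals[0])
            out = near_surface_moisture(column, state)
            assert vals.min() - 1e-12 <= out <= vals.max() + 1e-12

    def test_too_few_layers_rejected(self):
        column = SoilColumn(layers=(make_layer(),))
        state = ColumnState(theta=np.array([0.3]))
        with pytest.raises(HydrologyError):
            near_surface_moisture(column, state)


class TestSoilLayerInvariants:
    @pytest.mark.parametrize("kw", [
        dict(thickness=-0.1), dict(theta_r=0.5, theta_s=0.4),
        dict(vg_n=0.9), dict(ksat=0.0), dict(om_fraction=1.2),
    ])
    def test_invalid_layers_rejected(self, kw):
        with pytest.raises(InvalidProfileError):
            make_layer(**kw)

    def test_peat_flag_follows_om_threshold(self):
        assert make_layer(om_fraction=0.66).is_peat
        assert not make_layer(om_fraction=0.65).is_peat
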