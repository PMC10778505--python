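import numpy as np
import pytest

from sorptherm.constants import R_GAS
from sorptherm.data_model import Branch
from sorptherm.errors import DomainError, ValidationError
from sorptherm.thermodynamics import (
    TrendFamily,
    Verdict,
    build_isosteres,
    compensation,
    default_xe_grid,
    fit_isostere,
    fit_trend,
    gibbs_energy,
    harmonic_mean_temperature,
    integral_heat,
    latent_heat,
    thermo_profile,
)

from conftest import make_fit

TEMPS = (298.15, 308.15, 318.15)


def halsey_clausius_fits(a=0.02, b=20.0, B=1.2, temps=TEMPS, branch=Branch.ADSORPTION):
    """Halsey isotherms with A(T) = a + b/T, so that by construction

        ln aw = -(a + b/T) * xe**(-B)
        qst(xe) = R*b*xe**(-B),   dS(xe) = -R*a*xe**(-B)
    """
    return [make_fit("halsey", (a + b / T, B), T, branch=branch) for T in temps]


def true_qst(xe, b=20.0, B=1.2):
    return R_GAS * b * np.asarray(xe) ** (-B)


def true_ds(xe, a=0.02, B=1.2):
    return -R_GAS * a * np.asarray(xe) ** (-B)


class TestBuildIsosteres:
    def test_construction_round_trip(self):
        fits = halsey_clausius_fits()
        xe_grid = np.linspace(0.08, 0.30, 6)
        table = build_isosteres(fits, xe_grid)
        assert set(table.columns) == {"xe", "T", "aw", "ln_aw", "inv_T"}
        for _, row in table.iterrows():
            A = 0.02 + 20.0 / row["T"]
            expected_lnaw = -A * row["xe"] ** (-1.2)
            assert row["ln_aw"] == pytest.approx(expected_lnaw, abs=1e-9)

    def test_out_of_range_xe_dropped(self):
        fits = halsey_clausius_fits()
        table = build_isosteres(fits, [0.15, 50.0])
        assert set(np.round(table["xe"].unique(), 6)) == {0.15}

    def test_identical_models_give_zero_slope(self):
        fits = [make_fit("oswin", (0.10, 0.41), T) for T in TEMPS]
        table = build_isosteres(fits, [0.05, 0.10])
        for _, sub in table.groupby("xe"):
            qst, ds, _ = fit_isostere(sub["ln_aw"], sub["inv_T"])
            assert qst == pytest.approx(0.0, abs=1e-6)

    def test_fewer_than_three_temperatures_rejected(self):
        fits = halsey_clausius_fits(temps=(298.15, 308.15))
        with pytest.raises(ValidationError):
            build_isosteres(fits, [0.1])


class TestFitIsostere:
    def test_exact_recovery(self):
        qst, ds = 3000.0, 5.0
        invT = np.array([1.0 / T for T in TEMPS])
        lnaw = -qst / R_GAS * invT + ds / R_GAS
        q, s, r2 = fit_isostere(lnaw, invT)
        assert q == pytest.approx(qst, abs=1e-9)
        assert s == pytest.approx(ds, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_two_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_isostere([-1.0, -2.0], [1 / 298.0, 1 / 308.0])

    def test_degenerate_temperatures_rejected(self):
        with pytest.raises(ValidationError):
            fit_isostere([-1.0, -1.1, -1.2], [1 / 298.0] * 3)

    def test_zero_slope_limit(self):
        lnaw = np.array([-1.5, -1.5, -1.5])
        invT = np.array([1.0 / T for T in TEMPS])
        q, s, _ = fit_isostere(lnaw, invT)
        assert q == pytest.approx(0.0, abs=1e-9)
        assert s == pytest.approx(R_GAS * -1.5, rel=1e-9)


class TestLatentHeat:
    def test_hand_value(self):
        assert latent_heat(298.15) == pytest.approx(8.314 * (6687 - 5.31 * 298.15), rel=1e-12)
        assert latent_heat(298.15) == pytest.approx(4.2433e4, rel=1e-3)

    def test_decreasing_in_T(self):
        assert latent_heat(318.15) < latent_heat(298.15)

    def test_root_of_linear_form(self):
        assert latent_heat(6687.0 / 5.31) == pytest.approx(0.0, abs=1e-6)

    def test_out_of_range_warns_but_returns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            val = latent_heat(500.0)
        assert np.isfinite(val)
        assert any("outside" in r.message for r in caplog.records)


class TestIntegralHeat:
    def test_zero_net_heat(self):
        assert integral_heat(0.0, 307.8) == pytest.approx(latent_heat(307.8))

    def test_composition(self):
        assert integral_heat(500.0, 307.8) == pytest.approx(500.0 + latent_heat(307.8))

    def test_linearity(self):
        a, b, t = 300.0, 700.0, 305.0
        assert integral_heat(a, t) + integral_heat(b, t) - latent_heat(t) == pytest.approx(
            integral_heat(a + b, t)
        )


class TestGibbsEnergy:
    def test_zero_at_unity(self):
        assert gibbs_energy(298.15, 1.0) == 0.0

    def test_hand_value(self):
        assert gibbs_energy(298.15, 0.5) == pytest.approx(8.314 * 298.15 * np.log(2), rel=1e-12)

    def test_log_identity(self):
        assert gibbs_energy(298.15, 0.25) == pytest.approx(2 * gibbs_energy(298.15, 0.5))

    def test_positive_below_unity(self, rng):
        aw = rng.uniform(0.01, 0.99, 50)
        assert np.all(gibbs_energy(310.0, aw) > 0)

    def test_decreasing_in_aw(self):
        aw = np.linspace(0.05, 0.95, 50)
        dg = gibbs_energy(298.15, aw)
        assert np.all(np.diff(dg) < 0)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            gibbs_energy(298.15, 0.0)
        with pytest.raises(DomainError):
            gibbs_energy(298.15, -0.5)


class TestFitTrend:
    def test_power_recovery(self):
        x = np.linspace(0.05, 0.4, 12)
        y = 41.16 * x**-0.014
        fit = fit_trend(x, y, TrendFamily.POWER)
        assert fit.coefficients["a"] == pytest.approx(41.16, rel=1e-8)
        assert fit.coefficients["b"] == pytest.approx(-0.014, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0)

    def test_log_recovery(self):
        x = np.linspace(0.05, 0.4, 12)
        y = -1.54 * np.log(x) - 3.12
        fit = fit_trend(x, y, "log")
        assert fit.coefficients["a"] == pytest.approx(-1.54, rel=1e-10)
        assert fit.coefficients["c"] == pytest.approx(-3.12, rel=1e-10)

    def test_exp_recovery(self):
        x = np.linspace(0.05, 0.4, 12)
        y = 5.04 * np.exp(-11.8 * x)
        fit = fit_trend(x, y, TrendFamily.EXP)
        assert fit.coefficients["a"] == pytest.approx(5.04, rel=1e-8)
        assert fit.coefficients["b"] == pytest.approx(-11.8, rel=1e-8)

    def test_constant_y_power_gives_zero_exponent(self):
        x = np.linspace(0.05, 0.4, 10)
        fit = fit_trend(x, np.full(10, 3.0), TrendFamily.POWER)
        assert fit.coefficients["b"] == pytest.approx(0.0, abs=1e-6)

    def test_domain_mismatch(self):
        with pytest.raises(ValidationError):
            fit_trend([-0.1, 0.2, 0.3], [1, 2, 3], TrendFamily.POWER)

    def test_linear(self):
        x = np.linspace(0, 1, 5)
        fit = fit_trend(x, 2.0 * x + 1.0, TrendFamily.LINEAR)
        assert fit.coefficients["a"] == pytest.approx(2.0)
        assert fit.coefficients["c"] == pytest.approx(1.0)


class TestCompensation:
    def test_harmonic_mean_of_study_temperatures(self):
        assert harmonic_mean_temperature([298, 308, 318]) == pytest.approx(307.8, abs=0.05)

    def test_exact_line(self):
        ds = np.linspace(-10, 10, 5)
        dh = 400.0 * ds + 300.0
        res = compensation(dh, ds, [298.0, 308.0, 318.0])
        assert res.T_beta == pytest.approx(400.0, abs=1e-9)
        assert res.dG_beta == pytest.approx(300.0, abs=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.verdict is Verdict.ENTHALPY_DRIVEN

    def test_entropy_driven(self):
        ds = np.linspace(-10, 10, 5)
        dh = 200.0 * ds + 100.0
        res = compensation(dh, ds, [298.0, 308.0, 318.0])
        assert res.verdict is Verdict.ENTROPY_DRIVEN

    def test_indeterminate_on_weak_fit(self, rng):
        ds = np.linspace(-10, 10, 30)
        dh = rng.normal(0, 1000, 30)  # no relation
        res = compensation(dh, ds, [298.0, 308.0, 318.0])
        assert res.verdict is Verdict.INDETERMINATE

    def test_slope_equals_cov_over_var(self, rng):
        ds = rng.normal(0, 3, 40)
        dh = rng.normal(1000, 500, 40)
        res = compensation(dh, ds, [300.0, 310.0, 320.0], r2_min=0.0)
        expected = np.cov(dh, ds, bias=True)[0, 1] / np.var(ds)
        assert res.T_beta == pytest.approx(expected, rel=1e-9)

    def test_hm_am_inequality(self, rng):
        temps = rng.uniform(250, 400, 10)
        assert harmonic_mean_temperature(temps) <= np.mean(temps)
        assert harmonic_mean_temperature([300.0] * 4) == pytest.approx(300.0)

    def test_zero_variance_ds_rejected(self):
        with pytest.raises(ValidationError):
            compensation([1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [298.0, 308.0, 318.0])


class TestThermoProfile:
    def test_end_to_end_recovery_from_matching_model(self):
        # fits match the generating family exactly, so the isostere
        # regression must reproduce the constructed profiles to high accuracy
        fits = halsey_clausius_fits()
        xe_grid = np.linspace(0.08, 0.30, 8)
        profile = thermo_profile(fits, xe_grid=xe_grid)
        np.testing.assert_allclose(profile.qst, true_qst(xe_grid), rtol=1e-3)
        np.testing.assert_allclose(profile.dS, true_ds(xe_grid), rtol=1e-3)
        assert np.all(profile.r2_per_xe > 0.999)
        # positive heat, decreasing with moisture
        assert np.all(profile.qst > 0)
        assert np.all(np.diff(profile.qst) < 0)
        # integral heat offsets by the latent heat at T_ref
        np.testing.assert_allclose(
            profile.Qst, profile.qst + latent_heat(profile.T_ref), rtol=1e-12
        )
        # Gibbs energies positive below saturation
        assert np.all(profile.dG["dG"] > 0)

    def test_default_xe_grid_common_support(self):
        fits = halsey_clausius_fits()
        grid = default_xe_grid(fits, n=10)
        assert grid.size == 10
        assert np.all(np.diff(grid) > 0)
        # every grid point is invertible at every temperature
        table = build_isosteres(fits, grid)
        assert table["xe"].nunique() == 10

    def test_mixed_branches_rejected(self):
        fits = halsey_clausius_fits()[:2] + halsey_clausius_fits(
            temps=(318.15,), branch=Branch.DESORPTION
        )
        with pytest.raises(ValidationError):
            thermo_profile(fits)
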