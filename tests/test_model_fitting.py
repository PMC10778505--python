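import numpy as np
import pytest

from sorptherm.data_model import Branch, FitStatistics, SorptionDataset, SorptionPoint
from sorptherm.errors import ValidationError
from sorptherm.isotherm_models import MODEL_IDS, ModelParams, evaluate_raw
from sorptherm.model_fitting import (
    IsothermFit,
    fit_all_models,
    fit_isotherm,
    goodness_of_fit,
    rank_models,
)

from conftest import make_group


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        obs = [0.01, 0.05, 0.10]
        s = goodness_of_fit(obs, obs)
        assert s.sse == 0.0
        assert s.e_percent == 0.0
        assert s.r2_regression == pytest.approx(1.0)
        assert s.r2_standard == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # (1e-4 + 0 + 1e-4)/3 and (100/3)*(0.5 + 0 + 1/6)
        s = goodness_of_fit([0.02, 0.04, 0.06], [0.03, 0.04, 0.05])
        assert s.sse == pytest.approx(6.666666666666667e-5, rel=1e-12)
        assert s.e_percent == pytest.approx(22.22222222222222, rel=1e-12)

    def test_r2_variants_distinguished(self):
        # constant prediction at the observed mean: regression-SS ratio is 0
        # and so is the conventional R^2, but for a sloped imperfect fit the
        # two differ
        obs = np.array([0.02, 0.04, 0.06])
        pred = np.array([0.025, 0.04, 0.055])
        s = goodness_of_fit(obs, pred)
        assert s.r2_regression == pytest.approx(0.5625)
        assert s.r2_standard == pytest.approx(1.0 - (2 * 0.005**2) / (2 * 0.02**2))
        assert s.r2_regression != s.r2_standard

    def test_constant_mean_prediction(self):
        obs = np.array([0.02, 0.04, 0.06])
        pred = np.full(3, obs.mean())
        s = goodness_of_fit(obs, pred)
        assert s.r2_standard == pytest.approx(0.0)
        assert s.r2_regression == pytest.approx(0.0)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            goodness_of_fit([0.1, 0.2], [0.1])

    def test_single_point_rejected(self):
        with pytest.raises(ValidationError):
            goodness_of_fit([0.1], [0.1])

    def test_zero_observations_excluded_and_flagged(self):
        s = goodness_of_fit([0.0, 0.04, 0.06], [0.01, 0.04, 0.05])
        assert s.n_excluded_e == 1
        assert s.e_percent == pytest.approx(100.0 / 2 * (0.0 + 1.0 / 6.0))

    def test_permutation_invariance(self, rng):
        obs = rng.uniform(0.01, 0.5, 20)
        pred = obs + rng.normal(0, 0.01, 20)
        s1 = goodness_of_fit(obs, pred)
        perm = rng.permutation(20)
        s2 = goodness_of_fit(obs[perm], pred[perm])
        assert s1.sse == pytest.approx(s2.sse, rel=1e-12)
        assert s1.e_percent == pytest.approx(s2.e_percent, rel=1e-12)
        assert s1.r2_standard == pytest.approx(s2.r2_standard, rel=1e-12)


class TestFitIsotherm:
    def test_gab_recovery(self):
        truth = (0.06, 13.83, 0.89)
        group = make_group("gab", truth)
        fit = fit_isotherm(group, "gab", seed=1)
        np.testing.assert_allclose(fit.params.values, truth, rtol=1e-4)
        assert fit.converged

    def test_underdetermined_rejected(self):
        pts = [
            SorptionPoint(0.2, 0.01, 298.15, Branch.ADSORPTION),
            SorptionPoint(0.5, 0.02, 298.15, Branch.ADSORPTION),
        ]
        with pytest.raises(ValidationError):
            fit_isotherm(SorptionDataset(points=pts), "peleg")

    def test_determinism(self):
        group = make_group("gab", (0.06, 13.83, 0.89), noise_sd=0.002, seed=3)
        f1 = fit_isotherm(group, "gab", seed=42)
        f2 = fit_isotherm(group, "gab", seed=42)
        assert f1.params.values == f2.params.values
        assert f1.stats == f2.stats

    def test_single_T_required_for_plain_models(self):
        g1 = make_group("gab", (0.06, 13.83, 0.89), T=298.15)
        g2 = make_group("gab", (0.06, 13.83, 0.89), T=308.15)
        merged = SorptionDataset(points=g1.points + g2.points)
        with pytest.raises(ValidationError):
            fit_isotherm(merged, "gab")

    def test_mixed_branches_rejected(self):
        g1 = make_group("gab", (0.06, 13.83, 0.89), branch=Branch.ADSORPTION)
        g2 = make_group("gab", (0.06, 13.83, 0.89), branch=Branch.DESORPTION)
        merged = SorptionDataset(points=g1.points + g2.points)
        with pytest.raises(ValidationError):
            fit_isotherm(merged, "gab")

    def test_noise_robustness(self):
        # moderate noise degrades but does not break the fit
        for seed in range(20):
            group = make_group("gab", (0.06, 13.83, 0.89), n=30, noise_sd=0.002, seed=seed)
            fit = fit_isotherm(group, "gab", n_starts=8, seed=seed)
            assert fit.stats.r2_standard >= 0.97


def _fit_with_stats(model_id, branch, T, sse, r2, e):
    from sorptherm.isotherm_models import get_spec

    stats = FitStatistics(
        r2_regression=r2, r2_standard=r2, sse=sse, e_percent=e, n_points=20
    )
    n = get_spec(model_id).n_params
    params = ModelParams(model_id, tuple([0.1] * n))
    return IsothermFit(model_id, branch, T, params, stats, True, 1)


class TestRankModels:
    def test_filter_precedence(self):
        # the passing model wins even with larger sse
        fits = [
            _fit_with_stats("gab", Branch.ADSORPTION, 298.15, 1e-4, 0.95, 1.0),
            _fit_with_stats("bet", Branch.ADSORPTION, 298.15, 1e-6, 0.80, 1.0),
        ]
        ranking = rank_models(fits)
        assert ranking.best_model_id == "gab"
        assert ranking.passes_criteria == {"gab": True, "bet": False}

    def test_e_percent_threshold(self):
        fits = [
            _fit_with_stats("gab", Branch.ADSORPTION, 298.15, 1e-6, 0.99, 15.0),
            _fit_with_stats("oswin", Branch.ADSORPTION, 298.15, 1e-4, 0.95, 2.0),
        ]
        assert rank_models(fits).best_model_id == "oswin"

    def test_tie_break_fewer_parameters(self):
        fits = [
            _fit_with_stats("peleg", Branch.ADSORPTION, 298.15, 1e-5, 0.99, 1.0),
            _fit_with_stats("oswin", Branch.ADSORPTION, 298.15, 1e-5, 0.99, 1.0),
        ]
        assert rank_models(fits).best_model_id == "oswin"

    def test_criteria_applied_at_every_temperature(self):
        fits = [
            _fit_with_stats("gab", Branch.ADSORPTION, 298.15, 1e-6, 0.99, 1.0),
            _fit_with_stats("gab", Branch.ADSORPTION, 308.15, 1e-6, 0.85, 1.0),
            _fit_with_stats("oswin", Branch.ADSORPTION, 298.15, 1e-4, 0.95, 2.0),
            _fit_with_stats("oswin", Branch.ADSORPTION, 308.15, 1e-4, 0.95, 2.0),
        ]
        ranking = rank_models(fits)
        assert not ranking.passes_criteria["gab"]
        assert ranking.best_model_id == "oswin"

    def test_no_model_passes_falls_back_to_sse(self):
        fits = [
            _fit_with_stats("gab", Branch.ADSORPTION, 298.15, 1e-4, 0.5, 20.0),
            _fit_with_stats("bet", Branch.ADSORPTION, 298.15, 1e-6, 0.6, 30.0),
        ]
        ranking = rank_models(fits)
        assert ranking.no_model_passed
        assert ranking.best_model_id == "bet"

    def test_mixed_branches_rejected(self):
        fits = [
            _fit_with_stats("gab", Branch.ADSORPTION, 298.15, 1e-4, 0.95, 1.0),
            _fit_with_stats("gab", Branch.DESORPTION, 298.15, 1e-4, 0.95, 1.0),
        ]
        with pytest.raises(ValidationError):
            rank_models(fits)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            rank_models([])


class TestFitAllModels:
    def test_subset_of_models_all_groups(self):
        g = {}
        pts = []
        for T in (298.15, 308.15, 318.15):
            grp = make_group("gab", (0.06, 13.83, 0.89), T=T)
            pts.extend(grp.points)
        ds = SorptionDataset(points=pts)
        fits = fit_all_models(ds, model_ids=["gab", "oswin", "mod_oswin"], n_starts=8, seed=2)
        # 3 models x 3 temperatures, one branch
        assert len(fits) == 9
        assert {f.model_id for f in fits} == {"gab", "oswin", "mod_oswin"}
        # temperature-dependent model shares parameters across temperatures
        mo = sorted((f for f in fits if f.model_id == "mod_oswin"), key=lambda f: f.T)
        assert mo[0].params.values == mo[1].params.values == mo[2].params.values
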