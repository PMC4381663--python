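"""Unit and property tests for the beta / beta-mixture model layer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from symratio import betamodels as bm


class TestLogBetaPdf:
    @pytest.mark.parametrize(
        "x,a,b,expected",
        [
            (0.5, 1.0, 1.0, 0.0),
            (0.5, 2.0, 2.0, math.log(1.5)),
            (0.25, 2.0, 2.0, math.log(1.125)),
        ],
    )
    def test_closed_form_values(self, x, a, b, expected):
        assert bm.log_beta_pdf(x, a, b) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("x,a,b", [(0.0, 2, 2), (1.0, 2, 2), (0.5, 0, 1), (0.5, 1, -1)])
    def test_domain_errors(self, x, a, b):
        with pytest.raises(ValueError):
            bm.log_beta_pdf(x, a, b)


class TestClampRatios:
    def test_boundaries_move_interior_preserved(self):
        out = bm.clamp_ratios([0.0, 0.987, 1.0])
        assert out.tolist() == [0.001, 0.987, 0.999]

    def test_half_copy_policy_uses_total_copies(self):
        out = bm.clamp_ratios([0.0, 1.0], policy="half-copy", total_copies=[500.0, 2000.0])
        assert out[0] == pytest.approx(1 / 1000)
        assert out[1] == pytest.approx(1 - 1 / 4000)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=50)
    def test_idempotent_and_interior(self, values):
        once = bm.clamp_ratios(values)
        assert np.all((once > 0) & (once < 1))
        np.testing.assert_array_equal(bm.clamp_ratios(once), once)


class TestMixtureLoglik:
    def test_uniform_mixture_is_zero(self):
        assert bm.mixture_loglik([0.5], bm.HYPOTHESES["H2"], [0.5, 1, 1, 1, 1]) == 0.0

    def test_single_beta_matches_density(self):
        got = bm.mixture_loglik([0.5], bm.HYPOTHESES["H0"], [2, 2])
        assert got == pytest.approx(math.log(1.5), abs=1e-12)

    def test_matches_per_point_loop(self, rng):
        # independent oracle: plain-python loop with math.lgamma
        x = rng.uniform(0.05, 0.95, size=20)
        params = [0.3, 2.0, 5.0, 8.0, 3.0]

        def beta_pdf(v, a, b):
            lb = math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)
            return math.exp((a - 1) * math.log(v) + (b - 1) * math.log(1 - v) - lb)

        expected = sum(
            math.log(params[0] * beta_pdf(v, *params[1:3]) + (1 - params[0]) * beta_pdf(v, *params[3:]))
            for v in x
        )
        got = bm.mixture_loglik(x, bm.HYPOTHESES["H2"], params)
        assert got == pytest.approx(expected, abs=1e-10)


class TestInformationCriteria:
    @pytest.mark.parametrize(
        "ll,k,n,expected",
        [(0, 2, 30, 4 + 12 / 27), (0, 5, 30, 12.5), (-10, 2, 30, 24 + 12 / 27)],
    )
    def test_aicc_formula(self, ll, k, n, expected):
        assert bm.aicc(ll, k, n) == pytest.approx(expected, abs=1e-12)

    def test_aicc_undefined_for_small_n(self):
        with pytest.raises(ValueError):
            bm.aicc(0.0, 5, 6)

    def test_aicc_approaches_aic_for_large_n(self):
        ll, k, n = -123.4, 5, 10**6
        assert abs(bm.aicc(ll, k, n) - (-2 * ll + 2 * k)) < 1e-3

    def test_weights_symmetry(self):
        np.testing.assert_allclose(bm.akaike_weights([10, 10, 10]), [1 / 3] * 3)

    def test_weights_direct_evaluation(self):
        w = bm.akaike_weights([0, 10])
        np.testing.assert_allclose(w, [0.993307, 0.006693], atol=5e-7)

    def test_weights_empty_errors(self):
        with pytest.raises(ValueError):
            bm.akaike_weights([])

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=6), st.floats(-100, 100))
    @settings(derandomize=True, max_examples=100)
    def test_weights_sum_to_one_and_translation_invariant(self, aiccs, shift):
        w = bm.akaike_weights(aiccs)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(bm.akaike_weights(np.array(aiccs) + shift), w, atol=1e-9)


class TestFitHypothesis:
    def test_h0_recovers_generating_shapes(self):
        rng = np.random.default_rng(1)
        x = bm.clamp_ratios(rng.beta(26.08, 10.89, 1000))
        fit = bm.fit_hypothesis(bm.RatioSample("a", x), bm.HYPOTHESES["H0"])
        assert fit.converged
        assert fit.params[0] == pytest.approx(26.08, rel=0.15)
        assert fit.params[1] == pytest.approx(10.89, rel=0.15)

    def test_h2_loglik_dominates_generating_parameters(self):
        rng = np.random.default_rng(2)
        lo = rng.random(30) < 0.07
        x = bm.clamp_ratios(np.where(lo, rng.beta(3.48, 66.21, 30), rng.beta(10.99, 2.89, 30)))
        sample = bm.RatioSample("b", x)
        fit = bm.fit_hypothesis(sample, bm.HYPOTHESES["H2"])
        truth_ll = bm.mixture_loglik(x, bm.HYPOTHESES["H2"], [0.07, 3.48, 66.21, 10.99, 2.89])
        assert fit.loglik >= truth_ll - 1e-9

    def test_loglik_at_least_every_start(self):
        rng = np.random.default_rng(3)
        x = bm.clamp_ratios(rng.beta(2, 2, 40))
        sample = bm.RatioSample("c", x)
        for name in ("H0", "H1", "H2"):
            spec = bm.HYPOTHESES[name]
            fit = bm.fit_hypothesis(sample, spec)
            for s in bm.default_starts(spec):
                assert fit.loglik >= bm.mixture_loglik(x, spec, s) - 1e-9

    def test_degenerate_identical_sample_flags_boundary(self):
        sample = bm.RatioSample("d", np.full(20, 0.5))
        fit = bm.fit_hypothesis(sample, bm.HYPOTHESES["H1"])
        assert fit.at_boundary or not fit.converged

    def test_h2_components_ordered_by_mean(self, rng):
        x = bm.clamp_ratios(np.concatenate([rng.beta(2, 20, 15), rng.beta(20, 2, 15)]))
        fit = bm.fit_hypothesis(bm.RatioSample("e", x), bm.HYPOTHESES["H2"])
        m = fit.component_means
        assert m[0] <= m[1]

    def test_small_n_raises(self):
        sample = bm.RatioSample("f", np.linspace(0.1, 0.9, 6))
        with pytest.raises(ValueError):
            bm.fit_hypothesis(sample, bm.HYPOTHESES["H2"])

    def test_fitted_mixture_density_integrates_to_one(self, rng):
        x = bm.clamp_ratios(np.concatenate([rng.beta(3, 40, 10), rng.beta(10, 3, 20)]))
        fit = bm.fit_hypothesis(bm.RatioSample("g", x), bm.HYPOTHESES["H2"])
        pi, a1, b1, a2, b2 = fit.params

        def pdf(v):
            return pi * np.exp(bm.log_beta_pdf(v, a1, b1)) + (1 - pi) * np.exp(
                bm.log_beta_pdf(v, a2, b2)
            )

        total, _ = integrate.quad(pdf, 0, 1, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestSelectModel:
    def test_unimodal_interior_sample_prefers_single_population(self):
        rng = np.random.default_rng(10)
        sample = bm.RatioSample("a", rng.beta(5, 5, 30))
        result = bm.select_model(sample)
        assert result.best == "H0"
        assert sum(result.weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_boundary_bimodal_sample_rejects_single_population(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.beta(2, 80, 15), rng.beta(80, 2, 15)])
        result = bm.select_model(bm.RatioSample("b", x))
        assert result.best in ("H1", "H2")
        assert result.weights["H0"] < 0.05

    def test_mixture_sample_supports_recombination_model(self):
        rng = np.random.default_rng(12)
        lo = rng.random(30) < 0.5
        x = np.where(lo, rng.beta(2, 80, 30), rng.beta(12, 4, 30))
        result = bm.select_model(bm.RatioSample("c", x))
        assert result.best == "H2"
        assert result.unambiguous

    def test_small_colony_drops_mixture_with_weight_zero(self):
        sample = bm.RatioSample("d", np.array([0.2, 0.4, 0.5, 0.6, 0.8]))
        with pytest.warns(UserWarning, match="H2 not fitted"):
            result = bm.select_model(sample)
        assert result.weights["H2"] == 0.0
        assert "H2" in result.fit_errors
        assert sum(result.weights.values()) == pytest.approx(1.0, abs=1e-9)


class TestClassifyCells:
    def _colony_e_result(self, values):
        """Model-selection result pinned to the colony-e-style mixture fit."""
        sample = bm.RatioSample("e", np.asarray(values))
        spec = bm.HYPOTHESES["H2"]
        params = np.array([0.51, 16.58, 4.28, 114.8, 2.32])
        n = len(values)
        fit = bm.HypothesisFit(
            spec=spec,
            params=params,
            loglik=0.0,
            aicc=bm.aicc(0.0, 5, n) if n > 6 else np.inf,
            n=n,
            n_starts=1,
            converged=True,
            at_boundary=False,
            best_start=params,
        )
        return bm.ModelSelectionResult(
            colony_id="e", fits={"H2": fit}, weights={"H2": 1.0}, best="H2"
        ), sample

    def test_component_means_set_roles(self):
        result, sample = self._colony_e_result(np.linspace(0.3, 0.99, 10))
        cls = bm.classify_cells(result, sample)
        # means ~0.795 (heterogeneous) and ~0.980 (homogeneous C100)
        assert cls.component_roles == ["heterogeneous", "homogeneous-C100"]
        assert not cls.roles_ambiguous

    def test_codominant_cell_assigned_to_heterogeneous_component(self):
        result, sample = self._colony_e_result([0.5] + [0.9] * 9)
        cls = bm.classify_cells(result, sample)
        assert cls.cell_roles[0] == "heterogeneous"
        assert cls.responsibilities[0, 0] > 0.99
        np.testing.assert_allclose(cls.responsibilities.sum(axis=1), 1.0, atol=1e-12)

    def test_all_high_ratio_cells_give_zero_heterogeneous(self):
        result, sample = self._colony_e_result(np.full(10, 0.995))
        cls = bm.classify_cells(result, sample)
        assert cls.proportion_heterogeneous == 0.0

    def test_u_shaped_component_splits_at_half(self):
        sample = bm.RatioSample("u", np.array([0.01, 0.02, 0.98, 0.99, 0.03, 0.97, 0.5, 0.01]))
        spec = bm.HYPOTHESES["H1"]
        fit = bm.fit_hypothesis(sample, spec)
        result = bm.ModelSelectionResult(
            colony_id="u", fits={"H1": fit}, weights={"H1": 1.0}, best="H1"
        )
        cls = bm.classify_cells(result, sample)
        assert cls.component_roles == ["both-homogeneous"]
        assert cls.proportion_heterogeneous == 0.0
        assert set(cls.cell_roles) == {"homogeneous-C109", "homogeneous-C100"}
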