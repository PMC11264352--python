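import itertools

import numpy as np
import pytest
from scipy.optimize import approx_fprime

from repcost.capture_data import (
    EncounterHistory,
    EncounterHistorySet,
    OccasionSet,
    pool_identical_histories,
    split_histories_for_trapdep,
)
from repcost.multistate_cmr import (
    FitOptions,
    ModelSpec,
    Params,
    aicc,
    akaike_weights,
    build_design,
    fit_model,
    flag_confounded,
    history_loglik,
    pack_histories,
    rank_models,
    selection_cascade,
    split_loglik,
    total_loglik,
    trapdep_test,
    _forward_loglik,
    _loglik_and_grad,
    _pearson_chi2,
)
from repcost.synthetic_data import CmrTruth, simulate_histories

from _oracles import enumerate_history_prob
from conftest import random_params


class TestDesign:
    def test_state_by_time_parameter_count(self):
        occ = OccasionSet.from_years(range(2000, 2014))  # 13 intervals
        d = build_design(ModelSpec(phi="State*Time"), occ)
        assert d.classes["phi"].k == 26

    def test_state_plus_time_parameter_count(self):
        occ = OccasionSet.from_years(range(2000, 2014))
        d = build_design(ModelSpec(phi="State+Time"), occ)
        assert d.classes["phi"].k == 14

    def test_fixed_class_excluded_from_k(self):
        occ = OccasionSet.from_years(range(2000, 2005))
        d = build_design(ModelSpec(phi=".", p=".", psi=".",
                                   fixed=(("p", 1.0), ("psi", 0.0))), occ)
        assert d.k == 1

    def test_single_level_factor_rejected(self):
        occ = OccasionSet.from_years(range(2000, 2005))
        with pytest.raises(ValueError):
            build_design(ModelSpec(phi="TrapClass"), occ)


class TestModelSpec:
    def test_string_round_trip(self):
        spec = ModelSpec(phi="State*Time", p="TrapClass*State*Sex",
                         psi="State")
        assert ModelSpec.from_string(spec.name) == spec


class TestHistoryLoglik:
    def test_single_path(self):
        occ = OccasionSet.from_years([2000, 2001])
        par = Params.constant(occ, phi=[0.5, 0.5], p=[1.0, 1.0],
                              psi=[0.0, 0.0])
        ll = history_loglik(EncounterHistory("a", "M", (1, 1)), occ, par)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_death_only_explanation(self):
        occ = OccasionSet.from_years([2000, 2001])
        par = Params.constant(occ, phi=[0.5, 0.5], p=[1.0, 1.0],
                              psi=[0.3, 0.2])
        ll = history_loglik(EncounterHistory("a", "M", (1, 0)), occ, par)
        assert np.exp(ll) == pytest.approx(0.5, abs=1e-12)

    def test_two_latent_paths(self):
        # enumerated by hand: 1->1->2 and 1->2->2 give 0.02688 + 0.0336
        occ = OccasionSet.from_years([2000, 2001, 2002])
        par = Params.constant(occ, phi=[0.8, 0.7], p=[0.6, 0.5],
                              psi=[0.3, 0.2])
        ll = history_loglik(EncounterHistory("a", "M", (1, 0, 2)), occ, par)
        assert np.exp(ll) == pytest.approx(0.06048, abs=1e-12)

    def test_impossible_observation_is_neg_inf(self):
        occ = OccasionSet.from_years([2000, 2001])
        par = Params.constant(occ, phi=[0.9, 0.9], p=[0.5, 0.5],
                              psi=[0.1, 0.1])
        par.p[1] = 0.0  # state-2 detection structurally impossible
        ll = history_loglik(EncounterHistory("a", "M", (1, 2)), occ, par)
        assert ll == -np.inf


class TestTotalLoglik:
    def test_weight_multiplies(self, occ5):
        rng = np.random.default_rng(1)
        par = random_params(occ5, rng)
        h = EncounterHistory("a", "M", (1, 0, 2, 0, 0))
        one = EncounterHistorySet(occ5, (h,))
        three = EncounterHistorySet(occ5, (h,), (3,))
        assert total_loglik(three, par) == pytest.approx(
            3 * total_loglik(one, par), rel=1e-12)

    def test_permutation_invariance(self, occ5):
        rng = np.random.default_rng(2)
        par = random_params(occ5, rng)
        truth = CmrTruth(Params.constant(
            occ5, phi=[0.8, 0.7], p=[0.6, 0.6], psi=[0.3, 0.2]), seed=3)
        sim = simulate_histories(truth, 50, occ5)
        rev = EncounterHistorySet(occ5, tuple(reversed(sim.histories)))
        assert total_loglik(sim, par) == pytest.approx(
            total_loglik(rev, par), rel=1e-12)

    def test_matches_enumeration_on_simulated_set(self):
        occ = OccasionSet.from_years(range(2000, 2004))
        truth = CmrTruth(Params.constant(
            occ, phi=[0.8, 0.7], p=[0.6, 0.6], psi=[0.3, 0.2]), seed=4)
        sim = simulate_histories(truth, 20, occ)
        rng = np.random.default_rng(5)
        par = random_params(occ, rng)
        expected = sum(
            w * np.log(enumerate_history_prob(h.observations,
                                              0 if h.sex == "F" else 1,
                                              occ, par))
            for h, w in zip(sim.histories, sim.weights))
        assert total_loglik(sim, par) == pytest.approx(expected, abs=1e-10)


class TestGradient:
    def test_analytic_gradient_matches_fd(self):
        occ = OccasionSet.from_years(range(2000, 2007), inactive=[2003])
        truth = CmrTruth(Params.constant(
            occ, phi=[0.8, 0.7], p=[0.5, 0.6], psi=[0.3, 0.2],
            p_first=[0.9, 0.9]), seed=6)
        sim = pool_identical_histories(simulate_histories(truth, 200, occ))
        spec = ModelSpec(phi="State+Time", p="TrapClass*State", psi="State")
        design = build_design(spec, occ)
        packed = pack_histories(sim)
        rng = np.random.default_rng(7)
        beta = rng.normal(0, 0.4, design.k)

        def f(b):
            return float(np.dot(
                packed.w, _forward_loglik(packed, design.param_arrays(b))))

        ll, grad = _loglik_and_grad(packed, design, beta)
        assert ll == pytest.approx(f(beta), rel=1e-12)
        fd = approx_fprime(beta, f, 1e-6)
        assert np.allclose(grad, fd, rtol=1e-4, atol=1e-4)


class TestAicc:
    def test_arithmetic(self):
        assert aicc(-10.0, 2, 100) == pytest.approx(24 + 12 / 97)

    def test_k_zero(self):
        assert aicc(-10.0, 0, 100) == pytest.approx(20.0)

    def test_monotone_in_k(self):
        vals = [aicc(-10.0, k, 100) for k in range(0, 20)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_undefined(self):
        with pytest.raises(ValueError, match="AICc undefined"):
            aicc(-10.0, 99, 100)


class TestRanking:
    def test_weights_sum_to_one(self):
        d = np.array([0.0, 1.3, 2.5, 10.0])
        assert akaike_weights(d).sum() == pytest.approx(1.0)

    def test_equal_models_split_weight(self):
        w = akaike_weights([3.0, 3.0])
        assert np.allclose(w, [0.5, 0.5])

    def test_weights_invariant_to_common_shift(self):
        # deltas from a shifted AICc vector are unchanged, hence weights too
        aic = np.array([100.0, 102.0, 104.0])
        shifted = aic + 57.3
        assert np.allclose(akaike_weights(aic - aic.min()),
                           akaike_weights(shifted - shifted.min()))


class TestFitting:
    def test_binomial_closed_form(self):
        occ = OccasionSet.from_years([2000, 2001])
        hists = tuple(EncounterHistory(f"a{i}", "M", (1, 1))
                      for i in range(60)) + tuple(
            EncounterHistory(f"b{i}", "M", (1, 0)) for i in range(40))
        hset = pool_identical_histories(EncounterHistorySet(occ, hists))
        spec = ModelSpec(phi=".", p=".", psi=".",
                         fixed=(("p", 1.0), ("psi", 0.0)))
        fit = fit_model(hset, spec, FitOptions(multistart_n=1))
        assert fit.params.phi[0, 0, 0] == pytest.approx(0.6, abs=1e-8)
        assert fit.K == 1

    def test_boundary_no_state2_survivors(self):
        occ = OccasionSet.from_years(range(2000, 2003))
        hists = tuple(EncounterHistory(f"s2_{i}", "M", (2, 0, 0))
                      for i in range(30)) + tuple(
            EncounterHistory(f"s1_{i}", "M", (1, 1, 1)) for i in range(30))
        hset = pool_identical_histories(EncounterHistorySet(occ, hists))
        spec = ModelSpec(phi="State", p=".", psi=".",
                         fixed=(("psi", 0.0), ("p", 0.9)))
        fit = fit_model(hset, spec, FitOptions(multistart_n=1))
        assert fit.params.phi[1, 0, 0] < 0.05
        assert fit.se_unreliable

    def test_estimate_recovery_single_replicate(self, occ10):
        truth = CmrTruth(Params.constant(
            occ10, phi=[0.85, 0.75], p=[0.7, 0.7], psi=[0.4, 0.2]), seed=1)
        sim = pool_identical_histories(simulate_histories(truth, 3000, occ10))
        fit = fit_model(sim, ModelSpec(phi="State", p=".", psi="State"),
                        FitOptions(multistart_n=1))
        est = fit.estimates()
        phi1 = est[(est["class"] == "phi") & (est.State == 1)].iloc[0]
        phi2 = est[(est["class"] == "phi") & (est.State == 2)].iloc[0]
        assert abs(phi1.estimate - 0.85) < 3 * phi1.se
        assert abs(phi2.estimate - 0.75) < 3 * phi2.se


class TestConfounding:
    def test_time_dependent_terminal_flagged(self, occ5):
        d_spec = ModelSpec(phi="State*Time", p="Time", psi="State")
        design = build_design(d_spec, occ5)
        from repcost.multistate_cmr import ModelFit
        fit = ModelFit(d_spec, design, np.zeros(design.k),
                       design.param_arrays(np.zeros(design.k)),
                       0.0, design.k, 100.0, 1.0, True, 0.0)
        fit = flag_confounded(fit)
        T = occ5.n_occasions
        assert f"phi[state=1,t={T - 2},sex=M]" in fit.confounded
        assert f"p[state=2,t={T - 1},sex=F]" in fit.confounded

    def test_constant_phi_not_flagged(self, occ5):
        d_spec = ModelSpec(phi=".", p="Time", psi="State")
        design = build_design(d_spec, occ5)
        from repcost.multistate_cmr import ModelFit
        fit = ModelFit(d_spec, design, np.zeros(design.k),
                       design.param_arrays(np.zeros(design.k)),
                       0.0, design.k, 100.0, 1.0, True, 0.0)
        assert not flag_confounded(fit).confounded


class TestSplitEquivalence:
    def test_split_likelihood_equals_augmented_hmm(self, occ5):
        rng = np.random.default_rng(11)
        par = random_params(occ5, rng, trap=True)
        truth = CmrTruth(Params.constant(
            occ5, phi=[0.8, 0.7], p=[0.6, 0.6], psi=[0.3, 0.2],
            p_first=[0.9, 0.9]), seed=12)
        sim = simulate_histories(truth, 60, occ5)
        split = split_histories_for_trapdep(sim)
        assert split_loglik(split, par) == pytest.approx(
            total_loglik(sim, par, trap_aware=True), abs=1e-10)


class TestTrapdepTest:
    def test_pearson_arithmetic(self):
        chi2, expected = _pearson_chi2(np.array([[20., 5.], [5., 20.]]))
        assert expected[0, 0] == pytest.approx(12.5)
        assert chi2 == pytest.approx(18.0)

    def test_detects_trap_happiness(self, occ10):
        truth = CmrTruth(Params.constant(
            occ10, phi=[0.85, 0.8], p=[0.4, 0.4], psi=[0.2, 0.2],
            p_first=[0.9, 0.9]), seed=21)
        sim = simulate_histories(truth, 1500, occ10)
        res = trapdep_test(sim)
        assert res.p_value < 0.01
        assert res.direction > 0

    def test_insufficient_data(self):
        occ = OccasionSet.from_years(range(2000, 2004))
        h = EncounterHistory("a", "M", (1, 0, 0, 1))
        with pytest.raises(ValueError):
            trapdep_test(EncounterHistorySet(occ, (h,)))


class TestCascade:
    def test_single_candidate_identity(self, occ5):
        truth = CmrTruth(Params.constant(
            occ5, phi=[0.8, 0.7], p=[0.6, 0.6], psi=[0.3, 0.2]), seed=31)
        sim = pool_identical_histories(simulate_histories(truth, 400, occ5))
        res = selection_cascade(
            sim, ["State"], ["State"], ["State"],
            full_phi="State", full_psi="State",
            options=FitOptions(multistart_n=1, compute_se=False))
        assert res.chosen_p == "State"
        assert res.chosen_psi == "State"
        assert res.phi_table.best.spec.phi == "State"
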