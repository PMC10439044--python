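import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stratmix.binning import BinnedRT, bin_rts
from stratmix.hmm import (
    Family,
    HMMModel,
    count_params,
    cutpoints_from_probs,
    em_fit,
    fit_with_restarts,
    forward_backward,
    information_criteria,
    log_emission_matrix,
    probs_from_cutpoints,
    viterbi,
)
from stratmix.simulate import ParticipantDataset


def random_model(rng, S, K, family=Family.NONPARAMETRIC):
    kw = {}
    if family is Family.PARAMETRIC:
        kw = {"mean": rng.uniform(400, 900, S), "sd": rng.uniform(50, 200, S)}
    else:
        probs = rng.dirichlet(np.ones(K), S)
        if family is Family.SEMIPARAMETRIC:
            kw = {"cutpoints": cutpoints_from_probs(probs)}
        else:
            kw = {"bin_probs": probs}
    return HMMModel(
        family=family,
        initial=rng.dirichlet(np.ones(S)),
        transition=rng.dirichlet(np.ones(S), S),
        p_correct=rng.uniform(0.2, 0.8, S),
        **kw,
    )


def random_small_data(rng, T, K):
    bins = rng.integers(1, K + 1, T)
    rt = bins * 100.0 + rng.uniform(0, 80, T)
    binned = BinnedRT(bin_index=bins, edges=np.linspace(50, 50 + 100 * K, K + 1), K=K)
    data = ParticipantDataset("p", rt, rng.integers(0, 2, T), None)
    return data, binned


def enumerate_loglik_and_best_path(model, logB):
    """Exhaustive sum/max over all S**T paths — the independent oracle."""
    T, S = logB.shape
    total = 0.0
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(S), repeat=T):
        lp = math.log(model.initial[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += math.log(model.transition[path[t - 1], path[t]]) + logB[t, path[t]]
        total += math.exp(lp)
        if lp > best_lp:
            best_lp, best_path = lp, path
    return math.log(total), np.array(best_path) + 1, best_lp


class TestLogEmissionMatrix:
    def test_agrees_with_naive_per_trial_product(self, tiny_dataset):
        rng = np.random.default_rng(0)
        binned = bin_rts(tiny_dataset.rt_ms, 4)
        model = random_model(rng, 2, 4)
        logB = log_emission_matrix(model, tiny_dataset, binned)
        for t in range(tiny_dataset.n_trials):
            for s in range(2):
                p_rt = model.bin_probs[s, binned.bin_index[t] - 1]
                p_acc = (
                    model.p_correct[s]
                    if tiny_dataset.correct[t] == 1
                    else 1 - model.p_correct[s]
                )
                assert logB[t, s] == pytest.approx(math.log(p_rt * p_acc), rel=1e-10)

    def test_uninformative_accuracy_contributes_log_half(self, tiny_dataset):
        binned = bin_rts(tiny_dataset.rt_ms, 4)
        model = HMMModel(
            family=Family.NONPARAMETRIC,
            initial=[1.0],
            transition=[[1.0]],
            p_correct=[0.5],
            bin_probs=np.full((1, 4), 0.25),
        )
        logB = log_emission_matrix(model, tiny_dataset, binned)
        np.testing.assert_allclose(logB[:, 0], math.log(0.25) + math.log(0.5))

    def test_single_state_loglik_is_column_sum(self, tiny_dataset):
        rng = np.random.default_rng(1)
        binned = bin_rts(tiny_dataset.rt_ms, 4)
        model = random_model(rng, 1, 4)
        logB = log_emission_matrix(model, tiny_dataset, binned)
        ll, gamma, _ = forward_backward(model, tiny_dataset, binned)
        assert ll == pytest.approx(logB[:, 0].sum(), rel=1e-12)
        np.testing.assert_allclose(gamma, 1.0)


class TestForwardBackwardOracle:
    @given(
        seed=st.integers(0, 10_000),
        T=st.integers(2, 8),
        S=st.integers(1, 3),
        family=st.sampled_from([Family.NONPARAMETRIC, Family.PARAMETRIC]),
    )
    @settings(max_examples=40, deadline=None)
    def test_loglik_matches_enumeration(self, seed, T, S, family):
        rng = np.random.default_rng(seed)
        data, binned = random_small_data(rng, T, 4)
        model = random_model(rng, S, 4, family)
        b = None if family is Family.PARAMETRIC else binned
        logB = log_emission_matrix(model, data, b)
        expected_ll, _, _ = enumerate_loglik_and_best_path(model, logB)
        ll, gamma, xi = forward_backward(model, data, b)
        assert ll == pytest.approx(expected_ll, rel=1e-9)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)
        # expected transition counts sum to T-1
        assert xi.sum() == pytest.approx(T - 1, rel=1e-9)

    @given(seed=st.integers(0, 10_000), T=st.integers(2, 8), S=st.integers(2, 3))
    @settings(max_examples=40, deadline=None)
    def test_viterbi_matches_enumeration(self, seed, T, S):
        rng = np.random.default_rng(seed)
        data, binned = random_small_data(rng, T, 4)
        model = random_model(rng, S, 4)
        logB = log_emission_matrix(model, data, binned)
        _, best_path, best_lp = enumerate_loglik_and_best_path(model, logB)
        path = viterbi(model, data, binned)
        lp = math.log(model.initial[path[0] - 1]) + logB[0, path[0] - 1]
        for t in range(1, T):
            lp += math.log(model.transition[path[t - 1] - 1, path[t] - 1]) + logB[t, path[t] - 1]
        assert lp == pytest.approx(best_lp, rel=1e-9)

    def test_identical_emissions_make_transitions_irrelevant(self, tiny_dataset):
        rng = np.random.default_rng(2)
        binned = bin_rts(tiny_dataset.rt_ms, 4)
        probs = rng.dirichlet(np.ones(4))
        lls = []
        for trans in (np.array([[0.9, 0.1], [0.3, 0.7]]), np.array([[0.5, 0.5], [0.2, 0.8]])):
            model = HMMModel(
                family=Family.NONPARAMETRIC,
                initial=[0.5, 0.5],
                transition=trans,
                p_correct=[0.6, 0.6],
                bin_probs=np.vstack([probs, probs]),
            )
            lls.append(forward_backward(model, tiny_dataset, binned)[0])
        assert lls[0] == pytest.approx(lls[1], rel=1e-12)

    def test_single_state_viterbi_constant(self, tiny_dataset):
        binned = bin_rts(tiny_dataset.rt_ms, 4)
        model = random_model(np.random.default_rng(3), 1, 4)
        assert set(viterbi(model, tiny_dataset, binned)) == {1}


class TestEMFit:
    def test_one_state_recovers_empirical_frequencies(self, tiny_dataset):
        binned = bin_rts(tiny_dataset.rt_ms, 4)
        model = random_model(np.random.default_rng(4), 1, 4)
        fit = em_fit(model, tiny_dataset, binned)
        emp = binned.counts() / tiny_dataset.n_trials
        np.testing.assert_allclose(fit.model.bin_probs[0], emp, atol=1e-8)
        assert fit.model.p_correct[0] == pytest.approx(tiny_dataset.correct.mean(), abs=1e-8)

    @pytest.mark.parametrize("family", list(Family))
    def test_monotone_loglik_trace(self, family, baseline_participant):
        _, ds, binned = baseline_participant
        rng = np.random.default_rng(8)
        b = None if family is Family.PARAMETRIC else binned
        fit = fit_with_restarts(ds, 2, family, b, n_restarts=2, rng=rng)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs > -1e-8)

    def test_recovers_baseline_state_ordering(self, baseline_participant):
        _, ds, binned = baseline_participant
        fit = fit_with_restarts(
            ds, 2, Family.PARAMETRIC, None, n_restarts=10, rng=np.random.default_rng(9)
        )
        means = np.sort(fit.model.mean)
        assert 450 < means[0] < 750 < means[1] < 1100

    def test_transition_rows_stochastic_and_posteriors_normalized(self, baseline_participant):
        _, ds, binned = baseline_participant
        fit = fit_with_restarts(
            ds, 2, Family.NONPARAMETRIC, binned, n_restarts=3, rng=np.random.default_rng(10)
        )
        np.testing.assert_allclose(fit.model.transition.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(fit.state_posteriors.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(fit.model.bin_probs.sum(axis=1), 1.0, atol=1e-10)


class TestRestarts:
    def test_single_restart_equals_em_fit(self, baseline_participant):
        _, ds, binned = baseline_participant
        fit = fit_with_restarts(
            ds, 2, Family.NONPARAMETRIC, binned, n_restarts=1, rng=np.random.default_rng(1)
        )
        assert fit.restart_index == 0

    def test_deterministic_under_seed(self, baseline_participant):
        _, ds, binned = baseline_participant
        fits = [
            fit_with_restarts(
                ds, 2, Family.NONPARAMETRIC, binned, n_restarts=5, rng=np.random.default_rng(42)
            )
            for _ in range(2)
        ]
        assert fits[0].loglik == fits[1].loglik
        np.testing.assert_array_equal(fits[0].decoded, fits[1].decoded)
        np.testing.assert_allclose(fits[0].model.bin_probs, fits[1].model.bin_probs)

    def test_selected_bic_is_minimum_over_restarts(self, baseline_participant):
        _, ds, binned = baseline_participant
        rng = np.random.default_rng(6)
        singles = []
        for _ in range(5):
            singles.append(
                fit_with_restarts(ds, 2, Family.NONPARAMETRIC, binned, n_restarts=1, rng=rng)
            )
        best = fit_with_restarts(
            ds, 2, Family.NONPARAMETRIC, binned, n_restarts=5, rng=np.random.default_rng(6)
        )
        assert best.bic == pytest.approx(min(f.bic for f in singles), rel=1e-12)


class TestOrdinalEquivalence:
    def test_cutpoint_transform_is_bijective(self):
        rng = np.random.default_rng(11)
        probs = rng.dirichlet(np.ones(20), 3)
        back = probs_from_cutpoints(cutpoints_from_probs(probs))
        np.testing.assert_allclose(back, probs, atol=1e-9)
        cuts = cutpoints_from_probs(probs)
        assert np.all(np.diff(cuts, axis=1) > 0)

    def test_ordinal_and_multinomial_logliks_agree(self, baseline_participant):
        # The intercept-only cumulative logit with K-1 free cutpoints is a
        # reparameterization of the K-category multinomial, so identically
        # seeded EM runs must reach the same maximized log-likelihood.
        _, ds, binned = baseline_participant
        fit_np = fit_with_restarts(
            ds, 2, Family.NONPARAMETRIC, binned, n_restarts=5, rng=np.random.default_rng(13)
        )
        fit_sp = fit_with_restarts(
            ds, 2, Family.SEMIPARAMETRIC, binned, n_restarts=5, rng=np.random.default_rng(13)
        )
        assert fit_sp.loglik == pytest.approx(fit_np.loglik, abs=1e-6)


class TestCriteria:
    @pytest.mark.parametrize(
        "S, family, K, expected",
        [
            (2, Family.NONPARAMETRIC, 20, 43),
            (1, Family.PARAMETRIC, None, 3),
            (3, Family.PARAMETRIC, None, 17),
            (4, Family.SEMIPARAMETRIC, 10, 55),
        ],
    )
    def test_count_params(self, S, family, K, expected):
        assert count_params(S, family, K) == expected

    @given(S=st.integers(1, 4), K=st.integers(2, 35))
    @settings(max_examples=50, deadline=None)
    def test_bin_families_have_equal_counts(self, S, K):
        assert count_params(S, Family.NONPARAMETRIC, K) == count_params(
            S, Family.SEMIPARAMETRIC, K
        )

    def test_information_criteria_values(self):
        bic, aic = information_criteria(-50.0, 3, 100)
        assert bic == pytest.approx(100 + 3 * math.log(100))
        assert aic == pytest.approx(106.0)
        bic0, aic0 = information_criteria(-50.0, 0, 100)
        assert bic0 == aic0 == 100.0

    def test_fit_result_criteria_consistent(self, baseline_participant):
        _, ds, binned = baseline_participant
        fit = fit_with_restarts(
            ds, 2, Family.NONPARAMETRIC, binned, n_restarts=1, rng=np.random.default_rng(0)
        )
        assert fit.n_params == 43
        assert fit.bic == pytest.approx(-2 * fit.loglik + 43 * math.log(500))
        assert fit.aic == pytest.approx(-2 * fit.loglik + 86)


class TestAgainstHmmlearn:
    def test_loglik_matches_categorical_hmm(self, baseline_participant):
        # Independent implementation cross-check on the bin sequence alone
        # (hmmlearn has no joint RT+accuracy emission, so accuracy is
        # folded out by using a single shared Bernoulli of 0.5).
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        _, ds, binned = baseline_participant
        rng = np.random.default_rng(21)
        S, K = 2, binned.K
        probs = rng.dirichlet(np.ones(K), S)
        trans = rng.dirichlet(np.full(S, 5.0), S)
        init = rng.dirichlet(np.ones(S))
        model = HMMModel(
            family=Family.NONPARAMETRIC,
            initial=init,
            transition=trans,
            p_correct=np.full(S, 0.5),
            bin_probs=probs,
        )
        ll, _, _ = forward_backward(model, ds, binned)
        ref = hmmlearn.CategoricalHMM(n_components=S)
        ref.startprob_ = init
        ref.transmat_ = trans
        ref.emissionprob_ = probs
        ref_ll = ref.score(binned.bin_index.reshape(-1, 1) - 1)
        # our loglik includes the constant log(0.5) per trial for accuracy
        assert ll - ds.n_trials * math.log(0.5) == pytest.approx(ref_ll, rel=1e-10)

    def test_viterbi_matches_categorical_hmm(self, baseline_participant):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        _, ds, binned = baseline_participant
        rng = np.random.default_rng(22)
        S, K = 3, binned.K
        probs = rng.dirichlet(np.ones(K), S)
        trans = rng.dirichlet(np.full(S, 5.0), S)
        init = rng.dirichlet(np.ones(S))
        model = HMMModel(
            family=Family.NONPARAMETRIC,
            initial=init,
            transition=trans,
            p_correct=np.full(S, 0.5),
            bin_probs=probs,
        )
        ref = hmmlearn.CategoricalHMM(n_components=S)
        ref.startprob_ = init
        ref.transmat_ = trans
        ref.emissionprob_ = probs
        _, ref_path = ref.decode(binned.bin_index.reshape(-1, 1) - 1)
        np.testing.assert_array_equal(viterbi(model, ds, binned), ref_path + 1)
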