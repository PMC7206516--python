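"""Tests of sampling, likelihood weighting and the enumeration oracle."""

import numpy as np
import pytest

from cogbn.inference import (
    ImpossibleEvidenceError,
    averaged_inference,
    exact_posterior,
    likelihood_weighting,
    logic_sample,
    predict_status,
)
from cogbn.params import BNModel, CPT
from cogbn.structure import DAG
from cogbn.variables import STATUS


def deterministic_chain():
    """x -> y with all probability on one configuration."""
    return BNModel(
        dag=DAG(["x", "y"], [("x", "y")]),
        cpts={
            "x": CPT("x", (), (), np.array([[0.0, 1.0]])),
            "y": CPT("y", ("x",), (2,), np.array([[1.0, 0.0], [0.0, 1.0]])),
        },
    )


def ab_model(p_a=0.3, p_b_given=((0.9, 0.1), (0.2, 0.8))):
    return BNModel(
        dag=DAG(["a", "b"], [("a", "b")]),
        cpts={
            "a": CPT("a", (), (), np.array([[1 - p_a, p_a]])),
            "b": CPT("b", ("a",), (2,), np.array(p_b_given)),
        },
    )


class TestLogicSample:
    def test_deterministic_model_forces_configuration(self):
        d = logic_sample(deterministic_chain(), 200, seed=0)
        assert (d.codes["x"] == 1).all()
        assert (d.codes["y"] == 1).all()

    def test_reproducible(self, planted_model):
        a = logic_sample(planted_model, 500, seed=4).codes
        b = logic_sample(planted_model, 500, seed=4).codes
        assert a.equals(b)

    def test_marginals_match_enumeration(self, random_model_factory):
        model = random_model_factory(6, seed=12)
        d = logic_sample(model, 100_000, seed=1)
        for v in model.nodes:
            exact = exact_posterior(model, {}, v).probs
            emp = np.bincount(d.codes[v], minlength=model.cards[v]) / d.n_rows
            assert np.abs(emp - exact).max() < 0.01

    def test_sampled_data_reproduce_correlation_signs(self, planted_model,
                                                      gt_config):
        """Simulated examinations carry the dependence structure of the
        source model: discrete-level correlations along planted edges are
        positive and substantial."""
        d = logic_sample(planted_model, 3000, seed=8)
        for u, v in gt_config.dag.edges():
            if STATUS in (u, v):
                continue
            r = np.corrcoef(d.codes[u], d.codes[v])[0, 1]
            assert r > 0.3, (u, v)


class TestLikelihoodWeighting:
    def test_empty_evidence_recovers_marginal(self, random_model_factory):
        model = random_model_factory(5, seed=3)
        v = model.nodes[0]
        post = likelihood_weighting(model, {}, v, n_samples=50_000, seed=0)
        exact = exact_posterior(model, {}, v).probs
        assert post.tv_distance(exact_posterior(model, {}, v)) < 0.01
        assert post.probs.sum() == pytest.approx(1.0)
        assert np.abs(post.probs - exact).max() < 0.01

    def test_two_node_bayes_rule(self):
        model = ab_model()
        post = likelihood_weighting(model, {"b": 1}, "a",
                                    n_samples=50_000, seed=1)
        # hand Bayes: P(a=1|b=1) = .3*.8 / (.3*.8 + .7*.1)
        expected = 0.24 / (0.24 + 0.07)
        assert post.probs[1] == pytest.approx(expected, abs=0.01)

    def test_full_evidence_matches_enumeration(self, planted_model):
        rng = np.random.default_rng(0)
        d = logic_sample(planted_model, 10, seed=5)
        tests = [v for v in planted_model.nodes if v != STATUS]
        for i in range(3):
            ev = {v: int(d.codes.at[i, v]) for v in tests}
            approx = likelihood_weighting(planted_model, ev, STATUS,
                                          n_samples=50_000, seed=i)
            exact = exact_posterior(planted_model, ev, STATUS)
            assert approx.tv_distance(exact) < 0.02

    def test_impossible_evidence_raises(self):
        model = deterministic_chain()
        with pytest.raises(ImpossibleEvidenceError):
            likelihood_weighting(model, {"x": 0}, "y", n_samples=100, seed=0)

    def test_target_in_evidence_rejected(self):
        with pytest.raises(ValueError):
            likelihood_weighting(ab_model(), {"a": 0}, "a", n_samples=10)


class TestAveragedInference:
    def test_single_repeat_equals_one_lw_call(self, planted_model):
        seed = 17
        child = int(np.random.SeedSequence(seed).generate_state(1)[0]
                    % (2**31))
        avg = averaged_inference(planted_model, {"VRd": 0}, STATUS,
                                 repeats=1, n_samples=2000, seed=seed)
        single = likelihood_weighting(planted_model, {"VRd": 0}, STATUS,
                                      n_samples=2000, seed=child)
        assert avg.probs == pytest.approx(single.probs, abs=1e-12)

    def test_averaging_reduces_between_seed_variance(self, planted_model):
        ev = {"VRd": 0, "LMi": 1}
        singles, averaged = [], []
        for seed in range(12):
            singles.append(likelihood_weighting(
                planted_model, ev, STATUS, n_samples=300, seed=seed).probs[1])
            averaged.append(averaged_inference(
                planted_model, ev, STATUS, repeats=10, n_samples=300,
                seed=seed).probs[1])
        assert np.var(averaged) < np.var(singles)

    def test_converges_to_exact(self, planted_model):
        ev = {"VRd": 1, "LMi": 0, "SIM": 2}
        exact = exact_posterior(planted_model, ev, STATUS)
        post = averaged_inference(planted_model, ev, STATUS, repeats=20,
                                  n_samples=2000, seed=0)
        assert post.tv_distance(exact) < 0.01

    def test_tv_error_shrinks_when_samples_quadruple(self, random_model_factory):
        """Monte-Carlo rate: quadrupling samples should roughly halve the
        average TV error (importance sampling is O(n^-1/2))."""
        model = random_model_factory(6, seed=21)
        target = model.nodes[-1]
        ev = {model.nodes[0]: 0}
        exact = exact_posterior(model, ev, target)
        err = {n: [] for n in (250, 1000)}
        for seed in range(30):
            for n in err:
                post = likelihood_weighting(model, ev, target,
                                            n_samples=n, seed=seed)
                err[n].append(post.tv_distance(exact))
        ratio = np.mean(err[1000]) / np.mean(err[250])
        assert 0.25 <= ratio <= 0.75


class TestExactPosterior:
    def test_independent_model_posterior_is_prior(self):
        model = BNModel(
            dag=DAG(["a", "b"]),
            cpts={
                "a": CPT("a", (), (), np.array([[0.6, 0.4]])),
                "b": CPT("b", (), (), np.array([[0.1, 0.9]])),
            },
        )
        post = exact_posterior(model, {"b": 0}, "a")
        assert post.probs == pytest.approx([0.6, 0.4])

    def test_textbook_bayes_inversion(self):
        post = exact_posterior(ab_model(), {"b": 1}, "a")
        assert post.probs[1] == pytest.approx(0.24 / 0.31)

    def test_observed_mediator_blocks_upstream_evidence(self, planted_model):
        """Evidence on VRd d-separates status from SIM, BNT30 and VRi."""
        base = exact_posterior(planted_model, {"VRd": 2}, STATUS)
        for extra in ("SIM", "BNT30", "VRi"):
            more = exact_posterior(planted_model, {"VRd": 2, extra: 0},
                                   STATUS)
            assert np.abs(base.probs - more.probs).max() < 1e-12

    def test_oversized_state_space_rejected(self, random_model_factory):
        import cogbn.inference as inf
        model = random_model_factory(6, seed=2)
        old = inf._ENUM_LIMIT
        inf._ENUM_LIMIT = 3
        try:
            with pytest.raises(ValueError, match="enumeration"):
                exact_posterior(model, {}, model.nodes[0])
        finally:
            inf._ENUM_LIMIT = old


class TestPredictStatus:
    def test_argmax_label(self, planted_model):
        label, post, tie = predict_status(planted_model, {"VRd": 3},
                                          method="exact")
        assert label == "HC"
        assert not tie

    def test_uniform_tie_prefers_hc_and_flags(self):
        model = BNModel(
            dag=DAG([STATUS]),
            cpts={STATUS: CPT(STATUS, (), (),
                              np.array([[1 / 3, 1 / 3, 1 / 3]]))},
        )
        label, _, tie = predict_status(model, {}, method="exact")
        assert label == "HC"
        assert tie

    def test_sampled_agrees_with_exact_argmax(self, planted_model):
        d = logic_sample(planted_model, 60, seed=13)
        tests = [v for v in planted_model.nodes if v != STATUS]
        agree = 0
        for i in range(60):
            ev = {v: int(d.codes.at[i, v]) for v in tests}
            exact_label, _, _ = predict_status(planted_model, ev,
                                               method="exact")
            lw_label, _, _ = predict_status(planted_model, ev, repeats=10,
                                            n_samples=1000, seed=i)
            agree += exact_label == lw_label
        assert agree >= 58  # near-ties may flip under sampling noise
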