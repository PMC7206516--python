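"""Tests of BIC scoring, local search and bootstrap model averaging."""

import numpy as np
import pandas as pd
import pytest

from cogbn.dataset import DiscreteDataset, from_arrays
from cogbn.inference import logic_sample
from cogbn.structure import (
    CycleError,
    DAG,
    bic_score,
    bootstrap_average,
    enumerate_dags,
    exhaustive_search,
    family_bic,
    hill_climb,
    structural_hamming_distance,
    tabu_search,
)


def chain_dataset(n=2000, seed=0, flip=0.1):
    """A -> B -> C with strong binary dependence."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, n)
    b = np.where(rng.random(n) < flip, 1 - a, a)
    c = np.where(rng.random(n) < flip, 1 - b, b)
    return from_arrays({"A": a, "B": b, "C": c},
                       {"A": 2, "B": 2, "C": 2})


class TestDag:
    def test_cycle_rejected(self):
        d = DAG("abc", [("a", "b"), ("b", "c")])
        with pytest.raises(CycleError):
            d.add_edge("c", "a")

    def test_reverse_restores_on_failure(self):
        d = DAG("abc", [("a", "b"), ("b", "c"), ("a", "c")])
        with pytest.raises(CycleError):
            d.reverse_edge("a", "c")  # c->a would close a->b->c->a
        assert d.has_edge("a", "c")

    def test_shd_counts_reorientations(self):
        a = DAG("abc", [("a", "b"), ("b", "c")])
        b = DAG("abc", [("b", "a"), ("b", "c")])
        assert structural_hamming_distance(a, b) == 1
        c = DAG("abc", [("a", "c")])
        assert structural_hamming_distance(a, c) == 3


class TestFamilyBic:
    def test_parentless_binary_half_half(self):
        data = from_arrays({"x": np.array([0] * 5 + [1] * 5)}, {"x": 2})
        expected = 10 * np.log(0.5) - np.log(10) / 2
        assert family_bic("x", (), data) == pytest.approx(expected, abs=1e-12)

    def test_deterministic_copy_parent(self):
        x = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        data = from_arrays({"x": x, "y": x.copy()}, {"x": 2, "y": 2})
        n = len(x)
        # log-likelihood term is 0; q counts observed parent configs (2)
        expected = 0.0 - np.log(n) / 2 * 2 * (2 - 1)
        assert family_bic("y", ("x",), data) == pytest.approx(expected)

    def test_self_parent_rejected(self):
        data = from_arrays({"x": np.zeros(4, int)}, {"x": 2})
        with pytest.raises(ValueError):
            family_bic("x", ("x",), data)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_multinomial_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 80))
        df = pd.DataFrame({
            "x": rng.integers(0, 3, n),
            "p1": rng.integers(0, 2, n),
            "p2": rng.integers(0, 2, n),
        })
        data = from_arrays({c: df[c].to_numpy() for c in df},
                           {"x": 3, "p1": 2, "p2": 2})
        # oracle: groupby-based multinomial log-likelihood minus penalty
        ll = 0.0
        grouped = df.groupby(["p1", "p2"])["x"]
        q_obs = 0
        for _, g in grouped:
            counts = g.value_counts()
            nj = counts.sum()
            q_obs += 1
            ll += float((counts * np.log(counts / nj)).sum())
        expected = ll - np.log(n) / 2 * q_obs * (3 - 1)
        assert family_bic("x", ("p1", "p2"), data) == pytest.approx(expected)


class TestBicScore:
    def test_decomposes_over_families(self):
        data = chain_dataset()
        empty = DAG(["A", "B", "C"])
        total = bic_score(empty, data)
        parts = sum(family_bic(v, (), data) for v in "ABC")
        assert total == pytest.approx(parts)

    def test_chain_beats_empty_on_dependent_data(self):
        data = chain_dataset()
        chain = DAG(["A", "B", "C"], [("A", "B"), ("B", "C")])
        assert bic_score(chain, data) > bic_score(DAG(["A", "B", "C"]), data)

    def test_invariant_to_column_order(self):
        data = chain_dataset()
        reordered = DiscreteDataset(codes=data.codes[["C", "A", "B"]],
                                    cards=data.cards)
        chain = DAG(["A", "B", "C"], [("A", "B"), ("B", "C")])
        assert bic_score(chain, data) == pytest.approx(
            bic_score(chain, reordered))

    def test_cyclic_networkx_input_rejected(self):
        import networkx as nx
        g = nx.DiGraph([("A", "B"), ("B", "A")])
        with pytest.raises(CycleError):
            bic_score(g, chain_dataset())


class TestEnumeration:
    def test_dag_counts(self):
        assert sum(1 for _ in enumerate_dags("abc")) == 25
        assert sum(1 for _ in enumerate_dags("abcd")) == 543


class TestHillClimb:
    def test_independent_binaries_stay_unconnected(self):
        rng = np.random.default_rng(0)
        data = from_arrays(
            {c: rng.integers(0, 2, 5000) for c in "ABCD"},
            {c: 2 for c in "ABCD"})
        dag = hill_climb(data, restarts=0, seed=0)
        assert dag.n_edges == 0
        # analytic check: empty beats every single-edge graph
        empty_score = bic_score(DAG(list("ABCD")), data)
        one_edge = DAG(list("ABCD"), [("A", "B")])
        assert empty_score >= bic_score(one_edge, data)

    def test_attains_enumeration_optimum_on_chain(self):
        data = chain_dataset()
        dag = hill_climb(data, restarts=2, seed=1)
        _, best = exhaustive_search(data)
        assert bic_score(dag, data) == pytest.approx(best)

    def test_local_optimum_is_fixed_point(self):
        data = chain_dataset(seed=3)
        dag1 = hill_climb(data, restarts=0, seed=0)
        dag2 = hill_climb(data, init=dag1, restarts=0, seed=0)
        assert dag1 == dag2

    def test_deterministic_given_seed(self, planted_data):
        a = hill_climb(planted_data, restarts=2, seed=9)
        b = hill_climb(planted_data, restarts=2, seed=9)
        assert a == b


class TestTabuSearch:
    def test_matches_brute_force_on_three_nodes(self):
        data = chain_dataset(seed=5)
        dag = tabu_search(data, seed=0)
        _, best = exhaustive_search(data)
        assert bic_score(dag, data) == pytest.approx(best)

    def test_tabu_len_zero_reduces_to_hill_climb(self, planted_data):
        hc = hill_climb(planted_data, restarts=0, seed=0)
        tz = tabu_search(planted_data, tabu_len=0, seed=0)
        assert hc == tz

    def test_never_below_hill_climb(self, planted_data):
        hc = hill_climb(planted_data, restarts=0, seed=0)
        tb = tabu_search(planted_data, seed=0)
        assert (bic_score(tb, planted_data)
                >= bic_score(hc, planted_data) - 1e-9)


class TestBootstrapAverage:
    def test_single_replicate_degenerates(self):
        data = chain_dataset()
        support, avg = bootstrap_average(data, B=1, strength_threshold=0.0,
                                         seed=0)
        strengths = {support.strength(u, v) for u, v in avg.edges()}
        assert strengths <= {1.0}
        frame = support.to_frame()
        assert set(frame["strength"].unique()) <= {1.0}

    def test_unattainable_threshold_gives_empty_graph(self):
        data = chain_dataset()
        _, avg = bootstrap_average(data, B=5, strength_threshold=1.01, seed=0)
        assert avg.n_edges == 0

    def test_direction_frequencies_complementary(self, planted_data):
        support, _ = bootstrap_average(planted_data, B=10, seed=1)
        frame = support.to_frame()
        for (u, v) in {tuple(x) for x in frame[["from", "to"]].to_numpy()}:
            if support.strength(u, v) > 0:
                assert support.direction(u, v) + support.direction(v, u) \
                    == pytest.approx(1.0)

    def test_strong_planted_edges_supported(self, gt_config, planted_map):
        from cogbn.discretize import apply_discretization
        from cogbn.synth import default_ground_truth, sample_cohort

        cfg = default_ground_truth(missing_rate=0.0)
        table = sample_cohort(cfg, 4000, seed=6)
        data = apply_discretization(table, planted_map)
        support, avg = bootstrap_average(
            data,
            learner=lambda d, s: tabu_search(d, seed=s),
            B=30, strength_threshold=0.5, seed=2)
        for u, v in gt_config.dag.edges():
            assert support.strength(u, v) >= 0.7, (u, v)
        # non-adjacent pairs should rarely be connected
        adj = {frozenset(e) for e in gt_config.dag.edges()}
        weak = [
            (u, v)
            for i, u in enumerate(gt_config.dag.nodes)
            for v in gt_config.dag.nodes[i + 1:]
            if frozenset((u, v)) not in adj
            and support.strength(u, v) > 0.5
        ]
        assert len(weak) <= 2, weak
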