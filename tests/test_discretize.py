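"""Tests of PAM discretization, silhouette selection and interval maps."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cogbn.dataset import MISSING
from cogbn.discretize import (
    DegenerateVariableError,
    DiscretizationMap,
    InfeasibleKError,
    apply_discretization,
    fit_discretization,
    pam_1d,
    silhouette_width,
)


def brute_force_pam(values, k):
    """Oracle: exhaustive minimisation over all k-subsets of unique values."""
    vals = np.asarray(values, dtype=float)
    uniq = np.unique(vals)
    best_cost, best_set = np.inf, None
    for cand in itertools.combinations(uniq, k):
        cost = np.abs(vals[:, None] - np.array(cand)[None, :]).min(axis=1).sum()
        if cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-12 and cand < best_set
        ):
            best_cost, best_set = cost, cand
    return np.array(best_set), best_cost


class TestPam:
    def test_k_equals_distinct_gives_zero_cost(self):
        vals = [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]
        medoids, assign = pam_1d(vals, 5)
        assert list(medoids) == [0, 1, 2, 3, 4]
        cost = np.abs(np.asarray(vals, float)[:, None] - medoids).min(1).sum()
        assert cost == 0.0

    def test_two_well_separated_triplets(self):
        medoids, _ = pam_1d([1, 2, 3, 10, 11, 12], 2)
        oracle, _ = brute_force_pam([1, 2, 3, 10, 11, 12], 2)
        assert list(medoids) == [2, 11]
        assert list(medoids) == list(oracle)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_clustered_fixtures(self, seed):
        """On fixtures with genuine cluster structure (the discretization
        use case) BUILD+SWAP reaches the global optimum."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 4))
        centers = np.cumsum(rng.integers(10, 20, size=k))
        vals = np.concatenate([
            c + rng.integers(-1, 2, size=rng.integers(2, 4))
            for c in centers
        ]).astype(float)[:10]
        k = min(k, len(np.unique(vals)))
        medoids, _ = pam_1d(vals, k)
        _, oracle_cost = brute_force_pam(vals, k)
        cost = np.abs(vals[:, None] - medoids[None, :]).min(axis=1).sum()
        assert cost == pytest.approx(oracle_cost, abs=1e-9)

    def test_local_optimality_under_single_swaps(self):
        rng = np.random.default_rng(42)
        vals = np.sort(rng.normal(size=40).round(2))
        medoids, _ = pam_1d(vals, 4)
        uniq = np.unique(vals)
        cost = np.abs(vals[:, None] - medoids[None, :]).min(axis=1).sum()
        for out in medoids:
            for inn in uniq:
                if inn in medoids:
                    continue
                cand = np.array(sorted(set(medoids) - {out} | {inn}))
                c = np.abs(vals[:, None] - cand[None, :]).min(axis=1).sum()
                assert c >= cost - 1e-9

    def test_infeasible_k(self):
        with pytest.raises(InfeasibleKError):
            pam_1d([1, 1, 2, 2], 3)


class TestSilhouette:
    def test_separation_limit(self):
        vals = [0, 0.1, 100, 100.1]
        labels = [0, 0, 1, 1]
        assert silhouette_width(vals, labels) > 0.99

    def test_hand_enumerated_value(self):
        # {1,2} vs {3,4}: s = (0.6 + 1/3 + 1/3 + 0.6) / 4
        expected = (0.6 + 1 / 3 + 1 / 3 + 0.6) / 4
        assert silhouette_width([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(
            expected, abs=1e-12)

    def test_bounds_and_sklearn_agreement(self):
        from sklearn.metrics import silhouette_samples, silhouette_score

        rng = np.random.default_rng(0)
        for _ in range(5):
            vals = rng.normal(size=30)
            labels = rng.integers(0, 3, size=30)
            if len(np.unique(labels)) < 2:
                continue
            ours = silhouette_width(vals, labels)
            assert -1.0 <= ours <= 1.0
            ref = silhouette_score(vals.reshape(-1, 1), labels,
                                   metric="manhattan")
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_width([1, 2, 3], [0, 0, 0])


class TestFitDiscretization:
    def test_five_singletons_for_integer_scale(self):
        rng = np.random.default_rng(1)
        col = pd.DataFrame({
            "VRr": rng.choice([0, 1, 2, 3, 4], p=[.2, .25, .2, .15, .2],
                              size=400).astype(float)})
        dmap = fit_discretization(col, variables=["VRr"])
        assert dmap.intervals["VRr"] == tuple(
            (float(i), float(i)) for i in range(5))
        assert dmap.chosen_k["VRr"] == 5

    def test_two_point_column(self):
        col = pd.DataFrame({"x": [0.0, 10.0] * 20})
        dmap = fit_discretization(col, variables=["x"])
        assert dmap.chosen_k["x"] == 2
        assert dmap.intervals["x"] == ((0.0, 0.0), (10.0, 10.0))

    def test_bimodal_k_matches_brute_force_scan(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(3)
        # continuous scores: duplicate-free, so singleton-value clusters
        # cannot inflate the silhouette at large k
        vals = np.concatenate([rng.normal(0, 1, 100),
                               rng.normal(12, 1, 100)]).round(3)
        col = pd.DataFrame({"x": vals})
        dmap = fit_discretization(col, variables=["x"])
        # oracle: exhaustive k scan with an independently coded silhouette
        best_k, best_s = None, -np.inf
        for k in range(2, 11):
            _, assign = pam_1d(vals, k)
            s = silhouette_score(vals.reshape(-1, 1), assign,
                                 metric="manhattan")
            if s > best_s + 1e-12:
                best_k, best_s = k, s
        assert dmap.chosen_k["x"] == best_k == 2

    def test_shift_invariance_of_chosen_k(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(0, 1, 80), rng.normal(8, 1, 80),
                               rng.normal(16, 1, 80)]).round(1)
        k0 = fit_discretization(pd.DataFrame({"x": vals}),
                                variables=["x"]).chosen_k["x"]
        k1 = fit_discretization(pd.DataFrame({"x": vals + 100.0}),
                                variables=["x"]).chosen_k["x"]
        assert k0 == k1

    def test_constant_column_raises_naming_column(self):
        with pytest.raises(DegenerateVariableError, match="LMi"):
            fit_discretization(pd.DataFrame({"LMi": [3.0] * 10}),
                               variables=["LMi"])


class TestApplyDiscretization:
    def test_last_bin_of_reference_shaped_map(self):
        # interval map shaped like the published LMr row
        lmr = ((0, 1), (2, 3), (4, 4), (5, 5), (6, 6), (7, 7), (8, 8),
               (9, 9), (10, 10), (11, 11))
        dmap = DiscretizationMap(intervals={"LMr": lmr})
        assert dmap.bin_index("LMr", 11) == 9

    def test_missing_passes_through(self, planted_map, cohort):
        data = apply_discretization(cohort, planted_map)
        for t in planted_map.intervals:
            assert ((data.codes[t].to_numpy() == MISSING)
                    == cohort[t].isna().to_numpy()).all()

    def test_every_grid_value_maps_to_exactly_one_bin(self, gt_config,
                                                      planted_map):
        from cogbn.variables import grid_values

        for var, ivs in planted_map.intervals.items():
            for val in grid_values(var):
                hits = [j for j, (lo, hi) in enumerate(ivs)
                        if lo - 1e-9 <= val <= hi + 1e-9]
                assert len(hits) == 1, (var, val)

    def test_out_of_range_raises_with_context(self, planted_map):
        bad = pd.DataFrame({v: [0.0] for v in planted_map.intervals})
        bad["LMi"] = [99.0]
        with pytest.raises(ValueError, match="LMi.*99"):
            apply_discretization(bad, planted_map)

    def test_serialization_round_trip(self, planted_map):
        again = DiscretizationMap.from_json(planted_map.to_json())
        assert again.intervals == planted_map.intervals
        text = planted_map.to_text()
        assert "(0,"  in text and "PASi" in text
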