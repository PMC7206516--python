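"""Tests of the correlation-cluster and status-association analyses."""

import numpy as np
import pandas as pd
import pytest

from cogbn.correlation import (
    chi2_pair,
    correlation_matrix,
    extract_clusters,
    status_association,
)
from cogbn.discretize import apply_discretization
from cogbn.synth import block_ground_truth, sample_cohort
from cogbn.variables import NP_TESTS, STATUS


class TestCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self, cohort):
        rep = correlation_matrix(cohort)
        m = rep.matrix.to_numpy()
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)
        assert np.abs(m).max() <= 1 + 1e-12

    def test_negated_column_gives_minus_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        tab = pd.DataFrame({"a": x, "b": -x})
        rep = correlation_matrix(tab, variables=["a", "b"])
        assert rep.matrix.loc["a", "b"] == pytest.approx(-1.0)

    def test_insufficient_pairwise_rows_raise(self):
        tab = pd.DataFrame({"a": [1.0, 2.0, np.nan, np.nan],
                            "b": [np.nan, np.nan, 1.0, 2.0]})
        with pytest.raises(ValueError, match="complete rows"):
            correlation_matrix(tab, variables=["a", "b"])

    def test_planted_siblings_match_analytic_correlation(self):
        """Children of one parent: empirical r vs the closed-form value
        implied by the planted joint over bins and interval midpoints."""
        cfg = block_ground_truth(missing_rate=0.0)
        tab = sample_cohort(cfg, 60_000, seed=4)
        rep = correlation_matrix(tab, variables=["VRi", "VRd"])
        # analytic: enumerate P(parent bin, child bin), score = uniform
        # over the bin's grid -> E[score|bin] = midpoint,
        # Var adds the within-bin uniform variance
        pa, ch = "VRi", "VRd"
        p_pa = cfg.cpts[pa].table[0]  # block root: marginal is its CPT
        cpt = cfg.cpts[ch]
        joint = p_pa[:, None] * cpt.table
        def moments(var, marg):
            spec = cfg.spec(var)
            mids = np.array(spec.midpoints())
            widths = np.array([
                (hi - lo) / spec.score_step + 1 for lo, hi in spec.levels])
            var_within = (widths**2 - 1) * spec.score_step**2 / 12.0
            mean = marg @ mids
            var_total = marg @ (mids**2 + var_within) - mean**2
            return mids, mean, var_total
        mids_p, mu_p, var_p = moments(pa, joint.sum(axis=1))
        mids_c, mu_c, var_c = moments(ch, joint.sum(axis=0))
        e_xy = (joint * np.outer(mids_p, mids_c)).sum()
        r_analytic = (e_xy - mu_p * mu_c) / np.sqrt(var_p * var_c)
        assert rep.matrix.loc[pa, ch] == pytest.approx(r_analytic, abs=0.02)


class TestExtractClusters:
    def test_identity_matrix_gives_singletons(self):
        m = pd.DataFrame(np.eye(11), index=NP_TESTS, columns=NP_TESTS)
        assert len(extract_clusters(m)) == 11

    def test_two_block_matrix(self):
        names = list("abcdef")
        m = np.full((6, 6), 0.1)
        m[:3, :3] = 0.9
        m[3:, 3:] = 0.9
        np.fill_diagonal(m, 1.0)
        clusters = extract_clusters(pd.DataFrame(m, index=names,
                                                 columns=names))
        assert sorted(map(tuple, clusters)) == [tuple("abc"), tuple("def")]

    def test_five_planted_function_blocks_recovered(self):
        cfg = block_ground_truth()
        tab = sample_cohort(cfg, 4000, seed=3)
        clusters = extract_clusters(correlation_matrix(tab).matrix)
        assert sorted(map(tuple, clusters)) == sorted([
            ("LMd", "LMi", "LMr"), ("VRd", "VRi", "VRr"),
            ("PASd_h", "PASi", "PASi_h"), ("SIM",), ("BNT30",)])

    def test_raising_cutoff_only_refines(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 1, size=(8, 8))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 1.0)
        frame = pd.DataFrame(m, index=list("abcdefgh"),
                             columns=list("abcdefgh"))
        def as_sets(cl):
            return [set(c) for c in cl]
        for lo, hi in [(0.3, 0.5), (0.5, 0.7), (0.7, 0.9)]:
            coarse = as_sets(extract_clusters(frame, cutoff=lo))
            fine = as_sets(extract_clusters(frame, cutoff=hi))
            for f in fine:
                assert any(f <= c for c in coarse)


class TestStatusAssociation:
    def test_identical_group_distributions_give_f_zero(self):
        # every group sees the same multiset of values, so the
        # between-group variance vanishes exactly
        tab = pd.DataFrame({
            "x": np.tile([4.0, 5.0, 6.0], 30),
            STATUS: np.repeat(["HC", "AD", "NAD"], 30),
        })
        tab["x"] = np.concatenate([np.tile([4.0, 5.0, 6.0], 10)] * 3)
        res = status_association(tab, variables=["x"])
        assert res.loc["x", "F"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["x", "p"] == pytest.approx(1.0)

    def test_separated_groups_significant_after_bonferroni(self):
        rng = np.random.default_rng(2)
        tab = pd.DataFrame({
            "x": np.concatenate([rng.normal(0, 1, 100),
                                 rng.normal(5, 1, 100),
                                 rng.normal(10, 1, 100)]),
            STATUS: ["HC"] * 100 + ["AD"] * 100 + ["NAD"] * 100,
        })
        res = status_association(tab, variables=["x"])
        assert res.loc["x", "p_bonferroni"] < 1e-10
        assert all(res.loc["x", c] < 0.05
                   for c in res.columns if c.startswith("tukey"))

    def test_bonferroni_is_k_times_p_capped(self, cohort):
        res = status_association(cohort)
        k = len(res)
        assert k == 11
        for _, row in res.iterrows():
            assert row["p_bonferroni"] == pytest.approx(
                min(1.0, k * row["p"]), rel=1e-9)

    def test_f_invariant_to_additive_shift(self, cohort):
        shifted = cohort.copy()
        shifted["SIM"] = shifted["SIM"] + 7.0
        f0 = status_association(cohort, variables=["SIM"]).loc["SIM", "F"]
        f1 = status_association(shifted, variables=["SIM"]).loc["SIM", "F"]
        assert f0 == pytest.approx(f1, rel=1e-9)

    def test_empty_group_raises(self):
        tab = pd.DataFrame({"x": [1.0, 2.0, 3.0], STATUS: ["HC"] * 3})
        with pytest.raises(ValueError):
            status_association(tab, variables=["x"])


def test_chi2_pair_detects_planted_dependence(planted_data):
    stat, dof, p = chi2_pair(planted_data, "LMi", "LMd")
    assert p < 1e-10
    assert dof > 0
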