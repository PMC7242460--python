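import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

import refstab as rs
from refstab.genorm import GeNorm

from _oracles import brute_elimination, brute_m, brute_v_series
from conftest import make_aggregated, random_quantities


def qm_from_q(q: pd.DataFrame) -> rs.QuantityMatrix:
    return rs.QuantityMatrix(q=q, efficiency=pd.Series(2.0, index=q.index))


def helmert_design(alphas, n_samples=8):
    """Deterministic panel: gene j moves along its own orthogonal direction.

    The directions are mean-zero, mutually orthogonal, unit-sample-SD Helmert
    contrasts, so the pairwise variation between genes j and k is exactly
    sqrt(alpha_j^2 + alpha_k^2) and the stability ranking is the ascending
    order of the alphas.
    """
    K = len(alphas)
    assert K <= n_samples - 1
    H = np.zeros((n_samples, K))
    for j in range(K):
        H[: j + 1, j] = 1.0
        H[j + 1, j] = -(j + 1)
        H[:, j] /= H[:, j].std(ddof=1)
    L = np.array(alphas)[None, :] * H  # samples x genes, log2 scale
    q = pd.DataFrame(
        np.exp2(L.T),
        index=[f"G{j}" for j in range(K)],
        columns=[f"s{i}" for i in range(n_samples)],
    )
    return qm_from_q(q)


class TestPairwiseVariation:
    def test_coregulated_pair_has_zero_variation(self, toy_qm):
        assert rs.pairwise_variation(toy_qm, "A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_unit_sd_log_ratio(self, toy_qm):
        assert rs.pairwise_variation(toy_qm, "A", "C") == pytest.approx(1.0)
        assert rs.pairwise_variation(toy_qm, "C", "A") == pytest.approx(1.0)

    def test_two_sample_case(self):
        agg = make_aggregated([[20.0, 21.0], [30.0, 30.0]], ["A", "C"], ["s1", "s2"])
        qm = rs.relative_quantities(agg)
        assert rs.pairwise_variation(qm, "A", "C") == pytest.approx(math.sqrt(0.5))

    def test_single_sample_is_error(self):
        agg = make_aggregated([[20.0], [30.0]], ["A", "C"], ["s1"])
        qm = rs.relative_quantities(agg)
        with pytest.raises(ValueError, match="2 samples"):
            rs.pairwise_variation(qm, "A", "C")


class TestMValues:
    def test_toy_panel(self, toy_qm):
        m = rs.m_values(toy_qm)
        assert m["A"] == pytest.approx(0.5)
        assert m["B"] == pytest.approx(0.5)
        assert m["C"] == pytest.approx(1.0)

    def test_two_genes_share_their_pairwise_variation(self, toy_qm):
        m = rs.m_values(toy_qm, active_genes=["A", "C"])
        assert m["A"] == m["C"] == pytest.approx(rs.pairwise_variation(toy_qm, "A", "C"))

    def test_duplicating_a_gene_lowers_its_m(self, toy_qm):
        q = toy_qm.q.copy()
        q.loc["A2"] = q.loc["A"]
        m_with = rs.m_values(qm_from_q(q))
        m_without = rs.m_values(toy_qm)
        assert m_with["A"] < m_without["A"]
        assert m_with["A2"] < m_without["A"]

    def test_singleton_set_is_error(self, toy_qm):
        with pytest.raises(ValueError):
            rs.m_values(toy_qm, active_genes=["A"])


class TestRanking:
    def test_toy_elimination(self, toy_qm):
        res = rs.rank_genes(toy_qm)
        assert res.elimination_order == ["C"]
        assert res.final_ranking == ["A", "B", "C"]
        assert res.ranks["A"] == res.ranks["B"] == 1
        assert res.m_values["C"] == pytest.approx(1.0)
        assert res.m_values["A"] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_perfect_panel_uses_tie_break(self):
        # all genes mutually proportional: every M is 0; the lexicographically
        # last symbol is removed first at every iteration
        ct = np.tile([20.0, 21.0, 22.0], (4, 1)) + np.arange(4)[:, None]
        qm = rs.relative_quantities(make_aggregated(ct, list("ABCD"), ["s1", "s2", "s3"]))
        res = rs.rank_genes(qm)
        assert res.elimination_order == ["D", "C"]
        assert res.final_ranking == ["A", "B", "C", "D"]
        for trace in res.m_trace:
            assert (np.abs(trace.to_numpy()) < 1e-12).all()
        assert res.optimal_n == 2
        assert res.tie_events

    def test_oracle_equivalence_on_random_panels(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            qm = random_quantities(rng, n_genes=5 + seed % 2, n_samples=7)
            q_dict = {g: qm.q.loc[g].tolist() for g in qm.genes}
            trace, order = brute_elimination(q_dict)
            res = rs.rank_genes(qm)
            assert res.elimination_order == order
            for ours, theirs in zip(res.m_trace, trace):
                for g, val in theirs.items():
                    assert ours[g] == pytest.approx(val, abs=1e-12)

    def test_deterministic_design_is_recovered_at_any_noise_scale(self):
        alphas = [0.1, 0.2, 0.4, 0.8, 1.6]
        for eps in (1.0, 1e-3, 1e-6):
            qm = helmert_design([a * eps for a in alphas])
            res = rs.rank_genes(qm)
            assert set(res.final_ranking[:2]) == {"G0", "G1"}
            assert res.final_ranking[2:] == ["G2", "G3", "G4"]

    def test_reported_m_not_worsened_by_duplicate(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            qm = random_quantities(rng, n_genes=6, n_samples=10)
            target = qm.genes[seed % 6]
            base = rs.rank_genes(qm).m_values[target]
            q = qm.q.copy()
            q.loc[target + "_dup"] = q.loc[target]
            with_dup = rs.rank_genes(qm_from_q(q)).m_values[target]
            assert with_dup <= base + 1e-12

    def test_too_few_genes_is_error(self, toy_qm):
        qm = qm_from_q(toy_qm.q.loc[["A", "B"]])
        with pytest.raises(ValueError, match="3 genes"):
            rs.rank_genes(qm)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_scale_and_sample_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        qm = random_quantities(rng, n_genes=5, n_samples=8)
        res = rs.rank_genes(qm)
        # rescale one gene by a positive constant
        q2 = qm.q.copy()
        q2.loc[q2.index[2]] *= 37.5
        res_scaled = rs.rank_genes(qm_from_q(q2))
        # permute samples
        perm = rng.permutation(qm.q.columns)
        res_perm = rs.rank_genes(qm_from_q(qm.q[perm]))
        for other in (res_scaled, res_perm):
            assert other.final_ranking == res.final_ranking
            np.testing.assert_allclose(
                other.m_values.to_numpy(), res.m_values.to_numpy(), atol=1e-9
            )
            np.testing.assert_allclose(
                [v for _, v in other.v_series], [v for _, v in res.v_series], atol=1e-9
            )


class TestNormalizationFactor:
    def test_geomean_of_equal_vectors(self, toy_qm):
        nf = rs.normalization_factor(toy_qm, ["A", "B"], 2)
        assert nf.tolist() == pytest.approx([1.0, 0.5, 0.25])

    def test_adding_constant_gene(self, toy_qm):
        nf = rs.normalization_factor(toy_qm, ["A", "B", "C"], 3)
        assert nf.tolist() == pytest.approx([1.0, 2 ** (-2 / 3), 2 ** (-4 / 3)])

    def test_log_nf_is_mean_of_log_quantities(self):
        rng = np.random.default_rng(3)
        qm = random_quantities(rng, 5, 6)
        ranking = list(qm.genes)
        nf = rs.normalization_factor(qm, ranking, 4)
        expected = np.log2(qm.q.loc[ranking[:4]]).mean(axis=0)
        np.testing.assert_allclose(np.log2(nf.to_numpy()), expected.to_numpy(), atol=1e-12)

    def test_out_of_range_n(self, toy_qm):
        with pytest.raises(ValueError):
            rs.normalization_factor(toy_qm, ["A", "B", "C"], 4)


class TestVSeries:
    def test_toy_v23(self, toy_qm):
        series, optimal = rs.v_series_and_optimal_n(toy_qm, ["A", "B", "C"])
        assert series == [(2, pytest.approx(1 / 3))]
        assert optimal is None  # 1/3 is above the 0.15 cut-off

    def test_perfect_panel_all_v_zero(self):
        ct = np.tile([20.0, 21.0, 22.0], (4, 1)) + np.arange(4)[:, None]
        qm = rs.relative_quantities(make_aggregated(ct, list("ABCD"), ["s1", "s2", "s3"]))
        series, optimal = rs.v_series_and_optimal_n(qm, list("ABCD"))
        assert all(v == pytest.approx(0.0, abs=1e-12) for _, v in series)
        assert optimal == 2

    def test_first_subthreshold_entry_defines_optimal_n(self):
        rng = np.random.default_rng(11)
        qm = random_quantities(rng, 8, 10)
        res = rs.rank_genes(qm)
        series = res.v_series
        if res.optimal_n is not None:
            n = res.optimal_n
            assert dict(series)[n] < res.threshold
            assert all(dict(series)[m] >= res.threshold for m in range(2, n))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        qm = random_quantities(rng, 6, 9)
        res = rs.rank_genes(qm)
        q_dict = {g: qm.q.loc[g].tolist() for g in qm.genes}
        for (n, v), (n2, v2) in zip(res.v_series, brute_v_series(q_dict, res.final_ranking)):
            assert n == n2
            assert v == pytest.approx(v2, abs=1e-12)


class TestEstimatorApi:
    def test_clone_and_params(self):
        est = GeNorm(v_threshold=0.2, n_select=3)
        params = est.get_params()
        assert params["v_threshold"] == 0.2
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_transform_divides_by_nf(self):
        rng = np.random.default_rng(9)
        qm = random_quantities(rng, 5, 8)
        X = qm.to_sample_matrix()
        est = GeNorm(n_select=3).fit(X)
        nf = est.normalization_factors(X, n=3)
        normed = est.transform(X)
        np.testing.assert_allclose(
            normed.to_numpy(), X.to_numpy() / nf[:, None], atol=1e-12
        )

    def test_fitted_attributes_are_consistent(self):
        rng = np.random.default_rng(13)
        qm = random_quantities(rng, 6, 9)
        est = GeNorm().fit(qm.to_sample_matrix())
        assert sorted(est.elimination_order_ + est.final_ranking_[:2]) == sorted(est.genes_)
        assert set(est.final_ranking_) == set(est.genes_)
        assert (est.m_values_ >= 0).all()
        assert all(v >= 0 for _, v in est.v_series_)
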