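"""geNorm: pairwise variation, M-values, stepwise ranking, V(n/n+1)."""

import numpy as np
import pytest

from refstab import (
    collapse_replicates,
    genorm_rank,
    m_values,
    optimal_gene_count,
    pairwise_variation_matrix,
    relative_quantities,
)
from refstab.errors import InsufficientDataError

from conftest import build_dataset, random_dataset
from oracles import m_values_naive, v_matrix_naive, v_n_naive


class TestPairwiseVariation:
    def test_duplicated_gene_has_zero_v(self, worked_trio):
        rq = relative_quantities(worked_trio)
        v = pairwise_variation_matrix(rq)
        assert v.loc["a", "b"] == 0.0
        assert v.loc["a", "c"] == pytest.approx(1.0)
        assert (v.to_numpy() == v.to_numpy().T).all()
        assert (np.diag(v.to_numpy()) == 0).all()

    def test_matches_naive_recomputation(self):
        rng = np.random.default_rng(5)
        ds = random_dataset(rng)
        rq = relative_quantities(ds)
        v = pairwise_variation_matrix(rq)
        naive = v_matrix_naive({g: list(rq.log2.loc[g]) for g in rq.genes})
        for j in rq.genes:
            for k in rq.genes:
                assert v.loc[j, k] == pytest.approx(naive[(j, k)], abs=1e-12)

    def test_pair_with_too_few_shared_samples(self):
        ds = build_dataset({"a": [20.0, 21.0], "b": [20.0, 21.0]})
        ds.cq = ds.cq.drop(ds.cq[(ds.cq["gene"] == "b") & (ds.cq["sample"] == "s2")].index)
        rq = relative_quantities(ds)
        with pytest.raises(InsufficientDataError, match="'a' and 'b'"):
            pairwise_variation_matrix(rq)


class TestMValues:
    def test_hand_computed_trio(self, worked_trio):
        m = m_values(relative_quantities(worked_trio))
        assert m.to_dict() == pytest.approx({"a": 0.5, "b": 0.5, "c": 1.0})

    def test_shift_invariance(self, worked_trio):
        m0 = m_values(relative_quantities(worked_trio))
        shifted = build_dataset(
            {"a": [25.0, 26.0, 27.0], "b": [20.0, 21.0, 22.0], "c": [20.0, 22.0, 21.0]}
        )
        m1 = m_values(relative_quantities(shifted))
        assert np.allclose(m0.to_numpy(), m1.to_numpy())

    def test_identical_genes_up_to_shifts_have_zero_m(self):
        ds = build_dataset({"a": [20, 21, 22], "b": [25, 26, 27], "c": [18, 19, 20]})
        m = m_values(relative_quantities(ds))
        assert np.allclose(m.to_numpy(), 0.0)

    def test_noise_raises_only_that_genes_m_in_expectation(self):
        rng = np.random.default_rng(0)
        base = list(rng.uniform(18, 24, size=20))
        wins = 0
        for _ in range(100):
            noisy = [c + rng.normal(0, 0.8) for c in base]
            ds = build_dataset({"a": base, "b": base, "c": base, "noisy": noisy})
            m = m_values(relative_quantities(ds))
            wins += m["noisy"] == m.max()
        assert wins == 100

    def test_matches_naive(self):
        rng = np.random.default_rng(17)
        rq = relative_quantities(random_dataset(rng))
        m = m_values(rq)
        naive = m_values_naive({g: list(rq.log2.loc[g]) for g in rq.genes})
        for g in rq.genes:
            assert m[g] == pytest.approx(naive[g], abs=1e-12)


class TestRanking:
    def test_worked_trio_exclusion(self, worked_trio):
        res = genorm_rank(relative_quantities(worked_trio))
        assert res.exclusion_order == ["c"]
        assert res.most_stable_pair == ("a", "b")
        assert res.ranking.to_dict() == {"a": 1.0, "b": 1.0, "c": 3.0}

    def test_final_pair_rank_switch(self, worked_trio):
        res = genorm_rank(relative_quantities(worked_trio), final_pair_rank=1.5)
        assert res.ranking["a"] == res.ranking["b"] == 1.5

    def test_recovers_designed_stable_pair(self, celmisia, celmisia_rq):
        _, truth = celmisia
        res = genorm_rank(celmisia_rq)
        assert set(res.most_stable_pair) == set(truth.stable_pair)
        assert res.exclusion_order[0] == truth.least_stable

    def test_gene_order_invariance(self, celmisia_rq):
        res = genorm_rank(celmisia_rq)
        shuffled = type(celmisia_rq)(rq=celmisia_rq.rq.iloc[::-1])
        res2 = genorm_rank(shuffled)
        assert res.ranking_order == res2.ranking_order
        assert res.ranking.sort_index().equals(res2.ranking.sort_index())

    def test_stepwise_vs_single_pass_both_available(self, celmisia_rq):
        step = genorm_rank(celmisia_rq, stepwise=True)
        single = genorm_rank(celmisia_rq, stepwise=False)
        assert set(step.most_stable_pair) == set(single.most_stable_pair)
        assert len(step.m_steps) == len(celmisia_rq.genes) - 2


class TestOptimalN:
    def test_identical_top_genes_give_zero_v23(self):
        ds = build_dataset(
            {"a": [20, 21, 22, 23], "b": [20, 21, 22, 23], "c": [20, 21, 22, 23],
             "d": [20, 23, 21, 22]}
        )
        rq = relative_quantities(ds)
        res = genorm_rank(rq)
        opt = optimal_gene_count(rq, res.ranking_order)
        assert opt.nf_pairwise[2] == pytest.approx(0.0, abs=1e-12)
        assert opt.optimal_n == 2 and opt.satisfied

    def test_default_simulation_needs_only_two_genes(self, celmisia_rq):
        res = genorm_rank(celmisia_rq)
        opt = optimal_gene_count(celmisia_rq, res.ranking_order)
        assert opt.nf_pairwise[2] < 0.15
        assert opt.optimal_n == 2

    def test_matches_naive_v(self, celmisia_rq):
        res = genorm_rank(celmisia_rq)
        opt = optimal_gene_count(celmisia_rq, res.ranking_order)
        ranked = [list(celmisia_rq.rq.loc[g]) for g in res.ranking_order]
        for n in opt.nf_pairwise.index:
            assert opt.nf_pairwise[n] == pytest.approx(v_n_naive(ranked, n), abs=1e-12)

    def test_unsatisfiable_cutoff_flagged(self, celmisia_rq):
        res = genorm_rank(celmisia_rq)
        opt = optimal_gene_count(celmisia_rq, res.ranking_order, cutoff=1e-6)
        assert not opt.satisfied and opt.optimal_n == len(celmisia_rq.genes)


def test_cq_shift_invariance_of_v_m_and_vn(celmisia):
    """Adding a constant to one gene's Cq changes no V, M or V(n/n+1)."""
    ds, _ = celmisia
    collapsed, _ = collapse_replicates(ds)
    shifted = collapsed.cq.copy()
    shifted.loc[shifted["gene"] == "GAPDH", "cq"] += 3.0
    ds_shifted = type(ds)(cq=shifted, metadata=ds.metadata.copy(),
                          efficiencies=dict(ds.efficiencies))
    rq0 = relative_quantities(collapsed)
    rq1 = relative_quantities(ds_shifted)
    np.testing.assert_allclose(
        pairwise_variation_matrix(rq0).to_numpy(),
        pairwise_variation_matrix(rq1).to_numpy(),
        atol=1e-10,
    )
    res0, res1 = genorm_rank(rq0), genorm_rank(rq1)
    assert res0.ranking_order == res1.ranking_order
    np.testing.assert_allclose(
        optimal_gene_count(rq0, res0.ranking_order).nf_pairwise.to_numpy(),
        optimal_gene_count(rq1, res1.ranking_order).nf_pairwise.to_numpy(),
        atol=1e-10,
    )
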