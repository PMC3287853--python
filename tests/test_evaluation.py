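"""Replicate aggregation: gene calls, ROC algebra, SNP calls, t-test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gbpls.errors import ConfigError
from gbpls.evaluation import (
    ReplicateSelections,
    associated_snps,
    call_genes,
    median_snp_ranks,
    roc_curve,
    snp_t_test,
    tpr_fpr,
)
from gbpls.cohort import GenotypeMatrix, TraitReplicates
from gbpls.simulate import TruthSet

from conftest import make_genotypes


def _sel(table: dict[str, list[bool]], ranks=None) -> ReplicateSelections:
    genes = list(table)
    R = len(next(iter(table.values())))
    df = pd.DataFrame.from_dict(table, orient="index", columns=range(R))
    return ReplicateSelections(genes=genes, selected=df, snp_ranks=ranks or {})


def _truth(causal) -> TruthSet:
    return TruthSet(causal_gene_ids=set(causal), causal_snp_ids=set(),
                    effects={})


def test_call_genes_union_intersection_threshold():
    sel = _sel({"gA": [1, 1, 0, 1], "gB": [0, 1, 0, 0], "gC": [0, 0, 0, 0]})
    assert call_genes(sel, 1) == {"gA", "gB"}  # union
    assert call_genes(sel, 4) == set()  # intersection
    assert call_genes(sel, 2) == {"gA"}
    with pytest.raises(ConfigError):
        call_genes(sel, 0)
    with pytest.raises(ConfigError):
        call_genes(sel, 5)


def test_call_genes_nested_in_cutoff():
    rng = np.random.default_rng(0)
    sel = _sel({f"g{i}": list(rng.random(6) < 0.4) for i in range(25)})
    for c in range(1, 6):
        assert call_genes(sel, c) >= call_genes(sel, c + 1)


@settings(derandomize=True, deadline=None, max_examples=30)
@given(
    st.lists(
        st.lists(st.booleans(), min_size=5, max_size=5),
        min_size=2, max_size=12,
    )
)
def test_call_sets_nested_and_roc_monotone_property(rows):
    """For any selection table, call sets are nested in c and the ROC is
    monotone non-increasing in both coordinates."""
    table = {f"g{i}": row for i, row in enumerate(rows)}
    sel = _sel(table)
    for c in range(1, 5):
        assert call_genes(sel, c) >= call_genes(sel, c + 1)
    truth = _truth({"g0"})
    roc = roc_curve(sel, truth, c_max=5)
    assert (roc.table["tpr"].diff().dropna() <= 0).all()
    assert (roc.table["fpr"].diff().dropna() <= 0).all()
    assert roc.table[["tpr", "fpr"]].isin([0, 1]).all().all() or (
        ((roc.table[["tpr", "fpr"]] >= 0) & (roc.table[["tpr", "fpr"]] <= 1))
        .all().all()
    )


@settings(derandomize=True, deadline=None, max_examples=30)
@given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=12))
def test_snp_rank_property(weights):
    """Ranks are a permutation-equivariant midrank assignment of 1..m."""
    from gbpls.ranks import rank_abs_weights

    w = np.array(weights)
    r = rank_abs_weights(w)
    m = len(w)
    assert r.sum() == pytest.approx(m * (m + 1) / 2)
    assert r.min() >= 1 and r.max() <= m
    perm = np.random.default_rng(0).permutation(m)
    np.testing.assert_allclose(rank_abs_weights(w[perm]), r[perm])


def test_tpr_fpr_counting():
    truth = _truth({"g1", "g2"})
    universe = {f"g{i}" for i in range(1, 11)}
    assert tpr_fpr({"g1", "g2"}, truth, universe) == (1.0, 0.0)
    assert tpr_fpr(universe, truth, universe) == (1.0, 1.0)
    tpr, fpr = tpr_fpr({"g1", "g3", "g4"}, truth, universe)
    assert (tpr, fpr) == (0.5, 0.25)
    with pytest.raises(ConfigError):
        tpr_fpr({"g1"}, _truth(set()), universe)


def test_roc_curve_matches_brute_force_recount():
    rng = np.random.default_rng(1)
    R = 12
    table = {f"g{i}": list(rng.random(R) < rng.uniform(0.1, 0.9))
             for i in range(30)}
    sel = _sel(table)
    truth = _truth({"g0", "g1", "g2"})
    roc = roc_curve(sel, truth, c_max=10)
    assert list(roc.table["c"]) == list(range(1, 11))
    causal = truth.causal_gene_ids
    noncausal = set(table) - causal
    for _, row in roc.table.iterrows():
        c = int(row.c)
        called = {gid for gid, v in table.items() if sum(v) >= c}
        assert row.tpr == len(called & causal) / len(causal)
        assert row.fpr == len(called & noncausal) / len(noncausal)
    # monotone non-increasing in c
    assert (roc.table["tpr"].diff().dropna() <= 0).all()
    assert (roc.table["fpr"].diff().dropna() <= 0).all()
    assert 0.0 <= roc.auc() <= 1.0


def test_roc_with_no_selections_is_flat_zero():
    sel = _sel({"g0": [0, 0, 0], "g1": [0, 0, 0]})
    roc = roc_curve(sel, _truth({"g0"}), c_max=3)
    assert (roc.table["tpr"] == 0).all()
    assert (roc.table["fpr"] == 0).all()


def test_associated_snps_top_half_and_medians():
    ranks = {
        ("gA", 0): {"s1": 1.0, "s2": 2.0, "s3": 3.0, "s4": 4.0},
    }
    sel = _sel({"gA": [1, 0]}, ranks)
    assert associated_snps(sel, "gA") == {"s1", "s2"}  # ceil(4/2) = 2

    ranks3 = {
        ("gB", 0): {"s1": 1.0, "s2": 3.0, "s3": 2.0},
        ("gB", 1): {"s1": 3.0, "s2": 1.0, "s3": 2.0},
        ("gB", 2): {"s1": 2.0, "s2": 2.0, "s3": 1.0},
    }
    sel3 = _sel({"gB": [1, 1, 1]}, ranks3)
    med = median_snp_ranks(sel3, "gB")
    assert med["s1"] == 2.0  # median of (1, 3, 2)
    assert med["s2"] == 2.0
    assert med["s3"] == 2.0
    # full tie: ceil(3/2)=2 kept, ordered by snp_id
    assert associated_snps(sel3, "gB") == {"s1", "s2"}


def test_associated_snps_five_snp_enumeration_oracle():
    rng = np.random.default_rng(5)
    snps = [f"s{i}" for i in range(5)]
    reps = {}
    for r in range(3):
        perm = rng.permutation(5) + 1.0
        reps[("gC", r)] = dict(zip(snps, perm))
    sel = _sel({"gC": [1, 1, 1]}, reps)
    med_oracle = {
        s: float(np.median([reps[("gC", r)][s] for r in range(3)]))
        for s in snps
    }
    order = sorted(snps, key=lambda s: (med_oracle[s], s))
    assert associated_snps(sel, "gC") == set(order[:3])  # ceil(5/2) = 3


def test_single_snp_gene_always_associated():
    sel = _sel({"gD": [1, 0, 0]}, {("gD", 0): {"only": 1.0}})
    assert associated_snps(sel, "gD") == {"only"}


def test_never_selected_gene_warns_and_returns_empty():
    sel = _sel({"gE": [0, 0]})
    with pytest.warns(UserWarning, match="never selected"):
        assert associated_snps(sel, "gE") == set()


def test_t_test_matches_closed_form_and_scipy():
    # carriers y=(3,4,5), non-carriers y=(0,1,2)
    g = GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(6)], snp_ids=["v0"],
        G=np.array([[0], [0], [0], [1], [1], [2]]),
    )
    tr = TraitReplicates(Q=np.array([0.0, 1, 2, 3, 4, 5])[:, None])
    out = snp_t_test(g, tr)
    y1, y0 = np.array([3.0, 4, 5]), np.array([0.0, 1, 2])
    sp2 = (y1.var(ddof=1) * 2 + y0.var(ddof=1) * 2) / 4
    tstat = (y1.mean() - y0.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    p_exact = 2 * stats.t.sf(abs(tstat), 4)
    assert out.median_p[0] == pytest.approx(p_exact, abs=1e-12)
    assert out.median_p[0] == pytest.approx(
        stats.ttest_ind(y1, y0).pvalue, abs=1e-12
    )


def test_t_test_identical_groups_give_p_one():
    g = GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(6)], snp_ids=["v0"],
        G=np.array([[0], [0], [0], [1], [1], [1]]),
    )
    # same group means; pooled t = 0 -> p = 1
    tr = TraitReplicates(Q=np.array([1.0, 2, 3, 3, 2, 1])[:, None])
    out = snp_t_test(g, tr)
    assert out.median_p[0] == pytest.approx(1.0)


def test_t_test_monomorphic_excluded_and_welch_flag():
    rng = np.random.default_rng(2)
    G = np.column_stack([
        np.zeros(30, dtype=int),  # monomorphic: excluded
        rng.binomial(2, 0.4, size=30),
    ])
    g = GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(30)], snp_ids=["v0", "v1"], G=G
    )
    tr = TraitReplicates(Q=rng.normal(size=(30, 3)))
    with pytest.warns(UserWarning, match="monomorphic"):
        out = snp_t_test(g, tr)
    assert list(out.snp_id) == ["v1"]
    with pytest.warns(UserWarning, match="monomorphic"):
        out_w = snp_t_test(g, tr, welch=True)
    carriers = G[:, 1] > 0
    ps = []
    for r in range(3):
        y = tr.Q[:, r]
        ps.append(stats.ttest_ind(y[carriers], y[~carriers],
                                  equal_var=False).pvalue)
    assert out_w.median_p[0] == pytest.approx(float(np.median(ps)), abs=1e-10)


def test_t_test_median_over_replicates_matches_oracle():
    g = make_genotypes(40, 8, seed=4)
    rng = np.random.default_rng(7)
    tr = TraitReplicates(Q=rng.normal(size=(40, 5)))
    out = snp_t_test(g, tr)
    for _, row in out.iterrows():
        j = g.snp_ids.index(row.snp_id)
        carriers = g.G[:, j] > 0
        ps = [
            stats.ttest_ind(tr.Q[carriers, r], tr.Q[~carriers, r]).pvalue
            for r in range(5)
        ]
        assert row.median_p == pytest.approx(float(np.median(ps)), abs=1e-10)
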