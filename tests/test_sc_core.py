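"""Normalization, pseudobulk, rank-sum DEG, BH and Fisher enrichment.

Expected values come from closed forms (log(2501), hypergeometric tail,
BH step-up arithmetic) or from a brute-force enumeration oracle over all
rank assignments for tiny groups.
"""

import itertools
import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import somagerm.sc_core as sc
from somagerm import StatParams


def _adata(X, cell_types=None):
    X = np.asarray(X)
    n = X.shape[0]
    obs = pd.DataFrame(
        {"cell_type": cell_types or ["t"] * n, "condition": "WT",
         "timepoint": "d3_5"},
        index=[f"c{i}" for i in range(n)],
    )
    return ad.AnnData(X=X.astype(float), obs=obs,
                      var=pd.DataFrame(index=[f"g{j}" for j in range(X.shape[1])]))


# ----------------------------------------------------------- normalization


def test_normalize_closed_form():
    norm = sc.normalize(_adata([[1, 1, 2]]))
    expected = [math.log(2501), math.log(2501), math.log(5001)]
    np.testing.assert_allclose(norm.X[0], expected, rtol=1e-12)


def test_normalize_scale_invariance_and_zero_gene():
    a = sc.normalize(_adata([[3, 0, 7], [1, 5, 0]]))
    b = sc.normalize(_adata([[6, 0, 14], [1, 5, 0]]))
    np.testing.assert_allclose(a.X[0], b.X[0], rtol=1e-12)
    assert (sc.normalize(_adata([[5, 0], [3, 0]])).X[:, 1] == 0).all()


def test_normalize_rejects_zero_total_cells():
    with pytest.raises(ValueError, match="zero total"):
        sc.normalize(_adata([[1, 2], [0, 0]]))


def test_normalize_matches_scanpy():
    scanpy = pytest.importorskip("scanpy")
    rng = np.random.default_rng(3)
    counts = rng.poisson(2.0, size=(30, 50)) + (np.arange(50) == 0)
    ours = sc.normalize(_adata(counts))
    ref = _adata(counts)
    scanpy.pp.normalize_total(ref, target_sum=1e4)
    scanpy.pp.log1p(ref)
    np.testing.assert_allclose(ours.X, ref.X, rtol=1e-10)


# -------------------------------------------------------------- pseudobulk


def test_pseudobulk_mean_and_order_invariance(small_norm):
    pb = sc.pseudobulk(small_norm, ["cell_type", "condition", "timepoint"])
    key = ("CySC", "WT", "d3_5")
    mask = (
        (small_norm.obs["cell_type"] == "CySC")
        & (small_norm.obs["condition"] == "WT")
        & (small_norm.obs["timepoint"] == "d3_5")
    ).to_numpy()
    np.testing.assert_allclose(pb.loc[key].to_numpy(),
                               small_norm.X[mask].mean(axis=0), rtol=1e-12)
    perm = np.random.default_rng(0).permutation(small_norm.n_obs)
    pb2 = sc.pseudobulk(small_norm[perm], ["cell_type", "condition", "timepoint"])
    np.testing.assert_allclose(pb.to_numpy(), pb2.to_numpy(), rtol=1e-12)


def test_pseudobulk_single_cell_group():
    norm = sc.normalize(_adata([[1, 2, 3]], cell_types=["solo"]))
    pb = sc.pseudobulk(norm, ["cell_type"])
    np.testing.assert_allclose(pb.loc["solo"].to_numpy(), norm.X[0], rtol=1e-12)


# ------------------------------------------------------------ rank-sum DEG


def brute_force_ranksum_p(a, b):
    """Enumerate all C(n1+n2, n1) group assignments; two-sided p is the
    fraction with |U - mu| at least the observed |U - mu|."""
    pooled = list(a) + list(b)
    n1 = len(a)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    mu = n1 * len(b) / 2.0

    def ustat(idx):
        r1 = sum(ranks[i] for i in idx)
        return r1 - n1 * (n1 + 1) / 2.0

    obs = abs(ustat(range(n1)) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ustat(idx) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


def test_exact_p_matches_enumeration_oracle():
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    assert brute_force_ranksum_p(a, b) == pytest.approx(0.1)
    p = sc._ranksum_pvalues(np.array(a)[:, None], np.array(b)[:, None])[0]
    assert p == pytest.approx(0.1, rel=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_exact_path_agrees_with_enumeration_on_random_data(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=5)
    b = rng.normal(loc=0.8, size=6)
    expected = brute_force_ranksum_p(a, b)
    got = sc._ranksum_pvalues(a[:, None], b[:, None])[0]
    assert got == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_normal_approximation_close_to_exact_8v8(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=8)
    b = rng.normal(loc=0.5, size=8)
    exact = sc._ranksum_pvalues(a[:, None], b[:, None])[0]
    approx = sc._ranksum_pvalues(a[:, None], b[:, None], force_asymptotic=True)[0]
    assert abs(approx - exact) < 0.02


def test_identical_groups_are_ns():
    vals = np.tile([[1.0], [2.0], [3.0]], (1, 1))
    deg = sc.wilcoxon_deg(vals, vals.copy(), ["g0"])
    assert deg.loc["g0", "pval"] == pytest.approx(1.0)
    assert deg.loc["g0", "log2fc"] == pytest.approx(0.0)
    assert deg.loc["g0", "direction"] == "ns"


def test_wilcoxon_symmetry(small_norm):
    X = small_norm.X[:20]
    deg_ab = sc.wilcoxon_deg(X[:10], X[10:], list(small_norm.var_names))
    deg_ba = sc.wilcoxon_deg(X[10:], X[:10], list(small_norm.var_names))
    np.testing.assert_allclose(deg_ab["pval"], deg_ba["pval"], rtol=1e-9)
    np.testing.assert_allclose(deg_ab["log2fc"], -deg_ba["log2fc"], atol=1e-9)


def test_deg_between_rejects_overlap(small_norm):
    mask = np.zeros(small_norm.n_obs, dtype=bool)
    mask[:10] = True
    with pytest.raises(ValueError, match="overlap"):
        sc.deg_between(small_norm, mask, mask)


def test_planted_deg_recall_and_fdr():
    """Planted 2-fold genes at n=100 cells/group: recall >= 0.9, FDR <= 0.1."""
    rng = np.random.default_rng(7)
    # plant DE in 10% of genes so library-composition shifts stay negligible
    n_genes, n_planted, n_cells = 400, 40, 100
    means = rng.lognormal(1.3, 0.6, size=n_genes)
    means_b = means.copy()
    means_b[:n_planted] *= 2.0
    r = 1 / 0.3
    Xa = rng.poisson(rng.gamma(r, np.tile(means, (n_cells, 1)) / r))
    Xb = rng.poisson(rng.gamma(r, np.tile(means_b, (n_cells, 1)) / r))
    genes = [f"g{j}" for j in range(n_genes)]
    na = sc.normalize(_adata(Xa))
    nb = sc.normalize(_adata(Xb))
    deg = sc.wilcoxon_deg(nb.X, na.X, genes)
    called = set(deg.index[deg["direction"] != "ns"])
    planted = set(genes[:n_planted])
    recall = len(called & planted) / n_planted
    fdr = len(called - planted) / max(1, len(called))
    assert recall >= 0.9
    assert fdr <= 0.1


# ----------------------------------------------------------------------- BH


def test_bh_closed_forms():
    np.testing.assert_allclose(sc.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04], rtol=1e-12)
    np.testing.assert_allclose(sc.bh_adjust([0.3]), [0.3])
    np.testing.assert_allclose(sc.bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        sc.bh_adjust([0.1, 1.5])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_bounded_and_dominates_raw(pvals):
    adj = sc.bh_adjust(pvals)
    assert ((adj >= np.asarray(pvals) - 1e-12) & (adj <= 1.0 + 1e-12)).all()
    # monotone in the order statistics
    order = np.argsort(pvals)
    assert (np.diff(adj[order]) >= -1e-12).all()


# ------------------------------------------------------------------- Fisher


def test_fisher_hypergeometric_closed_form():
    res = sc.fisher_enrichment(
        query_genes=[f"g{i}" for i in range(10)],
        gene_sets={"hit": [f"g{i}" for i in range(10)]},
        universe=[f"g{i}" for i in range(20)],
    )
    assert res.loc["hit", "pval"] == pytest.approx(1 / math.comb(20, 10), rel=1e-9)
    assert res.loc["hit", "enriched"]


def test_fisher_no_overlap_and_full_set():
    universe = [f"g{i}" for i in range(40)]
    res = sc.fisher_enrichment(
        query_genes=universe[:5],
        gene_sets={"disjoint": universe[10:14], "everything": universe},
        universe=universe,
    )
    assert res.loc["disjoint", "pval"] == pytest.approx(1.0, abs=0.25)
    assert res.loc["everything", "pval"] == pytest.approx(1.0)
    assert not res.loc["disjoint", "enriched"]


def test_fisher_rejects_query_outside_universe():
    with pytest.raises(ValueError, match="absent"):
        sc.fisher_enrichment(["x"], {"s": ["a"]}, ["a", "b"])
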