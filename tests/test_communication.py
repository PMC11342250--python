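"""Communication-probability model, permutation test, aggregation levels and
differential networks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import anndata as ad
import somagerm as sg
from somagerm import communication as comm
from somagerm.lrdb import LRDatabase, LRInteraction


PARAMS = sg.CommParams(n_perm=50, seed=1)


def _norm_from_values(values, cell_types, genes):
    values = np.asarray(values, dtype=float)
    obs = pd.DataFrame(
        {"cell_type": cell_types, "condition": "WT", "timepoint": "d3_5"},
        index=[f"c{i}" for i in range(values.shape[0])],
    )
    return ad.AnnData(X=values, obs=obs, var=pd.DataFrame(index=list(genes)))


def _db(pairs):
    return LRDatabase([
        LRInteraction(f"i{k}", lig, tuple(rec), "secreted", pw,
                      antagonists=tuple(ant))
        for k, (lig, rec, pw, ant) in enumerate(pairs)
    ])


# ------------------------------------------------- probability closed forms


@pytest.mark.parametrize(
    "L, R, A, expected",
    [
        (1.0, (1.0,), 0.0, 2.0 / 3.0),
        (0.0, (1.0,), 0.0, 0.0),
        (1.0, (0.0,), 0.0, 0.0),
        (1.0, (1.0,), 0.5, 1.0 / 3.0),
        (4.0, (9.0,), 0.0, 36.0 / 36.5),
    ],
)
def test_interaction_probability_closed_forms(L, R, A, expected):
    assert sg.interaction_probability(L, R, A) == pytest.approx(expected, rel=1e-12)


def test_geometric_mean_receptor_subunits():
    # subunits 1 and 4 -> R = 2; L = 1 -> P = 2 / 2.5
    assert sg.interaction_probability(1.0, (1.0, 4.0)) == pytest.approx(0.8)


def test_probability_rejects_negative_inputs():
    with pytest.raises(ValueError):
        sg.interaction_probability(-1.0, (1.0,))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    L=st.floats(0, 10), dL=st.floats(0, 5),
    R=st.floats(0, 10), dR=st.floats(0, 5),
    A=st.floats(0, 10), dA=st.floats(0, 5),
)
def test_probability_monotone_and_bounded(L, dL, R, dR, A, dA):
    p0 = sg.interaction_probability(L, (R,), A)
    assert 0.0 <= p0 <= 1.0
    assert sg.interaction_probability(L + dL, (R,), A) >= p0 - 1e-12
    assert sg.interaction_probability(L, (R + dR,), A) >= p0 - 1e-12
    assert sg.interaction_probability(L, (R,), A + dA) <= p0 + 1e-12


def test_probability_limits():
    assert sg.interaction_probability(1e9, (1e9,)) == pytest.approx(1.0, abs=1e-9)
    assert sg.interaction_probability(0.0, (1e9,)) == 0.0


# -------------------------------------------------------- type expression


def test_celltype_expression_threshold_and_mean():
    # gene g0: expressed in 1/20 cells of type a -> below 10% fraction -> 0
    # gene g1: values 0 and 2 alternating -> mean 1, fraction 0.5 -> kept
    vals = np.zeros((20, 2))
    vals[0, 0] = 5.0
    vals[::2, 1] = 2.0
    norm = _norm_from_values(vals, ["a"] * 20, ["g0", "g1"])
    assert sg.communication.celltype_expression(norm, "a", "g0") == 0.0
    assert sg.communication.celltype_expression(norm, "a", "g1") == pytest.approx(1.0)
    with pytest.raises(KeyError):
        sg.communication.celltype_expression(norm, "a", "nope")


# ------------------------------------------------------- permutation test


def test_pvalues_bounded_and_zero_prob_is_one(small_norm, small_db):
    params = sg.CommParams(n_perm=40, seed=3)
    cr = sg.infer_communication(small_norm, None, small_db, params)
    assert cr.pval.min() >= 1.0 / 41 - 1e-12
    assert cr.pval.max() <= 1.0
    zero = cr.P == 0
    assert (cr.pval[zero] == 1.0).all()
    assert not cr.significant[zero].any()


def test_inference_deterministic_under_seed(small_norm, small_db):
    a = sg.infer_communication(small_norm, None, small_db, PARAMS)
    b = sg.infer_communication(small_norm, None, small_db, PARAMS)
    np.testing.assert_array_equal(a.P, b.P)
    np.testing.assert_array_equal(a.pval, b.pval)


def test_absent_gene_skips_interaction_with_warning(small_norm, caplog):
    db = _db([("not_a_gene", ["InR"], "insulin", [])])
    with caplog.at_level("WARNING"):
        cr = sg.infer_communication(small_norm, None, db, PARAMS)
    assert cr.P.shape[2] == 0
    assert "skipping interaction" in caplog.text


def test_planted_circuit_is_significant(small_norm, small_db):
    cr = sg.infer_communication(
        small_norm[small_norm.obs["condition"] == "mutant"], None, small_db,
        sg.CommParams(n_perm=100, seed=2))
    i = [r.interaction_id for r in cr.interactions].index("circuit_0_Dilp6")
    s = cr.cell_types.index("hub")
    r = cr.cell_types.index("GSC_spermatogonia")
    assert cr.P[s, r, i] > 0.5
    assert cr.pval[s, r, i] <= 0.05


def test_permutation_null_calibration():
    """Label permutation p-values are near-uniform when labels carry no
    signal: fraction below 0.05 stays in [0.03, 0.07] and the KS statistic
    against uniform is < 0.15 (p-values pooled over pairs, n_perm=200)."""
    fracs = []
    pooled = []
    for seed in (1, 2, 3):
        adata = sg.synthetic_data.generate_null_counts(
            n_cells=240, n_genes=60, n_cell_types=4, seed=seed)
        norm = sg.normalize(adata)
        db = sg.synthetic_data.null_decoy_db(list(norm.var_names), n_pairs=8,
                                             seed=seed)
        pv = comm.permutation_test(norm, norm.obs["cell_type"].to_numpy(), db,
                                   sg.CommParams(n_perm=200, seed=seed))
        pooled.append(pv.ravel())
        fracs.append((pv < 0.05).mean())
    assert abs(np.mean(fracs) - 0.05) <= 0.02
    pooled = np.concatenate(pooled)
    grid = np.linspace(0, 1, 101)
    ks = np.abs(np.searchsorted(np.sort(pooled), grid) / len(pooled) - grid).max()
    assert ks < 0.15


# ------------------------------------------------------------ aggregation


def _toy_result():
    # 2 cell types, 3 interactions in 2 pathways with hand-set P and pvals
    P = np.zeros((2, 2, 3))
    P[0, 1, 0] = 0.3
    P[0, 1, 1] = 0.2
    P[1, 0, 2] = 0.4
    pval = np.full((2, 2, 3), 1.0)
    pval[0, 1, 0] = pval[0, 1, 1] = pval[1, 0, 2] = 0.01
    recs = [
        LRInteraction("a", "l1", ("r1",), "secreted", "insulin"),
        LRInteraction("b", "l2", ("r2",), "secreted", "insulin"),
        LRInteraction("c", "l3", ("r3",), "secreted", "BMP"),
    ]
    return comm.CommResult("WT", ["CySC", "GSC"], recs, P, pval, 0.05)


def test_pathway_sum_and_network_marginals():
    cr = _toy_result()
    pw = comm.aggregate_pathway(cr)
    assert pw.matrices["insulin"][0, 1] == pytest.approx(0.5)
    assert pw.matrices["BMP"][1, 0] == pytest.approx(0.4)
    net = comm.aggregate_network(cr)
    total = sum(pw.matrices.values())
    np.testing.assert_allclose(net.strength, total, rtol=1e-12)
    np.testing.assert_allclose(net.outgoing, net.strength.sum(axis=1))
    np.testing.assert_allclose(net.incoming, net.strength.sum(axis=0))
    assert sg.count_significant_pairs(cr) == 3 == int(cr.significant.sum())


def test_no_significant_pairs_gives_zero_matrices():
    cr = _toy_result()
    cr.pval[:] = 1.0
    assert sg.count_significant_pairs(cr) == 0
    assert not comm.aggregate_network(cr).strength.any()


def test_differential_network_antisymmetry_and_values():
    a, b = _toy_result(), _toy_result()
    b.P = b.P * 0.5
    d_ab = comm.differential_network(a, b)
    d_ba = comm.differential_network(b, a)
    np.testing.assert_allclose(d_ab.strength_diff, -d_ba.strength_diff)
    np.testing.assert_allclose(d_ab.pair_diff, -d_ba.pair_diff)
    assert d_ab.strength_diff[0, 1] == pytest.approx(0.25)
    zero = comm.differential_network(a, a)
    assert not zero.strength_diff.any()


def test_differential_network_rejects_mismatched_types():
    a = _toy_result()
    b = _toy_result()
    b.cell_types = ["CySC", "hub"]
    with pytest.raises(ValueError, match="cell-type"):
        comm.differential_network(a, b)


def test_relative_contribution_normalizes():
    cr = _toy_result()
    frac = comm.relative_contribution(cr, "insulin", "GSC")
    assert frac.sum() == pytest.approx(1.0, abs=1e-12)
    assert frac["a"] == pytest.approx(0.6)
    assert frac["b"] == pytest.approx(0.4)
    single = comm.relative_contribution(cr, "BMP", "CySC")
    assert single["c"] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="significant"):
        comm.relative_contribution(cr, "BMP", "GSC")


# --------------------------------------------------- planted-circuit diffs


def test_differential_recovery_across_seeds():
    """Mutant-amplified ligand->receptor circuit with a WT-restricted
    antagonist: aggregate incoming strength into the receiver type rises in
    the mutant in >= 9/10 seeds."""
    hits = 0
    for seed in range(10):
        cfg = sg.SimConfig(
            n_genes=120, cell_types=("hub", "CySC", "GSC_spermatogonia"),
            cells_per_type_per_condition=40, timepoints=("d3_5",),
            alpha_schedule=(0.5,), seed=seed,
        )
        adata, _ = sg.generate_counts(cfg)
        norm = sg.normalize(adata)
        db = sg.synthetic_lrdb(cfg, n_decoy_pairs=5)
        params = sg.CommParams(n_perm=50, seed=seed)
        results = {}
        for cond in ("WT", "mutant"):
            sub = norm[norm.obs["condition"] == cond]
            results[cond] = sg.infer_communication(
                sub, sub.obs["cell_type"].to_numpy(), db, params, condition=cond)
        diff = comm.differential_network(results["mutant"], results["WT"])
        r = diff.cell_types.index("GSC_spermatogonia")
        if diff.strength_diff[:, r].sum() > 0:
            hits += 1
    assert hits >= 9
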