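"""Single-cell statistical substrate: normalization, pseudobulk, DEG and enrichment.

The count container is an :class:`anndata.AnnData` with obligatory obs columns
``cell_type``, ``condition`` and ``timepoint``. Normalization is log1p of
counts-per-10k (natural log). Differential expression follows the two-sided
Wilcoxon rank-sum test with a linear fold-change threshold: a gene is a DEG
when raw p < 0.05 and fold change >= 1.5 (or <= 1/1.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

import anndata as ad

REQUIRED_OBS = ("cell_type", "condition", "timepoint")


@dataclass(frozen=True)
class StatParams:
    """Thresholds for DEG calling and enrichment.

    p_threshold and fc_threshold implement the rule "rank-sum p < 0.05 and
    |fold change| >= 1.5"; the pseudocount keeps fold changes finite on
    all-zero groups.
    """

    p_threshold: float = 0.05
    fc_threshold: float = 1.5
    pseudocount: float = 1e-9
    enrichment_adj_p: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_threshold", "fc_threshold", "pseudocount", "enrichment_adj_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def validate_counts(adata: ad.AnnData) -> None:
    """Check the count-matrix contract: non-negative integers, complete metadata."""
    X = _dense(adata.X)
    if (X < 0).any():
        raise ValueError("count matrix contains negative entries")
    if not np.allclose(X, np.round(X)):
        raise ValueError("count matrix contains non-integer entries")
    for col in REQUIRED_OBS:
        if col not in adata.obs.columns:
            raise ValueError(f"missing obs column {col!r}")
        if adata.obs[col].isna().any():
            raise ValueError(f"obs column {col!r} has missing values")
    if adata.var_names.duplicated().any():
        raise ValueError("gene ids are not unique")


def normalize(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """log1p counts-per-10k: value(c,g) = ln(1 + target_sum * count(c,g)/total(c)).

    Returns a new AnnData with float X; obs/var are shared views of the input.
    Cells with zero total are an error (there is nothing to scale).
    """
    X = _dense(adata.X).astype(np.float64)
    totals = X.sum(axis=1)
    bad = np.flatnonzero(totals == 0)
    if bad.size:
        names = list(adata.obs_names[bad[:10]])
        raise ValueError(f"cells with zero total counts: {names}")
    vals = np.log1p(target_sum * X / totals[:, None])
    return ad.AnnData(X=vals, obs=adata.obs.copy(), var=adata.var.copy())


def pseudobulk(norm: ad.AnnData, group_keys: Sequence[str]) -> pd.DataFrame:
    """Per-group arithmetic mean of normalized values; groups x genes.

    Index is a MultiIndex over group_keys (or plain index for one key);
    empty groups cannot arise (groups are defined by the cells present), but
    an empty input is rejected.
    """
    if norm.n_obs == 0:
        raise ValueError("cannot pseudobulk an empty matrix")
    df = pd.DataFrame(_dense(norm.X), columns=norm.var_names, index=norm.obs_names)
    for k in group_keys:
        df[k] = norm.obs[k].values
    out = df.groupby(list(group_keys), observed=True, sort=True).mean()
    return out


# ---------------------------------------------------------------- rank-sum DEG


def _ranksum_pvalues(
    a: np.ndarray, b: np.ndarray, force_asymptotic: bool = False
) -> np.ndarray:
    """Two-sided rank-sum p per column (gene).

    Exact enumeration (scipy) when both groups have <= 10 observations and a
    column has no ties; otherwise the tie-corrected normal approximation with
    continuity correction. A column with zero rank variance (all values tied)
    gets p = 1.
    """
    n1, n2 = a.shape[0], b.shape[0]
    n = n1 + n2
    pooled = np.vstack([a, b])
    ranks = stats.rankdata(pooled, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    # tie correction per column
    pvals = np.empty(pooled.shape[1])
    small = n1 <= 10 and n2 <= 10 and not force_asymptotic
    for j in range(pooled.shape[1]):
        col = pooled[:, j]
        _, counts = np.unique(col, return_counts=True)
        has_ties = (counts > 1).any()
        if small and not has_ties:
            pvals[j] = stats.mannwhitneyu(a[:, j], b[:, j], method="exact").pvalue
            continue
        tie_term = float((counts**3 - counts).sum())
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            pvals[j] = 1.0
            continue
        z = (u1[j] - mu - 0.5 * np.sign(u1[j] - mu)) / math.sqrt(var)
        pvals[j] = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return pvals


def wilcoxon_deg(
    values_a: np.ndarray,
    values_b: np.ndarray,
    gene_ids: Sequence[str],
    params: StatParams = StatParams(),
) -> pd.DataFrame:
    """Differential expression of group A (e.g. mutant) vs group B (e.g. WT).

    Inputs are normalized (log1p CP10K) value matrices, cells x genes. Fold
    change is computed on the linear scale: (mean expm1 A + pc)/(mean expm1 B
    + pc). Returns a DataFrame indexed by gene with columns log2fc, pval,
    padj (BH) and direction in {up, down, ns}.
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if values_a.shape[0] < 3 or values_b.shape[0] < 3:
        raise ValueError("each group needs at least 3 cells")
    if values_a.shape[1] != values_b.shape[1] or values_a.shape[1] != len(gene_ids):
        raise ValueError("gene dimensions do not agree")

    pvals = _ranksum_pvalues(values_a, values_b)
    mean_a = np.expm1(values_a).mean(axis=0)
    mean_b = np.expm1(values_b).mean(axis=0)
    fc = (mean_a + params.pseudocount) / (mean_b + params.pseudocount)
    log2fc = np.log2(fc)
    padj = bh_adjust(pvals)

    direction = np.full(len(gene_ids), "ns", dtype=object)
    sig = pvals < params.p_threshold
    direction[sig & (fc >= params.fc_threshold)] = "up"
    direction[sig & (fc <= 1.0 / params.fc_threshold)] = "down"

    return pd.DataFrame(
        {"log2fc": log2fc, "pval": pvals, "padj": padj, "direction": direction},
        index=pd.Index(gene_ids, name="gene"),
    )


def deg_between(
    norm: ad.AnnData,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    params: StatParams = StatParams(),
) -> pd.DataFrame:
    """Convenience wrapper: DEG table between two boolean cell masks."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if (mask_a & mask_b).any():
        raise ValueError("groups overlap")
    X = _dense(norm.X)
    return wilcoxon_deg(X[mask_a], X[mask_b], list(norm.var_names), params)


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    params: StatParams = StatParams(),
) -> pd.DataFrame:
    """One-sided (upper-tail) Fisher's exact enrichment of a query in gene sets.

    For each set the 2x2 table over the universe is tested with
    alternative="greater" (equivalently the hypergeometric upper tail
    including the observed overlap); p-values are BH-adjusted across sets and
    sets with adjusted p below ``params.enrichment_adj_p`` are flagged.
    """
    universe = set(universe)
    query = set(query_genes)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes absent from universe: {sorted(stray)[:10]}")
    rows = []
    for name, genes in gene_sets.items():
        genes = set(genes) & universe
        k = len(query & genes)
        table = [
            [k, len(query) - k],
            [len(genes) - k, len(universe) - len(query) - len(genes) + k],
        ]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append({"gene_set": name, "overlap": k, "set_size": len(genes),
                     "odds_ratio": odds, "pval": p})
    out = pd.DataFrame(rows).set_index("gene_set")
    out["padj"] = bh_adjust(out["pval"]) if len(out) else []
    out["enriched"] = out["padj"] < params.enrichment_adj_p
    return out
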