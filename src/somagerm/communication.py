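"""Cell-cell communication inference at three levels, with differential networks.

For every (sender type, receiver type, ligand-receptor pair) triple a bounded
communication probability is computed from cell-type mean expression via a
Hill saturation of the ligand x receptor product with a hyperbolic antagonist
attenuation:

    R = geometric mean of receptor-subunit expression
    x = (L * R)^n
    P = x / (K^n + x) * K_ant / (K_ant + A)

where L is sender-side ligand expression, A the mean antagonist expression
over sender and receiver types (short-range antagonism, e.g. secreted ImpL2
sequestering the insulin ligand Dilp6), K the half-saturation constant, n the
Hill exponent. Gene-level expression per cell type is the mean normalized
value, zeroed when fewer than ``min_expr_fraction`` of the type's cells
express the gene. Significance comes from a global cell-type label
permutation test with an add-one p-value estimator; results aggregate to the
signaling-pathway level (sum of significant pair probabilities per pathway)
and the overall network level (sender x receiver interaction strength with
outgoing/incoming marginals). Two conditions compare by elementwise
difference at all three levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import anndata as ad

from .lrdb import LRDatabase, LRInteraction
from .sc_core import _dense

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CommParams:
    K: float = 0.5
    n: float = 1.0
    K_ant: float = 0.5
    min_expr_fraction: float = 0.1
    n_perm: int = 100
    sig_p: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K <= 0 or self.K_ant <= 0:
            raise ValueError("K and K_ant must be > 0")
        if self.n < 1:
            raise ValueError("Hill exponent n must be >= 1")
        if not (0.0 <= self.min_expr_fraction <= 1.0):
            raise ValueError("min_expr_fraction must lie in [0, 1]")
        if self.n_perm < 20:
            raise ValueError("n_perm must be >= 20")
        if not (0.0 < self.sig_p < 1.0):
            raise ValueError("sig_p must lie in (0, 1)")


@dataclass
class CommResult:
    """Sender x receiver x interaction probability tensor for one condition."""

    condition: str
    cell_types: list[str]
    interactions: list[LRInteraction]
    P: np.ndarray  # (T, T, I), entries in [0, 1]
    pval: np.ndarray  # same shape, entries in (0, 1]
    sig_p: float

    @property
    def significant(self) -> np.ndarray:
        return (self.pval < self.sig_p) & (self.P > 0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (sender, receiver, interaction)."""
        rows = []
        sig = self.significant
        for i, rec in enumerate(self.interactions):
            for s, sender in enumerate(self.cell_types):
                for r, receiver in enumerate(self.cell_types):
                    rows.append(
                        {"condition": self.condition, "sender": sender,
                         "receiver": receiver, "interaction_id": rec.interaction_id,
                         "pathway": rec.pathway, "probability": self.P[s, r, i],
                         "pval": self.pval[s, r, i],
                         "significant": bool(sig[s, r, i])}
                    )
        return pd.DataFrame(rows)


@dataclass
class PathwayComm:
    cell_types: list[str]
    matrices: dict[str, np.ndarray]  # pathway -> (T, T)


@dataclass
class NetworkSummary:
    cell_types: list[str]
    strength: np.ndarray  # (T, T)

    @property
    def outgoing(self) -> np.ndarray:
        return self.strength.sum(axis=1)

    @property
    def incoming(self) -> np.ndarray:
        return self.strength.sum(axis=0)


@dataclass
class DiffNetwork:
    cell_types: list[str]
    interaction_ids: list[str]
    pair_diff: np.ndarray  # (T, T, I) significant-masked mutant - WT
    pathway_diff: dict[str, np.ndarray]
    strength_diff: np.ndarray  # (T, T)


# --------------------------------------------------------------- expression


def _thresholded_means(
    X: np.ndarray, labels: np.ndarray, cell_types: Sequence[str], min_frac: float
) -> np.ndarray:
    """(T, G) mean normalized expression per type, zeroed below the expressed
    fraction threshold."""
    T, G = len(cell_types), X.shape[1]
    out = np.zeros((T, G))
    for t, ct in enumerate(cell_types):
        sub = X[labels == ct]
        if sub.shape[0] == 0:
            continue
        means = sub.mean(axis=0)
        frac = (sub > 0).mean(axis=0)
        means[frac < min_frac] = 0.0
        out[t] = means
    return out


def celltype_expression(
    norm: ad.AnnData, cell_type: str, gene: str, params: CommParams = CommParams()
) -> float:
    """Mean normalized expression of a gene in a cell type, or 0 when expressed
    in fewer than ``min_expr_fraction`` of the type's cells."""
    if gene not in norm.var_names:
        raise KeyError(f"unknown gene {gene!r}")
    labels = norm.obs["cell_type"].to_numpy()
    if cell_type not in labels:
        raise KeyError(f"unknown cell type {cell_type!r}")
    X = _dense(norm.X)
    j = list(norm.var_names).index(gene)
    E = _thresholded_means(X[:, [j]], labels, [cell_type], params.min_expr_fraction)
    return float(E[0, 0])


def interaction_probability(
    L: float,
    R_subunits: Sequence[float],
    A: float = 0.0,
    params: CommParams = CommParams(),
) -> float:
    """Closed-form communication probability for scalar expression summaries."""
    if L < 0 or A < 0 or any(r < 0 for r in R_subunits):
        raise ValueError("expression summaries must be >= 0")
    R = float(np.prod(R_subunits)) ** (1.0 / len(R_subunits))
    x = (L * R) ** params.n
    return float(x / (params.K**params.n + x) * params.K_ant / (params.K_ant + A))


# ---------------------------------------------------------------- inference


def _resolve_interactions(
    db: LRDatabase, var_names: Sequence[str]
) -> tuple[list[LRInteraction], dict[str, int]]:
    present = set(var_names)
    kept = []
    for rec in db:
        genes = (rec.ligand, *rec.receptor_subunits, *rec.antagonists)
        missing = [g for g in genes if g not in present]
        if missing:
            logger.warning(
                "skipping interaction %s: genes absent from matrix: %s",
                rec.interaction_id, missing,
            )
            continue
        kept.append(rec)
    idx = {g: i for i, g in enumerate(var_names)}
    return kept, idx


def _probability_tensor(
    E: np.ndarray,
    interactions: Sequence[LRInteraction],
    gene_idx: dict[str, int],
    params: CommParams,
) -> np.ndarray:
    """(T, T, I) tensor from a (T, G) thresholded-mean expression matrix."""
    T = E.shape[0]
    P = np.zeros((T, T, len(interactions)))
    for i, rec in enumerate(interactions):
        L = E[:, gene_idx[rec.ligand]]  # (T,)
        sub = E[:, [gene_idx[g] for g in rec.receptor_subunits]]  # (T, S)
        R = np.prod(sub, axis=1) ** (1.0 / sub.shape[1])
        x = np.outer(L, R) ** params.n
        hill = x / (params.K**params.n + x)
        if rec.antagonists:
            ant = E[:, [gene_idx[g] for g in rec.antagonists]].mean(axis=1)  # (T,)
            A = (ant[:, None] + ant[None, :]) / 2.0  # sender/receiver mean
            hill = hill * params.K_ant / (params.K_ant + A)
        P[:, :, i] = hill
    return P


def _observed_tensor(norm, labels, db, params):
    labels = np.asarray(labels)
    cell_types = sorted(set(labels))
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    X = _dense(norm.X)
    interactions, gene_idx = _resolve_interactions(db, list(norm.var_names))
    genes_needed = sorted({g for rec in interactions for g in
                           (rec.ligand, *rec.receptor_subunits, *rec.antagonists)})
    cols = [gene_idx[g] for g in genes_needed]
    sub_idx = {g: j for j, g in enumerate(genes_needed)}
    Xs = X[:, cols]
    E = _thresholded_means(Xs, labels, cell_types, params.min_expr_fraction)
    P = _probability_tensor(E, interactions, sub_idx, params)
    return cell_types, interactions, labels, Xs, sub_idx, P


def permutation_test(
    norm: ad.AnnData,
    labels: Sequence[str],
    db: LRDatabase,
    params: CommParams = CommParams(),
) -> np.ndarray:
    """p-value tensor from global cell-type label permutations.

    p = (1 + #{P_perm >= P_obs}) / (1 + n_perm), permutations drawn with the
    seed in params; p is therefore in [1/(1+n_perm), 1].
    """
    cell_types, interactions, labels, Xs, sub_idx, P_obs = _observed_tensor(
        norm, labels, db, params
    )
    rng = np.random.default_rng(params.seed)
    exceed = np.zeros_like(P_obs)
    for _ in range(params.n_perm):
        perm = rng.permutation(labels)
        E = _thresholded_means(Xs, perm, cell_types, params.min_expr_fraction)
        P_perm = _probability_tensor(E, interactions, sub_idx, params)
        exceed += P_perm >= P_obs
    return (1.0 + exceed) / (1.0 + params.n_perm)


def infer_communication(
    norm: ad.AnnData,
    labels: Sequence[str] | None = None,
    db: LRDatabase = None,
    params: CommParams = CommParams(),
    condition: str = "",
) -> CommResult:
    """Full pair-level inference: probabilities, permutation p-values, mask.

    ``labels`` defaults to obs['cell_type']. Interactions whose genes are
    absent from the matrix are skipped with a logged warning.
    """
    if db is None or len(db) == 0:
        raise ValueError("a non-empty ligand-receptor database is required")
    if labels is None:
        labels = norm.obs["cell_type"].to_numpy()
    cell_types, interactions, labels, Xs, sub_idx, P = _observed_tensor(
        norm, labels, db, params
    )
    rng = np.random.default_rng(params.seed)
    exceed = np.zeros_like(P)
    for _ in range(params.n_perm):
        perm = rng.permutation(labels)
        E = _thresholded_means(Xs, perm, cell_types, params.min_expr_fraction)
        P_perm = _probability_tensor(E, interactions, sub_idx, params)
        exceed += P_perm >= P
    pval = (1.0 + exceed) / (1.0 + params.n_perm)
    return CommResult(condition=condition, cell_types=cell_types,
                      interactions=interactions, P=P, pval=pval,
                      sig_p=params.sig_p)


# -------------------------------------------------------------- aggregation


def aggregate_pathway(cr: CommResult, db: LRDatabase | None = None) -> PathwayComm:
    """Per-pathway sender x receiver matrix: sum of significant pair
    probabilities for the pathway's interactions."""
    sig = cr.significant
    masked = cr.P * sig
    pathways = sorted({rec.pathway for rec in cr.interactions})
    mats = {}
    for pw in pathways:
        idx = [i for i, rec in enumerate(cr.interactions) if rec.pathway == pw]
        mats[pw] = masked[:, :, idx].sum(axis=2)
    return PathwayComm(cell_types=list(cr.cell_types), matrices=mats)


def aggregate_network(cr: CommResult) -> NetworkSummary:
    """Aggregate interaction strength: sum of significant pair probabilities."""
    strength = (cr.P * cr.significant).sum(axis=2)
    return NetworkSummary(cell_types=list(cr.cell_types), strength=strength)


def differential_network(cr_mut: CommResult, cr_wt: CommResult) -> DiffNetwork:
    """Mutant minus WT at pair, pathway and aggregate level."""
    if cr_mut.cell_types != cr_wt.cell_types:
        raise ValueError("cell-type sets differ between conditions")
    ids_m = [r.interaction_id for r in cr_mut.interactions]
    ids_w = [r.interaction_id for r in cr_wt.interactions]
    if ids_m != ids_w:
        raise ValueError("interaction sets differ between conditions")
    pair_diff = cr_mut.P * cr_mut.significant - cr_wt.P * cr_wt.significant
    pw_mut = aggregate_pathway(cr_mut).matrices
    pw_wt = aggregate_pathway(cr_wt).matrices
    zeros = np.zeros_like(cr_mut.P[:, :, 0])
    pathway_diff = {
        pw: pw_mut.get(pw, zeros) - pw_wt.get(pw, zeros)
        for pw in sorted(set(pw_mut) | set(pw_wt))
    }
    strength_diff = (aggregate_network(cr_mut).strength
                     - aggregate_network(cr_wt).strength)
    return DiffNetwork(cell_types=list(cr_mut.cell_types), interaction_ids=ids_m,
                       pair_diff=pair_diff, pathway_diff=pathway_diff,
                       strength_diff=strength_diff)


def relative_contribution(
    cr: CommResult, pathway: str, receiver_type: str
) -> pd.Series:
    """Fraction of a pathway's signal into a receiver carried by each pair.

    For each interaction of the pathway: sender-summed significant
    probability into the receiver, divided by the pathway total into that
    receiver. Fractions sum to 1.
    """
    r = cr.cell_types.index(receiver_type)
    masked = cr.P * cr.significant
    idx = [i for i, rec in enumerate(cr.interactions) if rec.pathway == pathway]
    if not idx:
        raise ValueError(f"pathway {pathway!r} has no interactions in this result")
    sums = {cr.interactions[i].interaction_id: masked[:, r, i].sum() for i in idx}
    total = sum(sums.values())
    if total <= 0:
        raise ValueError(
            f"pathway {pathway!r} has no significant signal into {receiver_type!r}"
        )
    return pd.Series({k: v / total for k, v in sums.items()}).sort_index()


def count_significant_pairs(cr: CommResult) -> int:
    """Number of significant (sender, receiver, interaction) triples."""
    return int(cr.significant.sum())
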