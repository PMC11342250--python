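"""Pseudobulk sex-identity scoring and the toward-female DEG trend.

A query pseudobulk profile (e.g. the feminizing somatic cyst lineage of the
mutant) is correlated against male and female reference profiles by Pearson's
r on shared, detectably expressed genes. Separately, each differentially
expressed gene is classed "toward female" when its mutant-vs-WT change points
the same way as the female-vs-WT reference difference, and "divergent"
otherwise — the dichotomy behind statements like "most DEGs trended toward
female expression patterns".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SexIdentityScore:
    context: str
    r_male: float
    r_female: float
    n_genes_used: int


@dataclass(frozen=True)
class TrendReport:
    n_deg: int
    n_toward_female: int
    n_divergent: int

    @property
    def fraction_toward_female(self) -> float:
        return self.n_toward_female / self.n_deg


def correlation_identity(
    query: pd.Series,
    male_ref: pd.Series,
    female_ref: pd.Series,
    detection_floor: float = 0.1,
    min_genes: int = 10,
    context: str = "",
) -> SexIdentityScore:
    """Pearson r of a query profile against male and female references.

    Profiles are gene-indexed mean normalized expression. Computation is
    restricted to genes present in all three profiles whose mean reference
    expression exceeds ``detection_floor``; fewer than ``min_genes`` such
    genes is an error.
    """
    shared = query.index.intersection(male_ref.index).intersection(female_ref.index)
    ref_mean = (male_ref.loc[shared] + female_ref.loc[shared]) / 2.0
    genes = shared[ref_mean.to_numpy() > detection_floor]
    if len(genes) < min_genes:
        raise ValueError(
            f"only {len(genes)} shared detectable genes (need >= {min_genes})"
        )
    q = query.loc[genes].to_numpy()
    r_m = stats.pearsonr(q, male_ref.loc[genes].to_numpy()).statistic
    r_f = stats.pearsonr(q, female_ref.loc[genes].to_numpy()).statistic
    return SexIdentityScore(context=context, r_male=float(r_m), r_female=float(r_f),
                            n_genes_used=int(len(genes)))


def feminization_trend(
    deg: pd.DataFrame,
    wt_profile: pd.Series,
    female_ref: pd.Series,
) -> TrendReport:
    """Classify DEGs as toward-female or divergent by sign concordance.

    ``deg`` is a gene-indexed table with columns ``log2fc`` (mutant vs WT)
    and ``direction``; only rows called up or down participate. A DEG is
    toward_female when sign(log2fc) equals sign(female_ref - wt_profile) for
    that gene; genes with zero reference difference are divergent. Profiles
    must cover every DEG gene.
    """
    called = deg[deg["direction"].isin(["up", "down"])]
    if len(called) == 0:
        raise ValueError("no DEGs to classify")
    missing = [g for g in called.index
               if g not in wt_profile.index or g not in female_ref.index]
    if missing:
        raise ValueError(f"DEG genes missing from a profile: {missing[:10]}")
    change = np.sign(called["log2fc"].to_numpy())
    ref_diff = np.sign(
        female_ref.loc[called.index].to_numpy() - wt_profile.loc[called.index].to_numpy()
    )
    toward = (change == ref_diff) & (ref_diff != 0)
    return TrendReport(
        n_deg=int(len(called)),
        n_toward_female=int(toward.sum()),
        n_divergent=int((~toward).sum()),
    )
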