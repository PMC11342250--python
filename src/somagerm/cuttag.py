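"""Binding-site (CUT&Tag peak) analysis: I/O, reproducibility, promoter
annotation, condition-differential binding and direct-target intersection.

All interval arithmetic is 0-based half-open, matching BED. Peaks are consumed
here, not called: the module starts from per-condition, per-replicate peak
lists (BED or ENCODE narrowPeak), derives replicate-reproducible sites,
assigns each site to its nearest transcription start site, compares matched
site scores between conditions, and intersects condition-downregulated sites'
genes with a differential-expression gene list to produce direct targets of
the profiled factor, each labelled with an inferred regulation mode.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

STRANDS = ("+", "-")
MODES = ("activated_by_factor", "repressed_by_factor", "unresolved")


class PeakParseError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise PeakParseError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


def read_peaks(path: str | Path) -> list[GenomicInterval]:
    """Read a BED (>= 3 columns) or ENCODE narrowPeak (10 columns) file.

    narrowPeak's signalValue (column 7) maps to score; for BED, column 5 does
    when present. Malformed lines raise with their 1-based line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PeakParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError:
                raise PeakParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            score: float | None = None
            if len(fields) >= 10:  # narrowPeak: signalValue is column 7
                score = float(fields[6])
            elif len(fields) >= 5 and fields[4] not in (".", ""):
                score = float(fields[4])
            try:
                out.append(GenomicInterval(chrom, start, end, name=name,
                                           score=score, strand=strand))
            except PeakParseError as e:
                raise PeakParseError(f"{path}:{lineno}: {e}") from None
    return out


def write_peaks(peaks: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write 6-column BED; score column holds the interval score (0 if unset)."""
    with open(path, "w") as fh:
        for p in peaks:
            score = 0.0 if p.score is None else p.score
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{score:g}\t"
                     f"{p.strand}\n")


def read_tss(path: str | Path) -> pd.DataFrame:
    """TSS table TSV with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str,
                                            "tss": int, "strand": str})
    return validate_tss(df)


def validate_tss(df: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"TSS table must have columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_id in TSS table: {dups[:5]}")
    bad = ~df["strand"].isin(STRANDS)
    if bad.any():
        raise ValueError(f"invalid strand values: {df.loc[bad, 'strand'].unique()}")
    return df


def _trees(peaks: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    return trees


def reproducible_peaks(
    rep1: Sequence[GenomicInterval], rep2: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Peaks of rep1 that overlap (>= 1 bp) some rep2 peak.

    Coordinates come from rep1; the score becomes the mean score of the
    overlapping rep2 partners (unchanged if no partner carries a score).
    """
    trees = _trees(rep2)
    out: list[GenomicInterval] = []
    for p in rep1:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        hits = tree.overlap(p.start, p.end)
        if not hits:
            continue
        scores = [h.data.score for h in hits if h.data.score is not None]
        score = float(np.mean(scores)) if scores else p.score
        out.append(replace(p, score=score))
    return out


def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    tss: pd.DataFrame,
    promoter_window: int = 1000,
    distal_window: int = 3000,
    gene_spans: Sequence[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Assign each peak to its nearest TSS with a strand-aware signed distance.

    Distance is measured from the peak midpoint to the TSS; negative means
    upstream of the gene. Feature classes: promoter_1kb (|d| <= promoter
    window, inclusive), promoter_3kb (|d| <= distal window), then genic if
    the midpoint falls in a supplied gene span, else intergenic. Equidistant
    TSS ties break to the lexicographically smaller gene_id.
    """
    tss = validate_tss(tss)
    if len(tss) == 0:
        raise ValueError("empty TSS table")
    span_trees = _trees(gene_spans) if gene_spans else {}
    by_chrom = {c: g.sort_values(["tss", "gene_id"]) for c, g in tss.groupby("chrom")}

    rows = []
    for p in peaks:
        mid = p.midpoint
        sub = by_chrom.get(p.chrom)
        gene, dist = None, np.nan
        if sub is not None:
            absd = (sub["tss"] - mid).abs().to_numpy()
            best = absd.min()
            cands = sub[absd == best].sort_values("gene_id")
            row = cands.iloc[0]
            gene = row["gene_id"]
            dist = mid - row["tss"] if row["strand"] == "+" else row["tss"] - mid
        if gene is not None and abs(dist) <= promoter_window:
            feat = "promoter_1kb"
        elif gene is not None and abs(dist) <= distal_window:
            feat = "promoter_3kb"
        else:
            tree = span_trees.get(p.chrom)
            genic = tree is not None and bool(tree.overlap(int(mid), int(mid) + 1))
            feat = "genic" if genic else "intergenic"
        rows.append({"chrom": p.chrom, "start": p.start, "end": p.end,
                     "name": p.name, "gene_id": gene, "distance_to_tss": dist,
                     "feature": feat})
    return pd.DataFrame(rows)


def differential_binding(
    peaks_wt: Sequence[GenomicInterval],
    peaks_mut: Sequence[GenomicInterval],
    log2fc_threshold: float = 1.0,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Classify binding sites as condition-up or -down by overlap and score.

    A WT peak overlapping a mutant peak is compared via log2(mut/wt) of
    scores: >= threshold is up, <= -threshold is down, between is unchanged
    (dropped). WT-only peaks are down; mutant-only peaks are up. Returns
    (up_sites, down_sites); up sites carry mutant coordinates for
    mutant-only peaks, otherwise the WT interval.
    """
    mut_trees = _trees(peaks_mut)
    wt_trees = _trees(peaks_wt)
    up: list[GenomicInterval] = []
    down: list[GenomicInterval] = []

    for p in peaks_wt:
        tree = mut_trees.get(p.chrom)
        hits = tree.overlap(p.start, p.end) if tree is not None else set()
        if not hits:
            down.append(p)
            continue
        # partner = greatest overlap, ties to smaller start
        def ov(h):
            return min(p.end, h.end) - max(p.start, h.begin)
        partner = sorted(hits, key=lambda h: (-ov(h), h.begin))[0].data
        if p.score is None or partner.score is None:
            raise ValueError(
                f"matched peaks without scores at {p.chrom}:{p.start}-{p.end}"
            )
        lfc = np.log2(partner.score / p.score)
        if lfc >= log2fc_threshold:
            up.append(p)
        elif lfc <= -log2fc_threshold:
            down.append(p)

    for q in peaks_mut:
        tree = wt_trees.get(q.chrom)
        if tree is None or not tree.overlap(q.start, q.end):
            up.append(q)
    return up, down


@dataclass(frozen=True)
class DirectTarget:
    gene_id: str
    binding_direction: str
    expression_direction: str
    mode: str


@dataclass
class DirectTargetSet:
    targets: list[DirectTarget]

    @property
    def genes(self) -> set[str]:
        return {t.gene_id for t in self.targets}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.targets])


def regulation_mode(binding_direction: str, expression_direction: str) -> str:
    """Infer how the factor acts on a direct target.

    Binding lost in the condition where the factor is depleted, together with
    lost expression, implies the factor was activating the gene; lost binding
    with gained expression implies repression. Other combinations stay
    unresolved.
    """
    for d in (binding_direction, expression_direction):
        if d not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {d!r}")
    if binding_direction == "down" and expression_direction == "down":
        return "activated_by_factor"
    if binding_direction == "down" and expression_direction == "up":
        return "repressed_by_factor"
    return "unresolved"


def direct_targets(
    down_site_genes: Iterable[str],
    deg_directions: Mapping[str, str] | Iterable[str],
) -> DirectTargetSet:
    """Genes with condition-downregulated binding AND differential expression.

    ``deg_directions`` may be a mapping gene -> expression direction
    ('up'/'down'), in which case regulation modes are called; a bare iterable
    of DEG gene ids yields modes 'unresolved'.
    """
    down = set(down_site_genes)
    if isinstance(deg_directions, Mapping):
        dirs = dict(deg_directions)
    else:
        dirs = {g: None for g in deg_directions}
    hits = sorted(down & set(dirs))
    targets = []
    for g in hits:
        expr = dirs[g]
        mode = regulation_mode("down", expr) if expr in ("up", "down") else "unresolved"
        targets.append(DirectTarget(g, "down", expr if expr else "unknown", mode))
    return DirectTargetSet(targets)
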