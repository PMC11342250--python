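"""Curated Drosophila ligand-receptor interaction database: schema, I/O, composition.

A record links one secreted/contact ligand gene to a receptor that may have
several subunits, carries a pathway label (BMP, JAK-STAT, insulin, ...) and an
interaction category, and may name antagonist/agonist genes that modulate the
pair (e.g. the secreted insulin antagonist ImpL2 on the Ilp6-InR pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

CATEGORIES = ("secreted", "ecm_receptor", "contact")

#: dialect-tolerant category spellings, keyed on the canonicalized token
_CATEGORY_ALIASES = {
    "secreted": "secreted",
    "secreted signaling": "secreted",
    "ecm receptor": "ecm_receptor",
    "ecm_receptor": "ecm_receptor",
    "extracellular matrix receptor": "ecm_receptor",
    "contact": "contact",
    "cell cell contact": "contact",
    "cell contact": "contact",
}

_COLUMNS = (
    "interaction_id",
    "ligand",
    "receptor_subunits",
    "category",
    "pathway",
    "antagonists",
    "agonists",
)


class LRDBValidationError(ValueError):
    """Raised for schema or content violations in an interaction table."""


def normalize_category(token: str) -> str:
    """Map a category spelling to its canonical token.

    Case-insensitive; runs of spaces, hyphens and underscores collapse to a
    single space before lookup, so "Secreted Signaling", "ECM-Receptor" and
    "cell-cell contact" all resolve.
    """
    key = " ".join(token.strip().lower().replace("-", " ").replace("_", " ").split())
    try:
        return _CATEGORY_ALIASES[key]
    except KeyError:
        raise LRDBValidationError(f"unknown interaction category: {token!r}") from None


@dataclass(frozen=True)
class LRInteraction:
    interaction_id: str
    ligand: str
    receptor_subunits: tuple[str, ...]
    category: str
    pathway: str
    antagonists: tuple[str, ...] = ()
    agonists: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.interaction_id:
            raise LRDBValidationError("interaction_id must be non-empty")
        if not self.ligand:
            raise LRDBValidationError(
                f"{self.interaction_id}: ligand must be non-empty"
            )
        if not self.receptor_subunits or any(not s for s in self.receptor_subunits):
            raise LRDBValidationError(
                f"{self.interaction_id}: receptor_subunits must be non-empty"
            )
        if self.category not in CATEGORIES:
            raise LRDBValidationError(
                f"{self.interaction_id}: category {self.category!r} not in {CATEGORIES}"
            )


@dataclass
class LRDatabase:
    """An ordered collection of interactions with a derived pathway vocabulary."""

    interactions: list[LRInteraction]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.interactions:
            if rec.interaction_id in seen:
                raise LRDBValidationError(
                    f"duplicate interaction_id: {rec.interaction_id!r}"
                )
            seen.add(rec.interaction_id)

    @property
    def pathway_vocabulary(self) -> set[str]:
        return {rec.pathway for rec in self.interactions}

    def __len__(self) -> int:
        return len(self.interactions)

    def __iter__(self):
        return iter(self.interactions)

    def genes(self) -> set[str]:
        """All gene symbols referenced anywhere in the database."""
        out: set[str] = set()
        for rec in self.interactions:
            out.add(rec.ligand)
            out.update(rec.receptor_subunits)
            out.update(rec.antagonists)
            out.update(rec.agonists)
        return out


def _split_genes(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    parts = [p.strip() for p in str(cell).split(",")]
    return tuple(p for p in parts if p)


def read_lrdb(path: str | Path) -> LRDatabase:
    """Read a tab-separated interaction table, validating as it goes.

    Expected columns: interaction_id, ligand, receptor_subunits (comma-joined),
    category, pathway, antagonists (comma-joined, may be empty), agonists.
    Record order follows file order; gene symbols are whitespace-trimmed and
    category tokens normalized via :func:`normalize_category`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise LRDBValidationError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            LRInteraction(
                interaction_id=str(row.interaction_id).strip(),
                ligand=str(row.ligand).strip(),
                receptor_subunits=_split_genes(row.receptor_subunits),
                category=normalize_category(str(row.category)),
                pathway=str(row.pathway).strip(),
                antagonists=_split_genes(row.antagonists),
                agonists=_split_genes(row.agonists),
            )
        )
    return LRDatabase(records)


def write_lrdb(db: LRDatabase, path: str | Path) -> None:
    rows = [
        {
            "interaction_id": r.interaction_id,
            "ligand": r.ligand,
            "receptor_subunits": ",".join(r.receptor_subunits),
            "category": r.category,
            "pathway": r.pathway,
            "antagonists": ",".join(r.antagonists),
            "agonists": ",".join(r.agonists),
        }
        for r in db.interactions
    ]
    pd.DataFrame(rows, columns=list(_COLUMNS)).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CompositionReport:
    total: int
    counts: dict[str, int]
    percentages: dict[str, float]  # one decimal place, half-away-from-zero
    n_pathways: int


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def composition_stats(db: LRDatabase) -> CompositionReport:
    """Count interactions per category and report one-decimal percentages.

    Percentages are 100*count/total rounded half-away-from-zero to one
    decimal, so a category of 3 in 256 reports 1.2 (1.17 at two decimals).
    """
    if len(db) == 0:
        raise LRDBValidationError("composition_stats requires a non-empty database")
    counts = {c: 0 for c in CATEGORIES}
    for rec in db.interactions:
        counts[rec.category] += 1
    total = len(db)
    percentages = {c: _round1(100.0 * n / total) for c, n in counts.items()}
    return CompositionReport(
        total=total,
        counts=counts,
        percentages=percentages,
        n_pathways=len(db.pathway_vocabulary),
    )


def build_database(records: Iterable[LRInteraction] | Sequence[dict]) -> LRDatabase:
    """Build a database from LRInteraction objects or plain dicts."""
    recs = []
    for r in records:
        if isinstance(r, LRInteraction):
            recs.append(r)
        else:
            d = dict(r)
            d["receptor_subunits"] = tuple(d["receptor_subunits"])
            d["antagonists"] = tuple(d.get("antagonists", ()))
            d["agonists"] = tuple(d.get("agonists", ()))
            d["category"] = normalize_category(d["category"])
            recs.append(LRInteraction(**d))
    return LRDatabase(recs)
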