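"""Two-condition, three-timepoint testis-like scRNA-seq simulator with ground truth.

The generator emulates the design of the study this package supports: wild-type
("WT") and somatically feminized mutant ("mutant") testes sampled at three ages
(d3_5, d6_8, d9_11), with a designated somatic cell type (default "CySC")
whose mutant expression program is blended toward a female follicle-cell
program by a per-timepoint factor alpha in [0, 1]:

    E[expr | mutant, feminizing type, t] = (1 - alpha_t) * male + alpha_t * female

Counts are negative binomial (gamma-Poisson) around those means with log-normal
library-size variation. Planted ligand->receptor circuits — modeled on the
insulin axis Dilp6 -> InR with the secreted antagonist ImpL2 — are injected
additively on the linear mean scale, so expected communication probabilities
downstream are analytically computable. Toy peak/TSS fixtures plant WT-only
promoter binding sites over a known target-gene subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import anndata as ad

from .lrdb import LRDatabase, LRInteraction, build_database
from .cuttag import GenomicInterval

CONDITIONS = ("WT", "mutant")
DEFAULT_TIMEPOINTS = ("d3_5", "d6_8", "d9_11")
DEFAULT_CELL_TYPES = (
    "hub",
    "CySC",
    "early_cyst",
    "intermediate_cyst",
    "GSC_spermatogonia",
    "spermatocyte",
    "spermatid",
    "pigment",
)


class SimConfigError(ValueError):
    """Raised for inconsistent simulation configuration."""


@dataclass(frozen=True)
class PlantedCircuit:
    """A ligand->receptor circuit injected into the simulation.

    ``strength_by_condition`` is the additive linear-scale mean expression
    added to the ligand gene in sender cells and to every receptor subunit in
    receiver cells, per condition. The optional antagonist gene (the ImpL2
    role) gets its own per-condition additive mean, expressed in both sender
    and receiver types (short-range antagonism).
    """

    ligand_gene: str
    receptor_genes: tuple[str, ...]
    sender_type: str
    receiver_type: str
    strength_by_condition: Mapping[str, float]
    antagonist_gene: str | None = None
    antagonist_strength_by_condition: Mapping[str, float] | None = None
    pathway: str = "insulin"

    def __post_init__(self) -> None:
        if not self.receptor_genes:
            raise SimConfigError("circuit needs at least one receptor subunit")
        for cond, s in self.strength_by_condition.items():
            if cond not in CONDITIONS:
                raise SimConfigError(f"unknown condition {cond!r} in circuit")
            if s < 0:
                raise SimConfigError("circuit strengths must be >= 0")
        if self.antagonist_strength_by_condition:
            if self.antagonist_gene is None:
                raise SimConfigError("antagonist strength given without a gene")
            if any(v < 0 for v in self.antagonist_strength_by_condition.values()):
                raise SimConfigError("antagonist strengths must be >= 0")

    def genes(self) -> tuple[str, ...]:
        extra = (self.antagonist_gene,) if self.antagonist_gene else ()
        return (self.ligand_gene, *self.receptor_genes, *extra)


def default_circuits() -> tuple[PlantedCircuit, ...]:
    """The reference insulin-axis circuit: hub-derived Dilp6 onto germline InR,
    antagonized by ImpL2 which is present in WT soma and lost in the mutant."""
    return (
        PlantedCircuit(
            ligand_gene="Dilp6",
            receptor_genes=("InR",),
            sender_type="hub",
            receiver_type="GSC_spermatogonia",
            strength_by_condition={"WT": 2.0, "mutant": 6.0},
            antagonist_gene="ImpL2",
            antagonist_strength_by_condition={"WT": 4.0, "mutant": 0.0},
            pathway="insulin",
        ),
    )


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 2000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    cells_per_type_per_condition: int = 150  # per timepoint
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    alpha_schedule: tuple[float, ...] = (0.25, 0.5, 0.75)
    feminizing_cell_type: str = "CySC"
    sex_biased_fraction: float = 0.3
    divergent_fraction: float = 0.1
    nb_dispersion: float = 0.4
    library_size_mean: float = 5000.0
    library_size_sigma: float = 0.35
    circuits: tuple[PlantedCircuit, ...] = field(default_factory=default_circuits)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 50:
            raise SimConfigError("n_genes must be >= 50")
        if self.cells_per_type_per_condition < 1:
            raise SimConfigError("cells_per_type_per_condition must be positive")
        if len(self.alpha_schedule) != len(self.timepoints):
            raise SimConfigError("alpha_schedule must match timepoints in length")
        if any(not (0.0 <= a <= 1.0) for a in self.alpha_schedule):
            raise SimConfigError("alpha values must lie in [0, 1]")
        if any(b < a for a, b in zip(self.alpha_schedule, self.alpha_schedule[1:])):
            raise SimConfigError("alpha_schedule must be non-decreasing")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise SimConfigError("nb_dispersion and library_size_mean must be > 0")
        if not (0.0 <= self.sex_biased_fraction <= 1.0):
            raise SimConfigError("sex_biased_fraction must lie in [0, 1]")
        if not (0.0 <= self.divergent_fraction <= 1.0):
            raise SimConfigError("divergent_fraction must lie in [0, 1]")
        if self.feminizing_cell_type not in self.cell_types:
            raise SimConfigError("feminizing_cell_type not among cell_types")
        for c in self.circuits:
            if c.sender_type not in self.cell_types:
                raise SimConfigError(f"circuit sender {c.sender_type!r} unknown")
            if c.receiver_type not in self.cell_types:
                raise SimConfigError(f"circuit receiver {c.receiver_type!r} unknown")

    def gene_ids(self) -> list[str]:
        """Circuit genes first (named), then numbered background genes."""
        named: list[str] = []
        for c in self.circuits:
            for g in c.genes():
                if g not in named:
                    named.append(g)
        if len(named) > self.n_genes:
            raise SimConfigError("more circuit genes than n_genes")
        n_bg = self.n_genes - len(named)
        return named + [f"g{i:04d}" for i in range(n_bg)]


@dataclass
class GroundTruth:
    """Everything needed to recompute expected values independently."""

    gene_ids: list[str]
    male_program: np.ndarray  # linear mean scale, per gene
    female_program: np.ndarray
    type_factors: dict[str, np.ndarray]  # per cell type multiplicative factor
    alpha_by_timepoint: dict[str, float]
    feminizing_cell_type: str
    circuits: list[PlantedCircuit]
    sex_biased_up: list[str]  # male-high genes
    sex_biased_down: list[str]  # female-high genes
    divergent_folds: dict[str, float] = field(default_factory=dict)
    true_target_genes: list[str] = field(default_factory=list)

    def expected_mean(self, cell_type: str, condition: str, timepoint: str) -> pd.Series:
        """Expected linear-scale mean expression vector before library scaling."""
        base = self.male_program * self.type_factors[cell_type]
        gi = {g: i for i, g in enumerate(self.gene_ids)}
        if condition == "mutant" and cell_type == self.feminizing_cell_type:
            a = self.alpha_by_timepoint[timepoint]
            base = (1.0 - a) * self.male_program + a * self.female_program
            # mutant-specific dysregulation unrelated to sex identity
            base = base.copy()
            for g, fold in self.divergent_folds.items():
                base[gi[g]] *= fold
        mean = base.copy()
        for c in self.circuits:
            s = c.strength_by_condition.get(condition, 0.0)
            if cell_type == c.sender_type:
                mean[gi[c.ligand_gene]] += s
            if cell_type == c.receiver_type:
                for r in c.receptor_genes:
                    mean[gi[r]] += s
            if c.antagonist_gene and c.antagonist_strength_by_condition:
                sa = c.antagonist_strength_by_condition.get(condition, 0.0)
                if cell_type in (c.sender_type, c.receiver_type):
                    mean[gi[c.antagonist_gene]] += sa
        return pd.Series(mean, index=self.gene_ids)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_ids": self.gene_ids,
            "male_program": self.male_program.tolist(),
            "female_program": self.female_program.tolist(),
            "type_factors": {k: v.tolist() for k, v in self.type_factors.items()},
            "alpha_by_timepoint": self.alpha_by_timepoint,
            "feminizing_cell_type": self.feminizing_cell_type,
            "circuits": [
                {**asdict(c),
                 "strength_by_condition": dict(c.strength_by_condition),
                 "antagonist_strength_by_condition": (
                     dict(c.antagonist_strength_by_condition)
                     if c.antagonist_strength_by_condition else None)}
                for c in self.circuits
            ],
            "sex_biased_up": self.sex_biased_up,
            "sex_biased_down": self.sex_biased_down,
            "divergent_folds": self.divergent_folds,
            "true_target_genes": self.true_target_genes,
        }
        Path(path).write_text(json.dumps(payload))


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _make_programs(config: SimConfig):
    """Programs plus the explicit male-high / female-high gene index sets."""
    rng = _rng(config, 0)
    genes = config.gene_ids()
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    n_named = sum(1 for g in genes if not g.startswith("g"))
    # circuit genes start from zero so planted strengths fully control them
    base[:n_named] = 0.0
    male = base.copy()
    female = base.copy()

    n_biased = int(round(config.sex_biased_fraction * config.n_genes))
    if n_biased > config.n_genes - n_named:
        raise SimConfigError("sex_biased_fraction too large for background gene count")
    candidates = np.arange(n_named, config.n_genes)
    chosen = rng.choice(candidates, size=n_biased, replace=False)
    folds = rng.uniform(2.0, 6.0, size=n_biased)
    half = n_biased // 2
    male_high = chosen[: half + n_biased % 2]
    female_high = chosen[half + n_biased % 2:]
    female[male_high] = male[male_high] / folds[: len(male_high)]
    male[female_high] = female[female_high] / folds[len(male_high):]
    return (
        pd.Series(male, index=genes, name="male"),
        pd.Series(female, index=genes, name="female"),
        sorted(np.asarray(genes, dtype=object)[male_high]),
        sorted(np.asarray(genes, dtype=object)[female_high]),
    )


def generate_reference_programs(config: SimConfig) -> tuple[pd.Series, pd.Series]:
    """Male and female per-gene mean-expression programs on the linear scale.

    A ``sex_biased_fraction`` of genes differ by at least 2-fold between the
    programs (half male-high, half female-high); the rest are shared exactly.
    Circuit genes are never sex-biased so planted circuit means stay clean.
    """
    male, female, _, _ = _make_programs(config)
    return male, female


def _type_factors(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-type multiplicative modulation of the male program.

    The feminizing type keeps factor 1 so that its WT mean equals the male
    program exactly and the alpha-blend identities hold analytically.
    """
    factors: dict[str, np.ndarray] = {}
    n_named = sum(1 for g in config.gene_ids() if not g.startswith("g"))
    for ct in config.cell_types:
        f = np.ones(config.n_genes)
        if ct != config.feminizing_cell_type:
            n_marker = max(1, config.n_genes // 20)
            idx = rng.choice(np.arange(n_named, config.n_genes), size=n_marker,
                             replace=False)
            f[idx] = rng.uniform(2.0, 6.0, size=n_marker)
        factors[ct] = f
    return factors


def generate_counts(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Sample the full cells x genes negative-binomial count matrix.

    Cell order is deterministic: condition, then timepoint, then cell type.
    obs columns: cell_type, condition, timepoint.
    """
    male, female, male_high, female_high = _make_programs(config)
    rng = _rng(config, 1)
    factors = _type_factors(config, rng)
    # mutant-dysregulated genes outside the sex programs: these become DEGs in
    # the feminizing type whose change is NOT toward the female program
    genes = config.gene_ids()
    biased = set(male_high) | set(female_high)
    shared = [g for g in genes if g.startswith("g") and g not in biased]
    n_div = min(int(round(config.divergent_fraction * config.n_genes)), len(shared))
    div_rng = _rng(config, 5)
    div_genes = [shared[i] for i in
                 sorted(div_rng.choice(len(shared), size=n_div, replace=False))]
    div_mult = div_rng.uniform(2.0, 6.0, size=n_div)
    flip = div_rng.random(n_div) < 0.5
    div_mult[flip] = 1.0 / div_mult[flip]
    gt = GroundTruth(
        gene_ids=config.gene_ids(),
        male_program=male.to_numpy(),
        female_program=female.to_numpy(),
        type_factors=factors,
        alpha_by_timepoint=dict(zip(config.timepoints, config.alpha_schedule)),
        feminizing_cell_type=config.feminizing_cell_type,
        circuits=list(config.circuits),
        sex_biased_up=male_high,
        sex_biased_down=female_high,
        divergent_folds=dict(zip(div_genes, div_mult.tolist())),
    )

    sample_rng = _rng(config, 2)
    r = 1.0 / config.nb_dispersion
    blocks: list[np.ndarray] = []
    obs_rows: list[tuple[str, str, str]] = []
    n_cells = config.cells_per_type_per_condition
    for cond in CONDITIONS:
        for tp in config.timepoints:
            for ct in config.cell_types:
                mean = gt.expected_mean(ct, cond, tp).to_numpy()
                scaled = mean / mean.sum() * config.library_size_mean
                sig = config.library_size_sigma
                lib = sample_rng.lognormal(mean=-0.5 * sig**2, sigma=sig, size=n_cells)
                cell_means = lib[:, None] * scaled[None, :]
                lam = sample_rng.gamma(shape=r, scale=cell_means / r)
                blocks.append(sample_rng.poisson(lam))
                obs_rows.extend((ct, cond, tp) for _ in range(n_cells))
    X = np.vstack(blocks).astype(np.int64)
    obs = pd.DataFrame(obs_rows, columns=["cell_type", "condition", "timepoint"])
    obs.index = [f"cell{i:06d}" for i in range(len(obs))]
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=config.gene_ids()))
    return adata, gt


# ----------------------------------------------------------------- peak fixtures


@dataclass(frozen=True)
class PeakFixtureConfig:
    n_target_genes: int = 6  # genes with WT-only promoter peaks
    n_decoy_genes: int = 24  # genes with condition-shared promoter peaks
    n_replicates: int = 2
    jitter_bp: int = 30
    gene_spacing: int = 10_000
    chrom: str = "chr_toy"

    def __post_init__(self) -> None:
        if self.n_target_genes < 1 or self.n_decoy_genes < 0:
            raise SimConfigError("need at least one target gene")
        if self.jitter_bp < 0 or self.jitter_bp > 50:
            raise SimConfigError("replicate jitter must be in [0, 50] bp")


def generate_peak_fixtures(
    config: SimConfig,
    ground_truth: GroundTruth | None = None,
    fixture: PeakFixtureConfig = PeakFixtureConfig(),
) -> tuple[dict[str, list[list[GenomicInterval]]], pd.DataFrame, GroundTruth]:
    """Toy peak/TSS fixtures with planted WT-only promoter binding.

    Target genes (a subset of male-high sex-biased genes, so they are DEGs in
    the feminized cell type) get a WT-only peak within 1 kb of their TSS;
    decoy genes get equal-score peaks in both conditions. Replicate intervals
    are jittered by at most ``jitter_bp``. Returns
    (peaks[condition] -> list of replicate peak lists, TSS table, GroundTruth
    with true_target_genes filled).
    """
    if ground_truth is None:
        _, ground_truth = generate_counts(config)
    genes = ground_truth.gene_ids
    if len(genes) < 10:
        raise SimConfigError("peak fixtures need >= 10 genes")
    male_high = [g for g in ground_truth.sex_biased_up]
    if len(male_high) < fixture.n_target_genes:
        raise SimConfigError("not enough male-high genes to plant targets")
    targets = male_high[: fixture.n_target_genes]
    pool = [g for g in genes if g not in targets]
    decoys = pool[: fixture.n_decoy_genes]
    universe = targets + decoys

    rng = _rng(config, 3)
    tss_rows = []
    for i, g in enumerate(universe):
        tss_rows.append(
            {"gene_id": g, "chrom": fixture.chrom,
             "tss": fixture.gene_spacing * (i + 1),
             "strand": "+" if i % 2 == 0 else "-"}
        )
    tss = pd.DataFrame(tss_rows)

    def make_peak(tss_pos: int, name: str, score: float, jit: int) -> GenomicInterval:
        start = max(0, tss_pos - 400 + jit)
        return GenomicInterval(fixture.chrom, start, start + 300, name=name,
                               score=score)

    peaks: dict[str, list[list[GenomicInterval]]] = {c: [] for c in CONDITIONS}
    jitters = {
        (g, rep): int(rng.integers(-fixture.jitter_bp, fixture.jitter_bp + 1))
        if fixture.jitter_bp else 0
        for g in universe for rep in range(fixture.n_replicates)
    }
    for cond in CONDITIONS:
        for rep in range(fixture.n_replicates):
            plist: list[GenomicInterval] = []
            for g, row in zip(universe, tss_rows):
                is_target = g in targets
                if is_target and cond == "mutant":
                    continue  # WT-only binding: lost in the mutant
                score = 8.0 if is_target else 5.0
                plist.append(make_peak(row["tss"], f"{g}_peak", score,
                                       jitters[(g, rep)]))
            peaks[cond].append(plist)

    ground_truth.true_target_genes = list(targets)
    return peaks, tss, ground_truth


# ---------------------------------------------------------------- database fixtures


def synthetic_lrdb(config: SimConfig, n_decoy_pairs: int = 20) -> LRDatabase:
    """Ligand-receptor database matching the simulation: the planted circuits
    plus decoy pairs over background genes split across a few pathways."""
    records: list[LRInteraction] = []
    for i, c in enumerate(config.circuits):
        records.append(
            LRInteraction(
                interaction_id=f"circuit_{i}_{c.ligand_gene}",
                ligand=c.ligand_gene,
                receptor_subunits=tuple(c.receptor_genes),
                category="secreted",
                pathway=c.pathway,
                antagonists=(c.antagonist_gene,) if c.antagonist_gene else (),
            )
        )
    genes = [g for g in config.gene_ids() if g.startswith("g")]
    pathways = ("BMP", "EGFR", "Hedgehog", "JAK-STAT")
    rng = _rng(config, 4)
    pick = rng.choice(len(genes), size=min(2 * n_decoy_pairs, len(genes)),
                      replace=False)
    for j in range(len(pick) // 2):
        lig, rec = genes[pick[2 * j]], genes[pick[2 * j + 1]]
        records.append(
            LRInteraction(
                interaction_id=f"decoy_{j}_{lig}",
                ligand=lig,
                receptor_subunits=(rec,),
                category="secreted" if j % 5 else "ecm_receptor",
                pathway=pathways[j % len(pathways)],
            )
        )
    return LRDatabase(records)


_PATHWAY_14 = (
    "BMP", "Activin", "JAK-STAT", "EGFR", "TNF", "Hedgehog", "FGFR",
    "insulin", "Wnt-TCF", "Wnt-Ca2+", "Notch", "Pvr", "Hippo", "Toll",
)


def synthetic_signaling_database() -> LRDatabase:
    """Synthetic stand-in for the published curated Drosophila signaling database.

    The real curated table is a supplementary resource; this synthetic
    reconstruction reproduces only its composition — 256 interactions of
    which 222 are secreted-signaling, 31 ECM-receptor and 3 cell-cell
    contact, spread over the 14 named pathways — with placeholder gene
    symbols. It exists so composition statistics can be exercised at the
    published scale; it carries no real interaction curation.
    """
    records = []
    counts = {"secreted": 222, "ecm_receptor": 31, "contact": 3}
    i = 0
    for cat, n in counts.items():
        for k in range(n):
            records.append(
                LRInteraction(
                    interaction_id=f"syn_{cat}_{k}",
                    ligand=f"L{i}",
                    receptor_subunits=(f"R{i}",),
                    category=cat,
                    pathway=_PATHWAY_14[i % len(_PATHWAY_14)],
                )
            )
            i += 1
    return LRDatabase(records)


def generate_null_counts(
    n_cells: int = 400,
    n_genes: int = 100,
    n_cell_types: int = 4,
    nb_dispersion: float = 0.4,
    seed: int = 0,
) -> ad.AnnData:
    """Counts where cell-type labels carry no expression signal.

    Every cell draws from the same negative-binomial gene program; labels are
    assigned round-robin. Used to calibrate permutation p-values: any
    apparent type-specific communication is a false positive.
    """
    rng = np.random.default_rng(seed)
    means = rng.lognormal(mean=1.0, sigma=0.7, size=n_genes)
    r = 1.0 / nb_dispersion
    lam = rng.gamma(shape=r, scale=np.tile(means, (n_cells, 1)) / r)
    X = rng.poisson(lam).astype(np.int64)
    obs = pd.DataFrame(
        {
            "cell_type": [f"type{i % n_cell_types}" for i in range(n_cells)],
            "condition": "WT",
            "timepoint": "d3_5",
        },
        index=[f"cell{i:05d}" for i in range(n_cells)],
    )
    var = pd.DataFrame(index=[f"g{i:04d}" for i in range(n_genes)])
    return ad.AnnData(X=X, obs=obs, var=var)


def null_decoy_db(gene_ids: Sequence[str], n_pairs: int = 10, seed: int = 0
                  ) -> LRDatabase:
    """Decoy ligand-receptor pairs over arbitrary genes (for null calibration)."""
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(gene_ids), size=2 * n_pairs, replace=False)
    records = [
        LRInteraction(
            interaction_id=f"null_{j}",
            ligand=gene_ids[pick[2 * j]],
            receptor_subunits=(gene_ids[pick[2 * j + 1]],),
            category="secreted",
            pathway="null",
        )
        for j in range(n_pairs)
    ]
    return LRDatabase(records)


def program_to_profile(program: pd.Series, target_sum: float = 1e4) -> pd.Series:
    """Expected normalized profile of a linear-scale mean program.

    Applies the same transform as count normalization — log1p of the program
    rescaled to ``target_sum`` — so reference programs are comparable with
    pseudobulk profiles of normalized counts.
    """
    vals = program.to_numpy(dtype=float)
    return pd.Series(np.log1p(target_sum * vals / vals.sum()), index=program.index,
                     name=program.name)


# ------------------------------------------------------------------- writers


def write_counts_mtx(adata: ad.AnnData, out_dir: str | Path) -> None:
    """counts.mtx + genes.tsv + barcodes.tsv + metadata.tsv under out_dir."""
    from scipy import io as sio
    from scipy import sparse

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(out / "counts.mtx", sparse.csr_matrix(adata.X))
    pd.Series(adata.var_names).to_csv(out / "genes.tsv", sep="\t", index=False,
                                      header=False)
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t", index=False,
                                      header=False)
    adata.obs.to_csv(out / "metadata.tsv", sep="\t")


def read_counts_mtx(in_dir: str | Path) -> ad.AnnData:
    from scipy import io as sio

    p = Path(in_dir)
    X = np.asarray(sio.mmread(p / "counts.mtx").todense()).astype(np.int64)
    genes = pd.read_csv(p / "genes.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(p / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    obs = pd.read_csv(p / "metadata.tsv", sep="\t", index_col=0)
    obs = obs.loc[barcodes]
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))


def write_tss(tss: pd.DataFrame, path: str | Path) -> None:
    tss.to_csv(path, sep="\t", index=False)
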