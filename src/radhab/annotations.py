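"""Annotation summaries: module completeness, presence calls, aggregation.

A metabolic module (KEGG-module style) is an ordered list of reaction
steps; each step lists alternative gene families (KO/Pfam/TIGRfam ids),
any one of which satisfies it.  A genome's completeness for a module is
the fraction of steps with at least one annotated gene family — gene
copy number beyond presence is ignored.  Completeness matrices are
thresholded into presence/absence calls (strict >0.70 for KEGG-module
style figures, non-strict >=0.75 for nutrient-cycling pathway calls),
aggregated to genus level over the top-3 most complete genomes per
genus, and summarised as family-level composition and cross-sample
shared-taxon sets.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError, MissingRecordError, ValidationError
from .qc import GenomeQuality

__all__ = [
    "RANKS",
    "AnnotationTable",
    "ModuleDefinition",
    "TaxonomyTable",
    "module_completeness",
    "completeness_matrix",
    "call_presence",
    "genus_aggregate",
    "family_composition",
    "shared_taxa",
    "read_module_definitions",
    "write_module_definitions",
    "KEGG_MODULE_THRESHOLD",
    "PATHWAY_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Canonical taxonomic ranks, shallow to deep.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Default presence thresholds.  KEGG-module calls are strict (>0.70);
#: nutrient-cycling pathway calls are non-strict (>=0.75).
KEGG_MODULE_THRESHOLD = 0.70
PATHWAY_THRESHOLD = 0.75


class AnnotationTable:
    """Long-format gene-family annotations: (genome_id, gene_family_id, count).

    Duplicate (genome, gene_family) rows are merged by summing counts at
    ingestion.  Counts must be non-negative integers.
    """

    def __init__(self, rows: Iterable[Sequence] | pd.DataFrame):
        if isinstance(rows, pd.DataFrame):
            df = rows[["genome_id", "gene_family_id", "count"]].copy()
        else:
            df = pd.DataFrame(rows, columns=["genome_id", "gene_family_id", "count"])
        df["genome_id"] = df["genome_id"].astype(str)
        df["gene_family_id"] = df["gene_family_id"].astype(str)
        counts = pd.to_numeric(df["count"], errors="raise")
        if (counts < 0).any():
            bad = df.loc[counts < 0].iloc[0]
            raise ValidationError(
                f"count must be >= 0 (genome {bad.genome_id!r}, "
                f"gene family {bad.gene_family_id!r})"
            )
        if (counts != counts.astype(int)).any():
            raise ValidationError("count must be an integer")
        df["count"] = counts.astype(int)
        self.df = (
            df.groupby(["genome_id", "gene_family_id"], as_index=False, sort=True)["count"]
            .sum()
        )
        self._present: dict[str, frozenset[str]] = {
            gid: frozenset(grp.loc[grp["count"] > 0, "gene_family_id"])
            for gid, grp in self.df.groupby("genome_id", sort=False)
        }

    @property
    def genomes(self) -> list[str]:
        return sorted(self._present)

    def families_present(self, genome_id: str) -> frozenset[str]:
        """Gene families with count > 0 in a genome (empty if unknown)."""
        return self._present.get(genome_id, frozenset())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        needed = {"genome_id", "gene_family_id", "count"}
        if not needed.issubset(df.columns):
            raise ValidationError(
                f"{path}: annotation table needs columns {sorted(needed)}, "
                f"got {list(df.columns)}"
            )
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ModuleDefinition:
    """One metabolic module: ordered steps of alternative gene families."""

    module_id: str
    category: str
    steps: tuple[frozenset[str], ...]

    def __init__(self, module_id: str, category: str, steps: Iterable[Iterable[str]]):
        object.__setattr__(self, "module_id", module_id)
        object.__setattr__(self, "category", category)
        object.__setattr__(
            self, "steps", tuple(frozenset(str(a) for a in step) for step in steps)
        )
        if not self.steps:
            raise ValidationError(f"module {module_id!r} must have >= 1 step")
        for i, step in enumerate(self.steps):
            if not step:
                raise ValidationError(f"module {module_id!r} step {i} has no alternatives")

    @property
    def n_steps(self) -> int:
        return len(self.steps)


def module_completeness(
    table: AnnotationTable, module: ModuleDefinition, genome_id: str
) -> float:
    """Fraction of module steps satisfied by at least one gene family.

    A genome absent from the table scores 0 (logged, not an error):
    absence of annotations is indistinguishable from absence of genes at
    this stage.
    """
    present = table.families_present(genome_id)
    if not present and genome_id not in table._present:
        logger.info("genome %r absent from annotation table; completeness 0", genome_id)
        return 0.0
    satisfied = sum(1 for step in module.steps if step & present)
    return satisfied / module.n_steps


def completeness_matrix(
    table: AnnotationTable,
    modules: Sequence[ModuleDefinition],
    genomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Genome x module grid of completeness fractions in [0, 1]."""
    ids = [m.module_id for m in modules]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate module ids: {ids}")
    genomes = list(genomes) if genomes is not None else table.genomes
    data = {
        m.module_id: [module_completeness(table, m, g) for g in genomes] for m in modules
    }
    return pd.DataFrame(data, index=pd.Index(genomes, name="genome_id"))


def call_presence(
    matrix: pd.DataFrame, threshold: float, strict: bool
) -> pd.DataFrame:
    """Threshold a completeness matrix into boolean presence calls.

    ``strict`` uses completeness > threshold; non-strict uses >=.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold!r}")
    return matrix.gt(threshold) if strict else matrix.ge(threshold)


class TaxonomyTable:
    """Per-genome rank assignments (domain..species); deeper ranks may be empty.

    Once a rank is unassigned, every deeper rank must also be unassigned.
    """

    def __init__(self, df: pd.DataFrame):
        missing = {"genome_id", *RANKS} - set(df.columns)
        if missing:
            raise ValidationError(f"taxonomy table missing columns: {sorted(missing)}")
        df = df[["genome_id", *RANKS]].copy()
        df["genome_id"] = df["genome_id"].astype(str)
        for rank in RANKS:
            df[rank] = df[rank].fillna("").astype(str)
        if df["genome_id"].duplicated().any():
            dups = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
            raise ValidationError(f"duplicate genome_ids in taxonomy table: {dups}")
        for genome_id, values in zip(
            df["genome_id"], df[list(RANKS)].itertuples(index=False, name=None)
        ):
            seen_empty = False
            for rank, value in zip(RANKS, values):
                if value == "":
                    seen_empty = True
                elif seen_empty:
                    raise ValidationError(
                        f"genome {genome_id!r}: rank {rank!r} assigned below an "
                        "unassigned rank"
                    )
        self.df = df.reset_index(drop=True)

    @property
    def genomes(self) -> list[str]:
        return self.df["genome_id"].tolist()

    def taxa_at(self, rank: str) -> set[str]:
        """Non-empty taxon names at a rank."""
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return set(self.df.loc[self.df[rank] != "", rank])

    def rank_map(self, rank: str) -> dict[str, str]:
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return dict(zip(self.df["genome_id"], self.df[rank]))

    def genus_map(self) -> dict[str, str]:
        return self.rank_map("genus")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTable":
        return cls(pd.read_csv(path, sep="\t", comment="#", keep_default_na=False))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def genus_aggregate(
    presence: pd.DataFrame,
    taxonomy: TaxonomyTable,
    quality: Sequence[GenomeQuality],
    top_n: int = 3,
) -> pd.DataFrame:
    """Genus x module presence over each genus's top-N most complete genomes.

    For every genus, the ``top_n`` genomes by completeness (ties broken by
    lower contamination, then genome id) are selected — all of them when a
    genus has fewer — and a module is present for the genus iff it is
    present in at least one selected genome.  Genomes without a genus
    assignment are skipped.
    """
    if top_n < 1:
        raise ValidationError(f"top_n must be >= 1, got {top_n!r}")
    genome_ids = list(presence.index)
    genus_of = taxonomy.genus_map()
    quality_of = {q.genome_id: q for q in quality}
    missing_tax = [g for g in genome_ids if g not in genus_of]
    missing_q = [g for g in genome_ids if g not in quality_of]
    if missing_tax or missing_q:
        raise MissingRecordError(
            "genomes in presence matrix lack taxonomy and/or quality records",
            missing_ids=list(set(missing_tax) | set(missing_q)),
        )
    by_genus: dict[str, list[str]] = {}
    for g in genome_ids:
        genus = genus_of[g]
        if genus:
            by_genus.setdefault(genus, []).append(g)
    rows = {}
    for genus in sorted(by_genus):
        members = sorted(
            by_genus[genus],
            key=lambda g: (
                -quality_of[g].completeness_pct,
                quality_of[g].contamination_pct,
                g,
            ),
        )
        selected = members[:top_n]
        rows[genus] = presence.loc[selected].any(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "genus"
    return out.astype(bool)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def family_composition(taxonomy: TaxonomyTable) -> pd.DataFrame:
    """Family counts and relative abundance, largest first.

    Columns: family, count, fraction (exact, sums to 1), percent
    (integer, half-up — the rounding used on figure labels).  Genomes with
    no family assignment are grouped under "unassigned".
    """
    if len(taxonomy.df) == 0:
        raise DataError("taxonomy table is empty")
    fam = taxonomy.df["family"].replace("", "unassigned")
    counts = fam.value_counts().sort_values(ascending=False)
    total = int(counts.sum())
    out = pd.DataFrame(
        {
            "family": counts.index,
            "count": counts.to_numpy(),
            "fraction": counts.to_numpy() / total,
        }
    )
    out["percent"] = [_round_half_up(100 * f) for f in out["fraction"]]
    # stable order: by count desc then family name for reproducible reports
    out = out.sort_values(["count", "family"], ascending=[False, True]).reset_index(drop=True)
    return out


def shared_taxa(a: TaxonomyTable, b: TaxonomyTable, rank: str) -> set[str]:
    """Taxon names present (non-empty) in both tables at a rank."""
    return a.taxa_at(rank) & b.taxa_at(rank)


def read_module_definitions(path: str | Path) -> list[ModuleDefinition]:
    """Read module definitions from TSV or JSON.

    TSV columns: module_id, category, step_index, alternatives
    (comma-separated gene families); one row per step.  JSON: a list of
    {module_id, category, steps: [[...], ...]} objects.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        mods = [
            ModuleDefinition(m["module_id"], m.get("category", ""), m["steps"]) for m in raw
        ]
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        needed = {"module_id", "category", "step_index", "alternatives"}
        if not needed.issubset(df.columns):
            raise ValidationError(
                f"{path}: module file needs columns {sorted(needed)}, got {list(df.columns)}"
            )
        mods = []
        for mid, grp in df.groupby("module_id", sort=False):
            grp = grp.sort_values("step_index")
            steps = [
                [alt.strip() for alt in str(alts).split(",") if alt.strip()]
                for alts in grp["alternatives"]
            ]
            category = str(grp["category"].iloc[0])
            mods.append(ModuleDefinition(str(mid), category, steps))
    ids = [m.module_id for m in mods]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate module_id in definition file: {ids}")
    return mods


def write_module_definitions(modules: Sequence[ModuleDefinition], path: str | Path) -> None:
    rows = [
        {
            "module_id": m.module_id,
            "category": m.category,
            "step_index": i,
            "alternatives": ",".join(sorted(step)),
        }
        for m in modules
        for i, step in enumerate(m.steps)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
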