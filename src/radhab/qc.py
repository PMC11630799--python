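"""Genome and contig retention rules.

Three filters applied between assembly and downstream annotation work:

* single-cell amplified genomes (SAGs) are kept only when CheckM-style
  completeness is at least 1% and contamination at most 10%;
* metagenome bins are tiered high (>90% completeness, <5% contamination)
  or medium (>=50% completeness, <10% contamination), anything else fails;
* assembled contigs lose 100 bp from each end and must then exceed
  2000 bp.

Plus the genus-assignment rule for genomes without a marker-gene
taxonomy: inherit the genus of the highest-identity annotated genome at
>= 95% average nucleotide identity (ANI).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .errors import MissingRecordError, ValidationError

__all__ = [
    "GenomeQuality",
    "QualityThresholds",
    "ANIRecord",
    "ANIAssignment",
    "SAG_RETENTION",
    "RejectedGenome",
    "filter_genomes",
    "tier_bins",
    "trim_filter_contigs",
    "trim_filter_fasta",
    "assign_genus_by_ani",
    "read_quality_table",
    "write_quality_table",
    "read_ani_table",
]


@dataclass(frozen=True)
class GenomeQuality:
    """Per-genome completeness / contamination estimate, in percent."""

    genome_id: str
    completeness_pct: float
    contamination_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.completeness_pct <= 100.0):
            raise ValidationError(
                f"{self.genome_id}: completeness_pct must be in [0, 100], "
                f"got {self.completeness_pct!r}"
            )
        if self.contamination_pct < 0:
            raise ValidationError(
                f"{self.genome_id}: contamination_pct must be >= 0, "
                f"got {self.contamination_pct!r}"
            )


@dataclass(frozen=True)
class QualityThresholds:
    """Retention bounds with explicit boundary semantics.

    ``completeness_inclusive`` keeps genomes *at* the floor
    (retain completeness >= min); ``contamination_inclusive`` keeps
    genomes *at* the ceiling (retain contamination <= max).  The SAG
    preset derives both from exclusion wording — "<1% completeness ...
    not considered" and ">10% contamination ... not considered" — whose
    complements are inclusive bounds.
    """

    min_completeness_pct: float
    max_contamination_pct: float
    completeness_inclusive: bool = True
    contamination_inclusive: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_completeness_pct <= 100.0):
            raise ValidationError(
                f"min_completeness_pct must be in [0, 100], got {self.min_completeness_pct!r}"
            )
        if self.max_contamination_pct < 0:
            raise ValidationError(
                f"max_contamination_pct must be >= 0, got {self.max_contamination_pct!r}"
            )

    def completeness_ok(self, value: float) -> bool:
        if self.completeness_inclusive:
            return value >= self.min_completeness_pct
        return value > self.min_completeness_pct

    def contamination_ok(self, value: float) -> bool:
        if self.contamination_inclusive:
            return value <= self.max_contamination_pct
        return value < self.max_contamination_pct


#: Retention preset for single-cell amplified genomes.
SAG_RETENTION = QualityThresholds(min_completeness_pct=1.0, max_contamination_pct=10.0)


@dataclass(frozen=True)
class RejectedGenome:
    record: GenomeQuality
    reasons: tuple[str, ...]  # subset of {"completeness", "contamination"}


def filter_genomes(
    quality: Sequence[GenomeQuality],
    thresholds: QualityThresholds = SAG_RETENTION,
) -> tuple[list[GenomeQuality], list[RejectedGenome]]:
    """Partition genomes into retained and rejected-with-reasons.

    Retained and rejected are disjoint and together cover the input in
    its original order; each rejection records every rule that fired.
    """
    retained: list[GenomeQuality] = []
    rejected: list[RejectedGenome] = []
    for rec in quality:
        reasons = []
        if not thresholds.completeness_ok(rec.completeness_pct):
            reasons.append("completeness")
        if not thresholds.contamination_ok(rec.contamination_pct):
            reasons.append("contamination")
        if reasons:
            rejected.append(RejectedGenome(record=rec, reasons=tuple(reasons)))
        else:
            retained.append(rec)
    return retained, rejected


def tier_bins(quality: Sequence[GenomeQuality]) -> dict[str, str]:
    """Tier metagenome bins: 'high', 'medium' or 'fail'.

    high: completeness > 90 and contamination < 5;
    medium: not high, completeness >= 50 and contamination < 10;
    fail: everything else.  Tiers are mutually exclusive and exhaustive.
    """
    tiers: dict[str, str] = {}
    for rec in quality:
        if rec.completeness_pct > 90 and rec.contamination_pct < 5:
            tiers[rec.genome_id] = "high"
        elif rec.completeness_pct >= 50 and rec.contamination_pct < 10:
            tiers[rec.genome_id] = "medium"
        else:
            tiers[rec.genome_id] = "fail"
    return tiers


def trim_filter_contigs(
    records: Iterable[SeqRecord],
    trim_bp: int = 100,
    min_len: int = 2000,
) -> list[SeqRecord]:
    """Trim ``trim_bp`` from both contig ends, then keep length > ``min_len``.

    Trimming happens before the length test; records whose trimmed length
    is zero or negative are dropped.  IDs, descriptions and input order
    are preserved.
    """
    if trim_bp < 0:
        raise ValidationError(f"trim_bp must be >= 0, got {trim_bp!r}")
    if min_len <= 0:
        raise ValidationError(f"min_len must be > 0, got {min_len!r}")
    kept: list[SeqRecord] = []
    for rec in records:
        if len(rec.seq) <= 2 * trim_bp:
            continue
        trimmed = rec[trim_bp : len(rec.seq) - trim_bp] if trim_bp else rec
        trimmed.id, trimmed.description = rec.id, rec.description
        if len(trimmed.seq) > min_len:
            kept.append(trimmed)
    return kept


def trim_filter_fasta(
    in_path: str | Path,
    out_path: str | Path,
    trim_bp: int = 100,
    min_len: int = 2000,
) -> int:
    """FASTA-in / FASTA-out wrapper around :func:`trim_filter_contigs`.

    Returns the number of contigs written.
    """
    records = list(SeqIO.parse(str(in_path), "fasta"))
    kept = trim_filter_contigs(records, trim_bp=trim_bp, min_len=min_len)
    SeqIO.write(kept, str(out_path), "fasta")
    return len(kept)


@dataclass(frozen=True)
class ANIRecord:
    """Pairwise average nucleotide identity between two genomes, percent."""

    query_genome: str
    reference_genome: str
    ani_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ani_pct <= 100.0):
            raise ValidationError(
                f"{self.query_genome} vs {self.reference_genome}: ani_pct must be "
                f"in [0, 100], got {self.ani_pct!r}"
            )


@dataclass(frozen=True)
class ANIAssignment:
    genome_id: str
    genus: str
    reference_genome: str
    ani_pct: float


def assign_genus_by_ani(
    unassigned: Sequence[str],
    annotated,  # TaxonomyTable; duck-typed to avoid a circular import
    ani: Sequence[ANIRecord],
    cutoff: float = 95.0,
) -> dict[str, ANIAssignment]:
    """Give unassigned genomes the genus of their best annotated ANI partner.

    A genome is assigned the genus of the annotated genome with the
    highest ANI at or above ``cutoff``; equal-ANI ties break by
    lexicographic reference id.  Genomes with no qualifying partner are
    simply absent from the result.  ANI rows referencing genomes that are
    neither unassigned queries nor annotated references raise a keyed error.
    """
    if not (0.0 < cutoff <= 100.0):
        raise ValidationError(f"cutoff must be in (0, 100], got {cutoff!r}")
    genus_of = annotated.genus_map()
    unassigned_set = set(unassigned)
    unknown = [
        gid
        for rec in ani
        for gid in (rec.query_genome, rec.reference_genome)
        if gid not in unassigned_set and gid not in genus_of
    ]
    if unknown:
        raise MissingRecordError(
            "ANI records reference genomes absent from both the unassigned "
            "list and the annotated taxonomy",
            missing_ids=list(set(unknown)),
        )
    assignments: dict[str, ANIAssignment] = {}
    for gid in unassigned:
        candidates = [
            rec
            for rec in ani
            if rec.query_genome == gid
            and rec.reference_genome in genus_of
            and rec.ani_pct >= cutoff
            and genus_of[rec.reference_genome]
        ]
        if not candidates:
            continue
        best = min(candidates, key=lambda r: (-r.ani_pct, r.reference_genome))
        assignments[gid] = ANIAssignment(
            genome_id=gid,
            genus=genus_of[best.reference_genome],
            reference_genome=best.reference_genome,
            ani_pct=best.ani_pct,
        )
    return assignments


def read_quality_table(path: str | Path) -> list[GenomeQuality]:
    """Read a TSV with columns genome_id, completeness_pct, contamination_pct."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"genome_id", "completeness_pct", "contamination_pct"}
    if not needed.issubset(df.columns):
        raise ValidationError(
            f"{path}: quality table needs columns {sorted(needed)}, got {list(df.columns)}"
        )
    return [
        GenomeQuality(str(r.genome_id), float(r.completeness_pct), float(r.contamination_pct))
        for r in df.itertuples()
    ]


def write_quality_table(quality: Sequence[GenomeQuality], path: str | Path) -> None:
    pd.DataFrame(
        {
            "genome_id": [q.genome_id for q in quality],
            "completeness_pct": [q.completeness_pct for q in quality],
            "contamination_pct": [q.contamination_pct for q in quality],
        }
    ).to_csv(path, sep="\t", index=False)


def read_ani_table(path: str | Path) -> list[ANIRecord]:
    """Read a TSV with columns query_genome, reference_genome, ani_pct."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"query_genome", "reference_genome", "ani_pct"}
    if not needed.issubset(df.columns):
        raise ValidationError(
            f"{path}: ANI table needs columns {sorted(needed)}, got {list(df.columns)}"
        )
    return [
        ANIRecord(str(r.query_genome), str(r.reference_genome), float(r.ani_pct))
        for r in df.itertuples()
    ]
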