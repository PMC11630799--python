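"""Seeded synthetic fixtures for every pipeline stage.

Generators emulate the *structure* of the study system's data — a
hypersaline-brine genome collection dominated by a few halophilic
families, per-genome gene-family annotations with planted module
completeness, quality tables straddling the retention thresholds, and
noisy log-linear survival curves with known decimal-reduction doses.
They make no attempt at sequence content or phylogenetic realism.

All generators are pure functions of (spec, seed): a single global seed
fans out to per-stage substreams via a CRC32 hash of the stage name, so
any stage can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationTable, ModuleDefinition, TaxonomyTable
from .errors import ValidationError
from .qc import GenomeQuality
from .survival import SurvivalCurve

__all__ = [
    "SimulationSpec",
    "QualityDistribution",
    "CurveSpec",
    "BRINE_FAMILY_PROPORTIONS",
    "BRINE_TOP_FAMILY_PROPORTIONS",
    "FAMILY_GENUS",
    "substream",
    "largest_remainder",
    "achievable_completeness",
    "simulate_taxonomy",
    "simulate_annotations",
    "simulate_quality",
    "simulate_quality_straddling",
    "simulate_survival_curves",
    "default_modules",
    "fluid_family_tables",
    "SHARED_DOLOMITE_SERVICE_FAMILIES",
]

#: Family-level composition of the 95-genome brine collection (fractions
#: of genomes; the long tail of rare families resolved individually).
BRINE_FAMILY_PROPORTIONS: dict[str, float] = {
    "Halomonadaceae": 0.58,
    "Microbacteriaceae": 0.24,
    "Idiomarinaceae": 0.08,
    "Pseudomonadaceae": 0.03,
    "Rhodospirillaceae": 0.03,
    "Rhizobiaceae": 0.02,
    "Carnobacteriaceae": 0.01,
    "Salinarimonadaceae": 0.01,
}

#: Same collection with only the three dominant families resolved and the
#: rare tail aggregated into one bucket.
BRINE_TOP_FAMILY_PROPORTIONS: dict[str, float] = {
    "Halomonadaceae": 0.58,
    "Microbacteriaceae": 0.24,
    "Idiomarinaceae": 0.08,
    "other_families": 0.10,
}

#: Representative genus per simulated family.
FAMILY_GENUS: dict[str, str] = {
    "Halomonadaceae": "Halomonas",
    "Microbacteriaceae": "Microbacterium",
    "Idiomarinaceae": "Idiomarina",
    "Pseudomonadaceae": "Pseudomonas",
    "Rhodospirillaceae": "Caenispirillum",
    "Rhizobiaceae": "Shinella",
    "Carnobacteriaceae": "Atopococcus",
    "Salinarimonadaceae": "Salinarimonas",
}

_FAMILY_LINEAGE: dict[str, tuple[str, str, str]] = {
    # family -> (phylum, class, order)
    "Halomonadaceae": ("Proteobacteria", "Gammaproteobacteria", "Oceanospirillales"),
    "Microbacteriaceae": ("Actinobacteriota", "Actinomycetia", "Micrococcales"),
    "Idiomarinaceae": ("Proteobacteria", "Gammaproteobacteria", "Alteromonadales"),
    "Pseudomonadaceae": ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales"),
    "Rhodospirillaceae": ("Proteobacteria", "Alphaproteobacteria", "Rhodospirillales"),
    "Rhizobiaceae": ("Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales"),
    "Carnobacteriaceae": ("Firmicutes", "Bacilli", "Lactobacillales"),
    "Salinarimonadaceae": ("Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales"),
}


def substream(seed: int, stage: str) -> np.random.Generator:
    """Independent per-stage RNG derived from the global seed.

    Derivation: seed XOR crc32(stage), masked to 31 bits (documented so
    stages can be regenerated outside the full pipeline).
    """
    return np.random.default_rng((int(seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF)


@dataclass(frozen=True)
class QualityDistribution:
    """Uniform ranges for simulated completeness / contamination draws."""

    completeness_range: tuple[float, float] = (50.0, 99.0)
    contamination_range: tuple[float, float] = (0.0, 5.0)

    def __post_init__(self) -> None:
        lo, hi = self.completeness_range
        if not (0.0 <= lo <= hi <= 100.0):
            raise ValidationError(
                f"completeness_range must satisfy 0 <= lo <= hi <= 100, "
                f"got {self.completeness_range!r}"
            )
        lo, hi = self.contamination_range
        if not (0.0 <= lo <= hi):
            raise ValidationError(
                f"contamination_range must satisfy 0 <= lo <= hi, "
                f"got {self.contamination_range!r}"
            )


@dataclass(frozen=True)
class CurveSpec:
    """Parameters for one simulated survival curve."""

    organism: str
    true_d10_gy: float
    n_points: int = 6
    noise_sd_decades: float = 0.1

    def __post_init__(self) -> None:
        if self.true_d10_gy <= 0:
            raise ValidationError(f"true_d10_gy must be > 0, got {self.true_d10_gy!r}")
        if self.n_points < 3:
            raise ValidationError(f"n_points must be >= 3, got {self.n_points!r}")
        if self.noise_sd_decades < 0:
            raise ValidationError(
                f"noise_sd_decades must be >= 0, got {self.noise_sd_decades!r}"
            )


def _default_curve_specs() -> tuple[CurveSpec, ...]:
    # D10 values consistent with the published 1e-6 thresholds (threshold/6)
    return (
        CurveSpec("E. coli", 1000.0 / 6.0),
        CurveSpec("B. subtilis", 1400.0),
        CurveSpec("D. radiodurans", 2500.0),
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Everything the generators need, with study-scale defaults.

    Defaults emulate the brine genome collection: 95 genomes at the
    family proportions above, quality draws typical of retained
    single-cell genomes, and survival curves whose true D10 values match
    the published inactivation thresholds.
    """

    seed: int
    n_genomes: int = 95
    family_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(BRINE_FAMILY_PROPORTIONS)
    )
    module_completeness_targets: Mapping[tuple[str, str], float] = field(
        default_factory=dict
    )
    quality_distribution: QualityDistribution = field(default_factory=QualityDistribution)
    survival_curve_specs: tuple[CurveSpec, ...] = field(
        default_factory=_default_curve_specs
    )

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValidationError(f"n_genomes must be >= 1, got {self.n_genomes!r}")
        total = sum(self.family_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValidationError(
                f"family_proportions must sum to 1 (got {total!r})"
            )
        for fam, frac in self.family_proportions.items():
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(
                    f"family_proportions[{fam!r}] must be in [0, 1], got {frac!r}"
                )
        for key, frac in self.module_completeness_targets.items():
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(
                    f"module_completeness_targets[{key!r}] must be in [0, 1], got {frac!r}"
                )


def largest_remainder(proportions: Mapping[str, float], n: int) -> dict[str, int]:
    """Apportion ``n`` items to categories by the largest-remainder method.

    Each category gets floor(p*n); leftover units go to the largest
    fractional remainders (ties broken by category name) so counts sum to
    exactly ``n`` without independent-rounding drift.
    """
    if n < 0:
        raise ValidationError(f"n must be >= 0, got {n!r}")
    quotas = {k: p * n for k, p in proportions.items()}
    counts = {k: int(math.floor(q)) for k, q in quotas.items()}
    leftover = n - sum(counts.values())
    by_remainder = sorted(
        proportions, key=lambda k: (-(quotas[k] - counts[k]), k)
    )
    for k in by_remainder[:leftover]:
        counts[k] += 1
    return counts


def _lineage(family: str) -> dict[str, str]:
    phylum, cls, order = _FAMILY_LINEAGE.get(
        family, ("Proteobacteria", f"{family}_class", f"{family}_order")
    )
    genus = FAMILY_GENUS.get(family, f"{family}_genus")
    return {
        "domain": "Bacteria",
        "phylum": phylum,
        "class": cls,
        "order": order,
        "family": family,
        "genus": genus,
        "species": "",
    }


def simulate_taxonomy(spec: SimulationSpec) -> TaxonomyTable:
    """Genome taxonomy with family counts apportioned by largest remainder."""
    counts = largest_remainder(spec.family_proportions, spec.n_genomes)
    families: list[str] = []
    for fam in spec.family_proportions:  # insertion order: deterministic
        families.extend([fam] * counts[fam])
    rng = substream(spec.seed, "taxonomy")
    rng.shuffle(families)
    rows = []
    for i, fam in enumerate(families, start=1):
        row = {"genome_id": f"SAG{i:04d}", **_lineage(fam)}
        rows.append(row)
    return TaxonomyTable(pd.DataFrame(rows))


def achievable_completeness(target: float, n_steps: int) -> float:
    """Nearest step fraction k/n_steps to a target (half rounds up)."""
    k = int(math.floor(target * n_steps + 0.5))
    return k / n_steps


def simulate_annotations(
    spec: SimulationSpec,
    modules: Sequence[ModuleDefinition],
    taxonomy: TaxonomyTable,
) -> AnnotationTable:
    """Plant per-genus module-completeness targets into an annotation table.

    For each genome, every targeted (genus, module) pair gets exactly the
    nearest achievable number of satisfied steps — a random subset of
    steps, each via one randomly chosen alternative gene family.
    Untargeted modules receive no annotations (completeness 0).  A target
    that is not a multiple of 1/n_steps triggers a warning reporting the
    achieved value.
    """
    module_by_id = {m.module_id: m for m in modules}
    for (genus, module_id), _ in spec.module_completeness_targets.items():
        if module_id not in module_by_id:
            raise ValidationError(
                f"module_completeness_targets references unknown module {module_id!r}"
            )
    rng = substream(spec.seed, "annotations")
    genus_of = taxonomy.genus_map()
    rows: list[tuple[str, str, int]] = []
    for genome_id in taxonomy.genomes:
        genus = genus_of[genome_id]
        for module in modules:
            target = spec.module_completeness_targets.get((genus, module.module_id))
            if target is None:
                continue
            achieved = achievable_completeness(target, module.n_steps)
            if abs(achieved - target) > 1e-9:
                warnings.warn(
                    f"target completeness {target} for ({genus!r}, "
                    f"{module.module_id!r}) is not achievable with "
                    f"{module.n_steps} steps; planting {achieved}",
                    stacklevel=2,
                )
            k = round(achieved * module.n_steps)
            chosen_steps = rng.choice(module.n_steps, size=k, replace=False)
            for step_idx in sorted(int(s) for s in chosen_steps):
                alternatives = sorted(module.steps[step_idx])
                fam = alternatives[int(rng.integers(len(alternatives)))]
                rows.append((genome_id, fam, int(rng.integers(1, 4))))
    return AnnotationTable(rows)


def simulate_quality(spec: SimulationSpec, taxonomy: TaxonomyTable) -> list[GenomeQuality]:
    """Uniform completeness/contamination draws for every genome."""
    rng = substream(spec.seed, "quality")
    clo, chi = spec.quality_distribution.completeness_range
    xlo, xhi = spec.quality_distribution.contamination_range
    return [
        GenomeQuality(
            genome_id=gid,
            completeness_pct=round(float(rng.uniform(clo, chi)), 2),
            contamination_pct=round(float(rng.uniform(xlo, xhi)), 2),
        )
        for gid in taxonomy.genomes
    ]


def simulate_quality_straddling(
    n_total: int = 121,
    n_pass: int = 95,
    seed: int = 0,
) -> list[GenomeQuality]:
    """Quality table straddling the retention thresholds.

    Exactly ``n_pass`` genomes satisfy the retention preset
    (completeness >= 1%, contamination <= 10%); the rest fail on
    completeness, contamination, or both, in rotation.  Defaults mirror a
    single-cell sorting run where 95 of 121 amplified cells yield a
    retainable assembly.
    """
    if not (0 <= n_pass <= n_total):
        raise ValidationError(f"need 0 <= n_pass <= n_total, got {n_pass}/{n_total}")
    rng = substream(seed, "quality_straddle")
    records: list[GenomeQuality] = []
    for i in range(n_pass):
        records.append(
            GenomeQuality(
                genome_id=f"CELL{i + 1:04d}",
                completeness_pct=round(float(rng.uniform(1.0, 99.0)), 2),
                contamination_pct=round(float(rng.uniform(0.0, 10.0)), 2),
            )
        )
    fail_modes = ("completeness", "contamination", "both")
    for j in range(n_total - n_pass):
        mode = fail_modes[j % 3]
        comp = (
            round(float(rng.uniform(0.0, 0.99)), 2)
            if mode in ("completeness", "both")
            else round(float(rng.uniform(1.0, 50.0)), 2)
        )
        cont = (
            round(float(rng.uniform(10.01, 40.0)), 2)
            if mode in ("contamination", "both")
            else round(float(rng.uniform(0.0, 10.0)), 2)
        )
        records.append(
            GenomeQuality(
                genome_id=f"CELL{n_pass + j + 1:04d}",
                completeness_pct=comp,
                contamination_pct=cont,
            )
        )
    return records


def simulate_survival_curves(spec: SimulationSpec) -> list[SurvivalCurve]:
    """Noisy log-linear survival curves with known D10.

    Doses are evenly spaced over [0, 6*D10].  The zero-dose point is the
    exact normalised control (0, 1); every positive-dose point gets
    multiplicative lognormal noise, 10**eps with eps ~ Normal(0, sd)
    in decades, clipped at 1 to respect the surviving-fraction bound.
    """
    rng = substream(spec.seed, "survival_curves")
    curves = []
    for cs in spec.survival_curve_specs:
        doses = np.linspace(0.0, 6.0 * cs.true_d10_gy, cs.n_points)
        points: list[tuple[float, float]] = []
        for d in doses:
            if d == 0.0:
                points.append((0.0, 1.0))
                continue
            eps = float(rng.normal(0.0, cs.noise_sd_decades))
            sf = min(10.0 ** (-d / cs.true_d10_gy + eps), 1.0)
            points.append((float(d), sf))
        curves.append(SurvivalCurve(cs.organism, points))
    return curves


#: Families named in the published service-water and deep-aquifer lists
#: (the three families those two fluids share).
SHARED_DOLOMITE_SERVICE_FAMILIES = (
    "Burkholderiaceae",
    "Rhodocyclaceae",
    "Thiobacillaceae",
)


def fluid_family_tables() -> dict[str, TaxonomyTable]:
    """Family-level taxonomy tables for the three mine fluids.

    The brine table carries the eight published brine families; the
    service-water (6 families) and 1200-level dolomite-aquifer (13
    families) tables carry their three published shared families plus
    synthetic placeholder labels for the families the study does not name
    individually — placeholders are distinct between fluids, so the only
    possible overlaps are the published ones.  One genome per family.
    """
    def table(prefix: str, families: Sequence[str]) -> TaxonomyTable:
        rows = [
            {
                "genome_id": f"{prefix}{i:03d}",
                "domain": "Bacteria",
                "phylum": "p__placeholder" if fam.startswith("synthetic") else
                _lineage(fam)["phylum"],
                "class": "",
                "order": "",
                "family": "",
                "genus": "",
                "species": "",
            }
            for i, fam in enumerate(families)
        ]
        df = pd.DataFrame(rows)
        # fill class/order generically, then the family column
        df["class"] = df["phylum"] + "_c"
        df["order"] = df["phylum"] + "_o"
        df["family"] = list(families)
        return TaxonomyTable(df)

    brine = table("BRN", list(BRINE_FAMILY_PROPORTIONS))
    service = table(
        "SVC",
        list(SHARED_DOLOMITE_SERVICE_FAMILIES)
        + [f"synthetic_service_family_{i}" for i in range(1, 4)],
    )
    dolomite = table(
        "DOL",
        list(SHARED_DOLOMITE_SERVICE_FAMILIES)
        + [f"synthetic_dolomite_family_{i}" for i in range(1, 11)],
    )
    return {"brine_101": brine, "dolomite_1200": dolomite, "service_water": service}


def default_modules() -> list[ModuleDefinition]:
    """A compact module catalogue for simulations and examples.

    Step counts vary from 2 to 6, with some multi-alternative steps, so
    threshold and rounding behaviour gets exercised; gene-family ids are
    synthetic KO-style labels.
    """
    def mk(module_id: str, category: str, n_steps: int, alts_on: Sequence[int] = ()) -> ModuleDefinition:
        steps = []
        for i in range(n_steps):
            fams = [f"K{module_id[1:]}{i:02d}"]
            if i in alts_on:
                fams.append(f"K{module_id[1:]}{i:02d}b")
            steps.append(fams)
        return ModuleDefinition(module_id, category, steps)

    return [
        mk("M0001", "glycolysis", 5, alts_on=(0,)),
        mk("M0002", "citrate_cycle_oxidation", 4),
        mk("M0003", "acetate_oxidation", 3, alts_on=(1,)),
        mk("M0004", "ethanol_oxidation", 2),
        mk("M0005", "mixed_acid_fermentation", 4),
        mk("M0006", "denitrification", 4, alts_on=(2,)),
        mk("M0007", "nitrate_ammonification", 3),
        mk("M0008", "nitrogen_fixation", 3),
        mk("M0009", "thiosulfate_oxidation", 4),
        mk("M0010", "sulfide_oxidation", 2),
        mk("M0011", "carbon_fixation_cbb", 6),
        mk("M0012", "ectoine_biosynthesis", 4),
        mk("M0013", "trehalose_biosynthesis", 3),
        mk("M0014", "flagellar_motility", 5),
        mk("M0015", "benzoate_degradation", 5, alts_on=(0, 3)),
    ]
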