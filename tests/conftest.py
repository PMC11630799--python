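import pandas as pd
import pytest

from radhab.annotations import AnnotationTable, ModuleDefinition, TaxonomyTable


@pytest.fixture
def four_step_module() -> ModuleDefinition:
    return ModuleDefinition(
        "M1", "demo", [["K01"], ["K02"], ["K03"], ["K04"]]
    )


@pytest.fixture
def alt_module() -> ModuleDefinition:
    # two steps, the first with alternatives A|B
    return ModuleDefinition("M2", "demo", [["A", "B"], ["C"]])


def make_taxonomy(rows: dict[str, dict[str, str]]) -> TaxonomyTable:
    """Build a TaxonomyTable from {genome_id: {rank: value}} with blanks below."""
    ranks = ("domain", "phylum", "class", "order", "family", "genus", "species")
    records = []
    for gid, assigned in rows.items():
        rec = {"genome_id": gid}
        for r in ranks:
            rec[r] = assigned.get(r, "")
        records.append(rec)
    return TaxonomyTable(pd.DataFrame(records))


def family_table(families: list[str], prefix: str = "G") -> TaxonomyTable:
    """One genome per family, lineage filled down to family only."""
    return make_taxonomy(
        {
            f"{prefix}{i:03d}": {
                "domain": "Bacteria",
                "phylum": "p",
                "class": "c",
                "order": "o",
                "family": fam,
            }
            for i, fam in enumerate(families)
        }
    )


@pytest.fixture
def tiny_annotations() -> AnnotationTable:
    return AnnotationTable(
        [
            ("g1", "K01", 1),
            ("g1", "K02", 2),
            ("g1", "K03", 1),
            ("g2", "B", 1),
            ("g2", "C", 1),
        ]
    )
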