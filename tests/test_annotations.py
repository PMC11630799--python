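"""Annotation-profile unit and property tests."""

import itertools

import pandas as pd
import pytest

from radhab.annotations import (
    AnnotationTable,
    ModuleDefinition,
    TaxonomyTable,
    call_presence,
    completeness_matrix,
    family_composition,
    genus_aggregate,
    module_completeness,
    read_module_definitions,
    shared_taxa,
    write_module_definitions,
)
from radhab.errors import DataError, MissingRecordError, ValidationError
from radhab.qc import GenomeQuality

from conftest import family_table, make_taxonomy


class TestModuleCompleteness:
    def test_three_of_four_steps(self, four_step_module):
        table = AnnotationTable([("g", "K01", 1), ("g", "K02", 1), ("g", "K03", 1)])
        assert module_completeness(table, four_step_module, "g") == pytest.approx(0.75)

    def test_genome_with_no_hits(self, four_step_module):
        table = AnnotationTable([("other", "K01", 1)])
        assert module_completeness(table, four_step_module, "g") == 0.0

    def test_alternative_satisfaction_truth_table(self, alt_module):
        """Brute-force all presence combinations of {A,B,C} on the
        {A|B},{C} module: completeness = (A or B present) + (C present) / 2."""
        for has_a, has_b, has_c in itertools.product([0, 1], repeat=3):
            rows = []
            if has_a:
                rows.append(("g", "A", 1))
            if has_b:
                rows.append(("g", "B", 1))
            if has_c:
                rows.append(("g", "C", 1))
            rows.append(("g", "unrelated", 1))
            table = AnnotationTable(rows)
            expected = ((has_a or has_b) + has_c) / 2
            assert module_completeness(table, alt_module, "g") == pytest.approx(expected)

    def test_zero_count_is_absence(self, four_step_module):
        table = AnnotationTable([("g", "K01", 0), ("g", "K02", 1)])
        assert module_completeness(table, four_step_module, "g") == pytest.approx(0.25)

    def test_duplicate_rows_merged_by_sum(self):
        table = AnnotationTable([("g", "K01", 1), ("g", "K01", 2)])
        assert table.df["count"].tolist() == [3]

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError, match="count"):
            AnnotationTable([("g", "K01", -1)])

    def test_empty_module_rejected(self):
        with pytest.raises(ValidationError, match=">= 1 step"):
            ModuleDefinition("M", "c", [])
        with pytest.raises(ValidationError, match="no alternatives"):
            ModuleDefinition("M", "c", [["A"], []])

    def test_monotone_under_added_annotations(self, four_step_module):
        base_rows = [("g", "K01", 1)]
        base = module_completeness(
            AnnotationTable(base_rows), four_step_module, "g"
        )
        grown = module_completeness(
            AnnotationTable(base_rows + [("g", "K04", 1)]), four_step_module, "g"
        )
        assert grown >= base


class TestPresenceCalls:
    @pytest.mark.parametrize(
        "value,threshold,strict,expected",
        [
            (0.70, 0.70, True, False),  # strict boundary: absent
            (0.75, 0.75, False, True),  # non-strict boundary: present
            (0.71, 0.70, True, True),
            (0.74, 0.75, False, False),
        ],
    )
    def test_boundaries(self, value, threshold, strict, expected):
        matrix = pd.DataFrame({"M": [value]}, index=["g"])
        assert bool(call_presence(matrix, threshold, strict).loc["g", "M"]) is expected

    def test_monotone_in_completeness_and_threshold(self):
        matrix = pd.DataFrame({"M": [0.2, 0.5, 0.8]}, index=list("abc"))
        calls_low = call_presence(matrix, 0.4, strict=True)["M"]
        calls_high = call_presence(matrix, 0.6, strict=True)["M"]
        # higher completeness never flips present->absent down the column
        assert calls_low.tolist() == sorted(calls_low.tolist())
        # raising the threshold never creates a presence
        assert all(h <= l for l, h in zip(calls_low, calls_high))

    def test_invalid_threshold(self):
        matrix = pd.DataFrame({"M": [0.5]}, index=["g"])
        with pytest.raises(ValidationError):
            call_presence(matrix, 0.0, strict=True)
        with pytest.raises(ValidationError):
            call_presence(matrix, 1.5, strict=False)


def _genus_fixture(n_genomes: int, present_in: set[str]):
    """One genus, ``n_genomes`` genomes with descending completeness,
    pathway present only in ``present_in`` genome ids."""
    ids = [f"g{i}" for i in range(1, n_genomes + 1)]
    taxonomy = make_taxonomy(
        {
            gid: {
                "domain": "Bacteria", "phylum": "p", "class": "c",
                "order": "o", "family": "F", "genus": "Halomonas",
            }
            for gid in ids
        }
    )
    quality = [
        GenomeQuality(gid, completeness_pct=100 - 10 * i, contamination_pct=1.0)
        for i, gid in enumerate(ids)
    ]
    presence = pd.DataFrame(
        {"pathway": [gid in present_in for gid in ids]},
        index=pd.Index(ids, name="genome_id"),
    )
    return presence, taxonomy, quality


class TestGenusAggregate:
    def test_pathway_outside_top3_is_absent(self):
        # present only in the 4th-most-complete of five genomes
        presence, taxonomy, quality = _genus_fixture(5, {"g4"})
        out = genus_aggregate(presence, taxonomy, quality, top_n=3)
        assert not out.loc["Halomonas", "pathway"]

    def test_small_genus_considers_all_members(self):
        presence, taxonomy, quality = _genus_fixture(2, {"g2"})
        out = genus_aggregate(presence, taxonomy, quality, top_n=3)
        assert out.loc["Halomonas", "pathway"]

    def test_any_of_semantics_on_top_genome(self):
        presence, taxonomy, quality = _genus_fixture(5, {"g1"})
        out = genus_aggregate(presence, taxonomy, quality, top_n=3)
        assert out.loc["Halomonas", "pathway"]

    def test_equals_bruteforce_when_top_n_covers_genus(self):
        presence, taxonomy, quality = _genus_fixture(5, {"g5"})
        out = genus_aggregate(presence, taxonomy, quality, top_n=5)
        assert bool(out.loc["Halomonas", "pathway"]) == bool(presence["pathway"].any())

    def test_completeness_tie_broken_by_contamination(self):
        ids = ["a", "b"]
        taxonomy = make_taxonomy(
            {
                gid: {
                    "domain": "Bacteria", "phylum": "p", "class": "c",
                    "order": "o", "family": "F", "genus": "G",
                }
                for gid in ids
            }
        )
        quality = [
            GenomeQuality("a", 90.0, contamination_pct=5.0),
            GenomeQuality("b", 90.0, contamination_pct=1.0),
        ]
        presence = pd.DataFrame(
            {"m": [True, False]}, index=pd.Index(ids, name="genome_id")
        )
        # top-1 must pick "b" (lower contamination), where m is absent
        out = genus_aggregate(presence, taxonomy, quality, top_n=1)
        assert not out.loc["G", "m"]

    def test_missing_records_are_keyed_errors(self):
        presence, taxonomy, quality = _genus_fixture(3, {"g1"})
        with pytest.raises(MissingRecordError) as exc:
            genus_aggregate(presence, taxonomy, quality[:-1], top_n=3)
        assert "g3" in exc.value.missing_ids


class TestComposition:
    def test_dominant_family_percent(self):
        families = ["Halomonadaceae"] * 55 + ["Other%d" % i for i in range(40)]
        comp = family_composition(family_table(families))
        top = comp.iloc[0]
        assert top["family"] == "Halomonadaceae"
        assert top["fraction"] == pytest.approx(55 / 95)
        assert top["percent"] == 58

    def test_single_genome(self):
        comp = family_composition(family_table(["F"]))
        assert comp["percent"].tolist() == [100]

    def test_uniform_four_families(self):
        comp = family_composition(family_table(["A", "B", "C", "D"]))
        assert comp["percent"].tolist() == [25, 25, 25, 25]

    def test_fractions_sum_to_one_and_counts_to_total(self):
        families = ["A"] * 7 + ["B"] * 5 + ["C"] * 1
        comp = family_composition(family_table(families))
        assert comp["fraction"].sum() == pytest.approx(1.0, abs=1e-12)
        assert comp["count"].sum() == 13

    def test_unassigned_bucket(self):
        taxonomy = make_taxonomy(
            {
                "a": {"domain": "Bacteria", "phylum": "p", "class": "c",
                      "order": "o", "family": "F"},
                "b": {"domain": "Bacteria", "phylum": "p"},
            }
        )
        comp = family_composition(taxonomy).set_index("family")
        assert comp.loc["unassigned", "count"] == 1

    def test_empty_table_rejected(self):
        empty = TaxonomyTable(
            pd.DataFrame(
                columns=["genome_id", "domain", "phylum", "class", "order",
                         "family", "genus", "species"]
            )
        )
        with pytest.raises(DataError):
            family_composition(empty)


class TestSharedTaxa:
    def test_intersection_and_symmetry(self):
        a = family_table(["F1", "F2", "F3"], prefix="A")
        b = family_table(["F2", "F3", "F4"], prefix="B")
        assert shared_taxa(a, b, "family") == {"F2", "F3"}
        assert shared_taxa(a, b, "family") == shared_taxa(b, a, "family")

    def test_self_intersection_is_own_set(self):
        a = family_table(["F1", "F2"], prefix="A")
        assert shared_taxa(a, a, "family") == {"F1", "F2"}

    def test_disjoint_tables(self):
        a = family_table(["F1"], prefix="A")
        b = family_table(["F2"], prefix="B")
        assert shared_taxa(a, b, "family") == set()

    def test_unknown_rank_rejected(self):
        a = family_table(["F1"], prefix="A")
        with pytest.raises(ValidationError, match="rank"):
            shared_taxa(a, a, "clade")


class TestTaxonomyValidation:
    def test_duplicate_ids_rejected(self):
        df = family_table(["F1", "F2"]).df.copy()
        df["genome_id"] = ["x", "x"]
        with pytest.raises(ValidationError, match="duplicate"):
            TaxonomyTable(df)

    def test_gap_in_ranks_rejected(self):
        with pytest.raises(ValidationError, match="below an"):
            make_taxonomy({"a": {"domain": "Bacteria", "family": "F"}})


class TestModuleIO:
    def test_tsv_roundtrip(self, tmp_path, four_step_module, alt_module):
        path = tmp_path / "modules.tsv"
        write_module_definitions([four_step_module, alt_module], path)
        back = read_module_definitions(path)
        assert [m.module_id for m in back] == ["M1", "M2"]
        assert back[1].steps == alt_module.steps

    def test_json_format(self, tmp_path):
        path = tmp_path / "modules.json"
        path.write_text(
            '[{"module_id": "M", "category": "c", "steps": [["A", "B"], ["C"]]}]'
        )
        mods = read_module_definitions(path)
        assert mods[0].steps[0] == frozenset({"A", "B"})

    def test_duplicate_module_id_rejected(self, tmp_path):
        path = tmp_path / "modules.json"
        path.write_text(
            '[{"module_id": "M", "category": "c", "steps": [["A"]]},'
            ' {"module_id": "M", "category": "c", "steps": [["B"]]}]'
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_module_definitions(path)

    def test_completeness_matrix_shape(self, four_step_module, alt_module):
        table = AnnotationTable([("g1", "K01", 1), ("g2", "C", 1)])
        matrix = completeness_matrix(table, [four_step_module, alt_module])
        assert matrix.shape == (2, 2)
        assert matrix.loc["g1", "M1"] == pytest.approx(0.25)
        assert matrix.loc["g2", "M2"] == pytest.approx(0.5)
        assert ((matrix >= 0) & (matrix <= 1)).all().all()
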