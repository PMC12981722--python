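"""Allele-definition model, TSV dialect and coordinate consistency."""

from __future__ import annotations

from dataclasses import replace

import pytest

from pgxstar.defs import (
    AlleleDefinition,
    DefinitionError,
    DefinitionTable,
    FunctionClass,
    StructuralKind,
    VariantKey,
    builtin_table,
    check_coordinate_consistency,
    load_definition_table,
    write_definition_table,
)

TABLE1_ALLELES = [
    "*1", "*2", "*4", "*5", "*6", "*9", "*10", "*33", "*35", "*41",
    "*59", "*71", "*108",
]
STUDY_SUBALLELES = [
    "*1.069", "*1.070", "*1.071", "*2.038", "*2.039",
    "*4.036", "*4.037", "*4.038", "*41.010", "*186.001",
]
# Printed activity scores for the 13 catalogued non-duplication star alleles
# plus the x2 duplication contributing twice the *1 value.
ACTIVITY = {
    "*1": 1, "*2": 1, "*4": 0, "*5": 0, "*6": 0, "*9": 0.5, "*10": 0.25,
    "*33": 1, "*35": 1, "*41": 0.5, "*59": 0.5, "*71": None, "*108": None,
}


class TestVariantKey:
    def test_annotations_do_not_affect_identity(self):
        a = VariantKey(100, "A", "G", rsid="rs1", grch38_pos=5)
        b = VariantKey(100, "A", "G")
        assert a == b and hash(a) == hash(b)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(gene_pos=0, ref_base="A", alt_base="G"),
            dict(gene_pos=10, ref_base="A", alt_base="A"),
            dict(gene_pos=10, ref_base="N", alt_base="G"),
            dict(gene_pos=10, ref_base="A", alt_base="x"),
        ],
    )
    def test_invalid_variants_rejected(self, kwargs):
        with pytest.raises(DefinitionError):
            VariantKey(**kwargs)

    def test_token_round_trip(self):
        v = VariantKey(5102, "G", "A", rsid="rs377617003", aa_change="R28H")
        assert VariantKey.from_token(v.token) == v
        assert VariantKey.from_token(v.token).rsid == "rs377617003"

    def test_indel_tokens_allowed(self):
        v = VariantKey.from_token("7569:CT>C:rs5030655")
        assert (v.ref_base, v.alt_base) == ("CT", "C")


class TestBuiltinTables:
    def test_cyp2d6_has_all_catalogued_star_alleles(self, cyp2d6):
        names = cyp2d6.allele_names()
        for name in TABLE1_ALLELES:
            assert names.count(name) == 1

    def test_cyp2d6_has_study_suballeles(self, cyp2d6):
        labels = [a.suballele for a in cyp2d6.alleles if a.suballele]
        assert sorted(labels) == sorted(STUDY_SUBALLELES)

    def test_cyp2c19_alleles(self, cyp2c19):
        assert cyp2c19.allele_names() == ("*1", "*2", "*3", "*17")
        assert cyp2c19.allele("*2").function is FunctionClass.NO_FUNCTION
        assert cyp2c19.allele("*17").function is FunctionClass.INCREASED

    def test_activity_scores_match_catalogue(self, cyp2d6):
        for name, score in ACTIVITY.items():
            allele = cyp2d6.allele(name)
            if score is None:
                assert allele.activity_value is None
                assert allele.function.is_indeterminate
            else:
                assert allele.activity_value == pytest.approx(score)

    def test_star71_core_variant(self, cyp2d6):
        core = cyp2d6.allele("*71").core_variants
        assert {v.rsid for v in core} == {"rs118203758"}
        assert cyp2d6.allele("*71").function is FunctionClass.UNCERTAIN

    def test_star2_core_variants(self, cyp2d6):
        assert {v.rsid for v in cyp2d6.allele("*2").core_variants} == {
            "rs16947", "rs1135840",
        }

    def test_deletion_allele_is_variant_free(self, cyp2d6):
        d6_5 = cyp2d6.allele("*5")
        assert d6_5.structural is StructuralKind.DELETION
        assert not d6_5.core_variants

    def test_unsupported_gene_lists_supported(self):
        with pytest.raises(DefinitionError, match="CYP2D6.*CYP2C19"):
            builtin_table("CYP3A5")


class TestLoadAndRoundTrip:
    def test_round_trip_preserves_everything(self, cyp2d6, tmp_path):
        out = tmp_path / "d6.tsv"
        write_definition_table(cyp2d6, out)
        again = load_definition_table(out, "CYP2D6")
        assert again.reference_id == cyp2d6.reference_id
        assert set(again.alleles) == set(cyp2d6.alleles)
        assert again.default_allele == cyp2d6.default_allele

    def test_empty_file_is_a_parse_error(self, tmp_path):
        empty = tmp_path / "empty.tsv"
        empty.write_text("")
        with pytest.raises(DefinitionError):
            load_definition_table(empty, "CYP2D6")

    def test_malformed_row_names_line(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        header = "gene\tallele\tsuballele\tfunction\tactivity_score\tstructural\tgrch38_positions\tvariants"
        bad.write_text(header + "\nCYP2D6\t*1\t.\tnormal\t1\tnone\t.\n")
        with pytest.raises(DefinitionError, match="line 2"):
            load_definition_table(bad, "CYP2D6")

    def test_duplicate_allele_rejected(self, cyp2d6, tmp_path):
        out = tmp_path / "dup.tsv"
        write_definition_table(cyp2d6, out)
        lines = out.read_text().splitlines()
        lines.append(lines[2])  # repeat the first allele row
        out.write_text("\n".join(lines) + "\n")
        with pytest.raises(DefinitionError, match="duplicate"):
            load_definition_table(out, "CYP2D6")

    def test_missing_default_allele_rejected(self, cyp2d6, tmp_path):
        out = tmp_path / "nodefault.tsv"
        write_definition_table(cyp2d6, out)
        lines = [
            l for l in out.read_text().splitlines()
            if not l.startswith("CYP2D6\t*1\t")
        ]
        out.write_text("\n".join(lines) + "\n")
        with pytest.raises(DefinitionError, match="default"):
            load_definition_table(out, "CYP2D6")


def test_default_allele_must_be_variant_free(cyp2d6):
    with pytest.raises(DefinitionError):
        DefinitionTable(
            gene="CYP2D6",
            reference_id=cyp2d6.reference_id,
            alleles=tuple(
                a for a in cyp2d6.alleles
                if a.name != "*1" and a.suballele is None
            ),
            default_allele="*2",
        )


def test_deletion_allele_cannot_define_variants():
    with pytest.raises(DefinitionError):
        AlleleDefinition(
            gene="CYP2D6",
            name="*5",
            suballele=None,
            core_variants=frozenset({VariantKey(10, "A", "G")}),
            suballele_variants=frozenset(),
            function=FunctionClass.NO_FUNCTION,
            activity_value=0.0,
            structural=StructuralKind.DELETION,
        )


def test_indeterminate_function_cannot_carry_activity():
    with pytest.raises(DefinitionError):
        AlleleDefinition(
            gene="CYP2D6",
            name="*71",
            suballele=None,
            core_variants=frozenset({VariantKey(10, "A", "G")}),
            suballele_variants=frozenset(),
            function=FunctionClass.UNCERTAIN,
            activity_value=1.0,
        )


class TestCoordinateConsistency:
    def test_reverse_strand_constant(self, cyp2d6):
        # e.g. the UTR variant at gene position 4674 sits at GRCh38 42131137
        assert check_coordinate_consistency(cyp2d6) == 4674 + 42131137

    def test_constant_covers_exonic_rows(self, cyp2d6):
        constant = check_coordinate_consistency(cyp2d6)
        for gene_pos, g38 in [(5102, 42130709), (6706, 42129105)]:
            assert gene_pos + g38 == constant

    def test_corrupted_coordinate_detected(self, cyp2d6):
        corrupt = []
        for a in cyp2d6.alleles:
            core = {
                replace(v, grch38_pos=v.grch38_pos + 7)
                if v.grch38_pos is not None and v.gene_pos == 4674
                else v
                for v in a.core_variants
            }
            sub = {
                replace(v, grch38_pos=v.grch38_pos + 7)
                if v.grch38_pos is not None and v.gene_pos == 4674
                else v
                for v in a.suballele_variants
            }
            corrupt.append(
                replace(a, core_variants=frozenset(core),
                        suballele_variants=frozenset(sub))
            )
        table = DefinitionTable(
            gene="CYP2D6",
            reference_id=cyp2d6.reference_id,
            alleles=tuple(corrupt),
            default_allele="*1",
        )
        with pytest.raises(DefinitionError, match="inconsistent"):
            check_coordinate_consistency(table)

    def test_requires_two_dual_coordinate_variants(self, cyp2c19):
        with pytest.raises(DefinitionError, match="at least two"):
            check_coordinate_consistency(cyp2c19)
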