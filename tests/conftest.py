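from __future__ import annotations

import pytest

from pgxstar import builtin_table
from pgxstar.calling import HaplotypeObservation
from pgxstar.defs import DefinitionTable


@pytest.fixture(scope="session")
def cyp2d6():
    return builtin_table("CYP2D6")


@pytest.fixture(scope="session")
def cyp2c19():
    return builtin_table("CYP2C19")


@pytest.fixture(scope="session")
def cyp2d6_core_only(cyp2d6):
    """The CYP2D6 table stripped of suballele rows.

    Emulates the allele catalogue before the study's suballeles were
    described: a haplotype carrying one of those extra variants is then a
    novel-suballele candidate instead of a catalogued suballele.
    """
    return DefinitionTable(
        gene=cyp2d6.gene,
        reference_id=cyp2d6.reference_id,
        alleles=tuple(a for a in cyp2d6.alleles if a.suballele is None),
        default_allele=cyp2d6.default_allele,
    )


@pytest.fixture
def hap():
    """Factory for haplotype observations with passing depth."""

    def make(variants, sample_id="s1", hap_index=1, mean_depth=500.0):
        return HaplotypeObservation(
            sample_id=sample_id,
            hap_index=hap_index,
            variants=frozenset(variants),
            mean_depth=mean_depth,
        )

    return make


@pytest.fixture(scope="session")
def rs(cyp2d6):
    """Look up a fixture variant by rsid (CYP2D6)."""
    return cyp2d6.variant_by_rsid
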