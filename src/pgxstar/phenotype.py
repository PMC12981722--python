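"""Diplotype-to-metaboliser-phenotype translation.

CYP2D6 uses the standardised additive activity-score system: each allele
contributes a value (0, 0.25, 0.5, 1, ...), a duplicated allele "xN"
contributes N times its value, and the diplotype score is binned into
poor / intermediate / normal / ultra-rapid.  An allele of uncertain or
unknown function poisons the sum: the phenotype is then "uncertain", never
a numeric class.

CYP2C19 has no activity score; phenotype is a categorical rule table on
the pair of allele function classes, with a "rapid" class for one
increased-function allele (*17) alongside a normal one.

``reassign_function`` supports what-if scenario analysis — e.g. treating
an uncertain-function allele as nonfunctional and re-deriving the cohort's
phenotype distribution — without mutating the baseline table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

from .defs import AlleleDefinition, DefinitionTable, FunctionClass
from .diplotype import Diplotype, parse_allele_label

__all__ = [
    "PhenotypeClass",
    "PhenotypeCall",
    "diplotype_activity_score",
    "cyp2d6_phenotype",
    "cyp2c19_phenotype",
    "call_phenotype",
    "reassign_function",
    "CYP2D6_BINS",
]


class PhenotypeClass(str, Enum):
    ULTRA_RAPID = "ultra_rapid"
    RAPID = "rapid"
    NORMAL = "normal"
    INTERMEDIATE = "intermediate"
    POOR = "poor"
    UNCERTAIN = "uncertain"


#: Activity-score bin edges for CYP2D6 (CPIC standardised system):
#: poor = 0, intermediate = (0, 1.25), normal = [1.25, 2.25], ultra-rapid > 2.25.
CYP2D6_BINS = (0.0, 1.25, 2.25)


@dataclass(frozen=True)
class PhenotypeCall:
    sample_id: str
    gene: str
    phenotype: PhenotypeClass
    activity_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gene == "CYP2D6":
            if (self.activity_score is None) != (
                self.phenotype is PhenotypeClass.UNCERTAIN
            ):
                raise ValueError(
                    "CYP2D6 activity score must be absent exactly for the "
                    "uncertain phenotype"
                )
        elif self.activity_score is not None:
            raise ValueError(f"{self.gene} phenotype calls carry no activity score")


def _resolve(table: DefinitionTable, label: str) -> tuple[AlleleDefinition, int]:
    name, copies = parse_allele_label(label)
    return table.allele(name), copies


def diplotype_activity_score(
    d: Diplotype, table: DefinitionTable
) -> Optional[float]:
    """Additive activity score of a diplotype, or None if indeterminate.

    Each allele contributes ``copies × activity_value`` ("xN" labels are
    stripped to resolve the base allele).  If either allele's function is
    uncertain or unknown the score is undefined and None is returned.
    """
    total = 0.0
    for label in d.labels:
        allele, copies = _resolve(table, label)
        if allele.function.is_indeterminate:
            return None
        if allele.activity_value is None:
            raise ValueError(
                f"allele {allele.name} of {allele.gene} has no activity score"
            )
        total += copies * allele.activity_value
    return total


def cyp2d6_phenotype(score: Optional[float]) -> PhenotypeClass:
    """Bin a CYP2D6 activity score into a metaboliser class."""
    if score is None:
        return PhenotypeClass.UNCERTAIN
    if score < 0:
        raise ValueError(f"negative activity score {score}")
    poor_max, normal_min, normal_max = CYP2D6_BINS
    if score == poor_max:
        return PhenotypeClass.POOR
    if score < normal_min:
        return PhenotypeClass.INTERMEDIATE
    if score <= normal_max:
        return PhenotypeClass.NORMAL
    return PhenotypeClass.ULTRA_RAPID


_CYP2C19_RULES = {
    frozenset([FunctionClass.NO_FUNCTION]): PhenotypeClass.POOR,
    frozenset(
        [FunctionClass.NO_FUNCTION, FunctionClass.NORMAL]
    ): PhenotypeClass.INTERMEDIATE,
    frozenset(
        [FunctionClass.NO_FUNCTION, FunctionClass.INCREASED]
    ): PhenotypeClass.INTERMEDIATE,
    frozenset([FunctionClass.NORMAL]): PhenotypeClass.NORMAL,
    frozenset(
        [FunctionClass.NORMAL, FunctionClass.INCREASED]
    ): PhenotypeClass.RAPID,
    frozenset([FunctionClass.INCREASED]): PhenotypeClass.ULTRA_RAPID,
}


def cyp2c19_phenotype(d: Diplotype, table: DefinitionTable) -> PhenotypeClass:
    """Categorical CYP2C19 metaboliser class from the pair of function classes."""
    functions = frozenset(_resolve(table, label)[0].function for label in d.labels)
    try:
        return _CYP2C19_RULES[functions]
    except KeyError:
        raise ValueError(
            f"no CYP2C19 phenotype rule for function pair "
            f"{sorted(f.value for f in functions)} ({d.display})"
        ) from None


def call_phenotype(d: Diplotype, table: DefinitionTable) -> PhenotypeCall:
    """Dispatch on the table's gene and return a full phenotype call."""
    if table.gene == "CYP2D6":
        score = diplotype_activity_score(d, table)
        return PhenotypeCall(
            sample_id=d.sample_id,
            gene=table.gene,
            phenotype=cyp2d6_phenotype(score),
            activity_score=score,
        )
    if table.gene == "CYP2C19":
        return PhenotypeCall(
            sample_id=d.sample_id,
            gene=table.gene,
            phenotype=cyp2c19_phenotype(d, table),
        )
    raise ValueError(f"no phenotype system for gene {table.gene}")


def reassign_function(
    table: DefinitionTable,
    allele: str,
    new_function: FunctionClass,
    new_activity: Optional[float] = None,
) -> DefinitionTable:
    """Return a copy of ``table`` with one allele's function reassigned.

    All rows of the allele (the star allele and its suballeles) are updated;
    the input table is untouched.  Supplying a numeric activity for an
    uncertain/unknown function (or vice versa for CYP2D6 scoring) is
    rejected by the definition-model validators.
    """
    if not any(a.name == allele for a in table.alleles):
        raise KeyError(f"no allele {allele} in {table.gene} table")
    updated = tuple(
        replace(a, function=new_function, activity_value=new_activity)
        if a.name == allele
        else a
        for a in table.alleles
    )
    return replace(table, alleles=updated)
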