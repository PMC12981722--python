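"""Assigning star alleles to phased haplotypes.

Each phased haplotype is a set of small variants on the gene reference.
The caller assigns the star allele whose core-variant set is contained in
the haplotype and is largest — the most specific catalogued explanation —
then the best-matching suballele, and flags whatever variants remain as
candidate novel suballele-defining variants.  Matching is exact on
(gene_pos, ref, alt) tokens: amplicon consensus variants are assumed
pre-normalised upstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .defs import (
    AlleleDefinition,
    DefinitionTable,
    StructuralKind,
    VariantKey,
    star_number,
    suballele_number,
)

__all__ = [
    "HaplotypeObservation",
    "StarCall",
    "AmbiguousCallError",
    "match_haplotype",
    "qc_filter",
    "collect_novel_candidates",
    "DEFAULT_DEPTH_THRESHOLD",
]

#: Minimum mean amplicon read depth; samples must exceed it strictly.
DEFAULT_DEPTH_THRESHOLD = 100.0


class AmbiguousCallError(ValueError):
    """Two or more alleles explain a haplotype equally well after all tie-breaks."""


@dataclass(frozen=True)
class HaplotypeObservation:
    """One phased haplotype of one sample."""

    sample_id: str
    hap_index: int
    variants: frozenset[VariantKey]
    mean_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.hap_index not in (1, 2):
            raise ValueError(f"hap_index must be 1 or 2, got {self.hap_index}")
        if self.mean_depth < 0:
            raise ValueError("mean_depth cannot be negative")
        object.__setattr__(self, "variants", frozenset(self.variants))


@dataclass(frozen=True)
class StarCall:
    """Result of matching one haplotype against a definition table."""

    allele: str
    suballele: Optional[str]
    matched_core: frozenset[VariantKey]
    unexplained: frozenset[VariantKey]
    sample_id: str = ""
    hap_index: int = 1

    @property
    def is_novel_suballele(self) -> bool:
        return bool(self.unexplained)

    @property
    def label(self) -> str:
        return self.suballele if self.suballele is not None else self.allele


def _best_suballele(
    allele: AlleleDefinition,
    table: DefinitionTable,
    remaining: frozenset[VariantKey],
) -> tuple[Optional[AlleleDefinition], frozenset[VariantKey]]:
    """Largest non-empty suballele variant set contained in ``remaining``.

    Ties on size resolve to the lowest numeric suballele suffix.
    """
    best: Optional[AlleleDefinition] = None
    for sub in table.suballeles_of(allele.name):
        sv = sub.suballele_variants
        if sv and sv <= remaining:
            if best is None or (
                len(sv),
                -suballele_number(sub.suballele),
            ) > (
                len(best.suballele_variants),
                -suballele_number(best.suballele),
            ):
                best = sub
    if best is None:
        return None, remaining
    return best, remaining - best.suballele_variants


def match_haplotype(
    hap: HaplotypeObservation, table: DefinitionTable
) -> StarCall:
    """Assign a star allele (and suballele, if any) to a phased haplotype.

    The winning allele maximises the size of its core-variant set among
    alleles whose core is fully contained in the haplotype; ties are broken
    by fewer unexplained variants, then by lowest star-allele number.  A
    residual tie raises :class:`AmbiguousCallError` rather than guessing.
    A haplotype matching no core set at all is the table's default allele.
    Variants explained by neither core nor suballele sets are returned in
    ``unexplained`` and mark the call as a novel-suballele candidate.
    """
    variants = hap.variants
    candidates: list[
        tuple[tuple[int, int, int], AlleleDefinition,
              Optional[AlleleDefinition], frozenset[VariantKey]]
    ] = []
    for allele in table.star_alleles():
        if allele.structural is not StructuralKind.NONE:
            continue  # structural alleles are called from CNV evidence, not variants
        if not allele.core_variants <= variants:
            continue
        sub, unexplained = _best_suballele(
            allele, table, variants - allele.core_variants
        )
        score = (
            len(allele.core_variants),
            -len(unexplained),
            -star_number(allele.name),
        )
        candidates.append((score, allele, sub, unexplained))

    if not candidates:  # cannot happen for a valid table: default core is empty
        raise AmbiguousCallError(f"no allele matches haplotype of {hap.sample_id}")
    best_score = max(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] == best_score]
    if len(tied) > 1:  # unreachable while star numbers are unique per table
        raise AmbiguousCallError(
            "ambiguous call: " + ", ".join(sorted(c[1].name for c in tied))
        )
    _, allele, sub, unexplained = tied[0]
    return StarCall(
        allele=allele.name,
        suballele=None if sub is None else sub.suballele,
        matched_core=allele.core_variants,
        unexplained=unexplained,
        sample_id=hap.sample_id,
        hap_index=hap.hap_index,
    )


def qc_filter(
    depth_by_sample: Mapping[str, float],
    threshold: float = DEFAULT_DEPTH_THRESHOLD,
) -> tuple[list[str], list[str]]:
    """Partition samples by mean amplicon depth, strictly above ``threshold``.

    Returns ``(passed, failed)`` lists, together exhaustive and disjoint.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    passed, failed = [], []
    for sample, depth in depth_by_sample.items():
        if depth < 0:
            raise ValueError(f"negative depth for sample {sample}")
        (passed if depth > threshold else failed).append(sample)
    return passed, failed


def collect_novel_candidates(calls: Iterable[StarCall]) -> pd.DataFrame:
    """Tabulate unexplained variants across a cohort's star calls.

    One row per distinct (variant, host star allele) pair with the number of
    haplotypes observed carrying it — the shape of a novel-suballele report.
    """
    counter: Counter[tuple[VariantKey, str]] = Counter()
    for call in calls:
        for v in call.unexplained:
            counter[(v, call.allele)] += 1
    rows = [
        {
            "gene_pos": v.gene_pos,
            "ref": v.ref_base,
            "alt": v.alt_base,
            "rsid": v.rsid,
            "host_allele": allele,
            "n_observed": n,
        }
        for (v, allele), n in counter.items()
    ]
    df = pd.DataFrame(
        rows, columns=["gene_pos", "ref", "alt", "rsid", "host_allele", "n_observed"]
    )
    return df.sort_values(["gene_pos", "host_allele"], ignore_index=True)
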