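"""Cohort-level allele/phenotype frequency tables and reference comparison.

Allele frequencies are denominated per haplotype (2 per individual; a
duplicated allele label such as "*1x2" is one haplotype), phenotype
frequencies per individual.  Study-versus-reference comparison is a
Pearson chi-square on the 2×2 table of allele counts, with the
significance-star convention * p<0.05, ** p<0.01, *** p<0.001.

Reference population frequencies (ClinPGx aggregate values for the
Oceanian and European biogeographic groups) ship as a packaged fixture,
as do the study cohort's published haplotype and phenotype counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .defs import DefinitionError, star_number
from .diplotype import Diplotype, parse_allele_label
from .phenotype import PhenotypeCall, PhenotypeClass

__all__ = [
    "CohortSummary",
    "FrequencyComparison",
    "summarise_cohort",
    "compare_to_reference",
    "reference_fixture",
    "study_allele_counts",
    "study_phenotype_counts",
    "diplotypes_from_counts",
    "phenotype_calls_from_counts",
    "stars_for_p",
    "allele_sort_key",
    "POPULATIONS",
]

POPULATIONS = ("oceanian", "european")


def stars_for_p(p: float) -> str:
    """Significance stars: ``***`` p<0.001, ``**`` p<0.01, ``*`` p<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def allele_sort_key(label: str) -> tuple[int, int]:
    name, copies = parse_allele_label(label)
    return star_number(name), copies  # plain allele before its duplication


@dataclass(frozen=True)
class CohortSummary:
    gene: str
    n_individuals: int
    n_haplotypes: int
    allele_counts: dict[str, int] = field(default_factory=dict)
    phenotype_counts: dict[PhenotypeClass, int] = field(default_factory=dict)

    @property
    def allele_freqs(self) -> dict[str, float]:
        return {a: c / self.n_haplotypes for a, c in self.allele_counts.items()}

    @property
    def phenotype_freqs(self) -> dict[PhenotypeClass, float]:
        return {p: c / self.n_individuals for p, c in self.phenotype_counts.items()}


@dataclass(frozen=True)
class FrequencyComparison:
    allele: str
    study_count: int
    study_n: int
    ref_freq: Optional[float]
    ref_n_individuals: int
    chi2: Optional[float]
    p_value: Optional[float]
    stars: str

    @property
    def skipped(self) -> bool:
        return self.ref_freq is None


def summarise_cohort(
    diplotypes: Optional[Sequence[Diplotype]] = None,
    phenotypes: Optional[Sequence[PhenotypeCall]] = None,
    gene: str = "",
) -> CohortSummary:
    """Count alleles per haplotype and phenotype classes per individual.

    Either collection may be omitted; when both are given they must cover
    the same samples.  Zero-count alleles are simply absent (frequencies
    are kept at full precision; rounding is presentation-time only).
    """
    if diplotypes is None and phenotypes is None:
        raise ValueError("need diplotypes and/or phenotypes to summarise")
    if diplotypes is not None and phenotypes is not None:
        d_ids = {d.sample_id for d in diplotypes}
        p_ids = {p.sample_id for p in phenotypes}
        if d_ids != p_ids:
            raise ValueError(
                f"diplotype and phenotype sample sets differ "
                f"({len(d_ids ^ p_ids)} mismatching samples)"
            )
    allele_counts: dict[str, int] = {}
    if diplotypes is not None:
        n_individuals = len(diplotypes)
        for d in diplotypes:
            for label in d.labels:
                allele_counts[label] = allele_counts.get(label, 0) + 1
        allele_counts = dict(
            sorted(allele_counts.items(), key=lambda kv: allele_sort_key(kv[0]))
        )
    else:
        n_individuals = len(phenotypes)
    phenotype_counts: dict[PhenotypeClass, int] = {}
    if phenotypes is not None:
        if not gene and phenotypes:
            gene = phenotypes[0].gene
        for call in phenotypes:
            phenotype_counts[call.phenotype] = (
                phenotype_counts.get(call.phenotype, 0) + 1
            )
    if not gene and diplotypes is not None:
        gene = ""
    return CohortSummary(
        gene=gene,
        n_individuals=n_individuals,
        n_haplotypes=2 * n_individuals,
        allele_counts=allele_counts,
        phenotype_counts=phenotype_counts,
    )


def compare_to_reference(
    allele: str,
    study_count: int,
    study_n: int,
    ref_freq: Optional[float],
    ref_n_individuals: int,
    *,
    ref_n_is_individuals: bool = True,
    yates: bool = False,
) -> FrequencyComparison:
    """Chi-square comparison of a study allele count against a reference frequency.

    The 2×2 table is ``[[study_count, study_n - study_count],
    [ref_count, ref_total - ref_count]]`` where ``ref_total`` is
    ``2 × ref_n_individuals`` (reference n taken as individuals; pass
    ``ref_n_is_individuals=False`` if the reference n already counts
    haplotypes) and ``ref_count = round(ref_freq × ref_total)``.  Pearson
    chi-square with 1 df; Yates continuity correction off by default.
    A missing reference frequency ("n.d.") yields a skipped comparison.
    """
    if not 0 <= study_count <= study_n:
        raise ValueError(
            f"{allele}: study count {study_count} outside [0, {study_n}]"
        )
    if ref_freq is None:
        return FrequencyComparison(
            allele, study_count, study_n, None, ref_n_individuals, None, None, ""
        )
    if not 0.0 <= ref_freq <= 1.0:
        raise ValueError(f"{allele}: reference frequency {ref_freq} outside [0, 1]")
    if ref_n_individuals <= 0:
        raise ValueError(f"{allele}: non-positive reference n")
    ref_total = (2 if ref_n_is_individuals else 1) * ref_n_individuals
    ref_count = round(ref_freq * ref_total)
    table = [
        [study_count, study_n - study_count],
        [ref_count, ref_total - ref_count],
    ]
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return FrequencyComparison(
        allele=allele,
        study_count=study_count,
        study_n=study_n,
        ref_freq=ref_freq,
        ref_n_individuals=ref_n_individuals,
        chi2=float(chi2),
        p_value=float(p),
        stars=stars_for_p(float(p)),
    )


# ---------------------------------------------------------------------------
# Packaged study/reference fixtures
# ---------------------------------------------------------------------------


def _read_fixture(name: str) -> pd.DataFrame:
    data = resources.files("pgxstar.data") / name
    with resources.as_file(data) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def reference_fixture(gene: str, population: str) -> dict[str, tuple[Optional[float], int]]:
    """Reference allele frequencies: allele -> (freq or None for "n.d.", n individuals)."""
    if population not in POPULATIONS:
        raise DefinitionError(
            f"unsupported population {population!r}; "
            f"supported: {', '.join(POPULATIONS)}"
        )
    df = _read_fixture("reference_freqs.tsv")
    df = df[(df["gene"] == gene) & (df["population"] == population)]
    if df.empty:
        raise DefinitionError(f"no reference frequencies for gene {gene!r}")
    return {
        row["allele"]: (
            None if row["freq"] == "n.d." else float(row["freq"]),
            int(row["n_individuals"]),
        )
        for _, row in df.iterrows()
    }


def study_allele_counts(gene: str) -> dict[str, int]:
    """Published per-allele haplotype counts of the study cohort."""
    df = _read_fixture("study_counts.tsv")
    df = df[df["gene"] == gene]
    if df.empty:
        raise DefinitionError(f"no study counts for gene {gene!r}")
    return {row["allele"]: int(row["haplotype_count"]) for _, row in df.iterrows()}


def study_phenotype_counts(gene: str) -> dict[PhenotypeClass, int]:
    """Published per-class inferred-phenotype counts of the study cohort."""
    df = _read_fixture("study_phenotype_counts.tsv")
    df = df[df["gene"] == gene]
    if df.empty:
        raise DefinitionError(f"no study phenotype counts for gene {gene!r}")
    return {
        PhenotypeClass(row["phenotype"]): int(row["count"])
        for _, row in df.iterrows()
    }


def diplotypes_from_counts(
    counts: Mapping[str, int], sample_prefix: str = "S"
) -> list[Diplotype]:
    """Pair a haplotype-count table into concrete diplotypes.

    Expands each allele label to its count, then pairs consecutive labels;
    the total must be even.  Useful for reconstructing a cohort whose
    published summary is the only available data.
    """
    labels = [a for a, n in counts.items() for _ in range(n)]
    if len(labels) % 2:
        raise ValueError(f"odd number of haplotypes ({len(labels)}) cannot pair")
    return [
        Diplotype(f"{sample_prefix}{i + 1:04d}", labels[2 * i], labels[2 * i + 1])
        for i in range(len(labels) // 2)
    ]


def phenotype_calls_from_counts(
    counts: Mapping[PhenotypeClass, int], gene: str, sample_prefix: str = "S"
) -> list[PhenotypeCall]:
    """Expand a phenotype-count table into per-sample calls (for summarising)."""
    calls: list[PhenotypeCall] = []
    i = 0
    for cls, n in counts.items():
        for _ in range(n):
            i += 1
            score: Optional[float] = None
            if gene == "CYP2D6" and cls is not PhenotypeClass.UNCERTAIN:
                score = {
                    PhenotypeClass.POOR: 0.0,
                    PhenotypeClass.INTERMEDIATE: 1.0,
                    PhenotypeClass.NORMAL: 2.0,
                    PhenotypeClass.ULTRA_RAPID: 3.0,
                }[cls]
            calls.append(
                PhenotypeCall(
                    sample_id=f"{sample_prefix}{i:04d}",
                    gene=gene,
                    phenotype=cls,
                    activity_score=score,
                )
            )
    return calls
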