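"""Synthetic diploid pharmacogene cohorts with a ground-truth ledger.

The study this package models could not deposit raw sequence data (the
participants are indigenous and the data are held under data-sovereignty
arrangements), so every downstream test runs on synthetic cohorts drawn
from published star-allele frequencies.  Individuals draw two alleles
i.i.d. from the frequency vector (Hardy–Weinberg equilibrium, random
mating, genes independent); structural pseudo-alleles ("*5" deletions,
"*1x2" duplications) become per-sample CNV evidence; each non-deleted
haplotype's variant set is the chosen allele's core-variant set from the
definition table.  Optionally, novel variants are injected per haplotype
at reserved gene positions that no catalogued allele uses, so expected
downstream behaviour is unambiguous.  Everything emitted is recorded in a
ledger keyed by sample, making parameter-recovery tests exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .calling import HaplotypeObservation
from .defs import DefinitionTable, StructuralKind, VariantKey, builtin_table
from .diplotype import StructuralStatus, parse_allele_label
from . import io as pgx_io
from .cohort import study_allele_counts

__all__ = [
    "SimulationConfig",
    "GroundTruthLedger",
    "SimulatedCohort",
    "simulate_cohort",
    "study_frequency_vector",
    "write_cohort",
]

#: Offset above the largest catalogued variant position where the novel-variant
#: pool starts; injected variants can never collide with allele definitions.
_NOVEL_POOL_OFFSET = 500
_NOVEL_POOL_SIZE = 400


def study_frequency_vector(gene: str) -> dict[str, float]:
    """Published cohort allele frequencies as exact count ratios.

    The printed 3-decimal frequencies do not sum to exactly 1 (rounding),
    so the simulation default uses haplotype counts over their total.
    """
    counts = study_allele_counts(gene)
    total = sum(counts.values())
    return {a: c / total for a, c in counts.items()}


@dataclass(frozen=True)
class SimulationConfig:
    gene: str
    allele_freqs: dict[str, float]
    n_individuals: int
    seed: int
    novel_injection_rate: float = 0.0
    depth_mean: float = 1000.0
    depth_sd: float = 200.0

    def __post_init__(self) -> None:
        total = sum(self.allele_freqs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"allele frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.allele_freqs.values()):
            raise ValueError("negative allele frequency")
        if not 0.0 <= self.novel_injection_rate <= 1.0:
            raise ValueError("novel_injection_rate must be in [0, 1]")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.depth_mean < 0 or self.depth_sd < 0:
            raise ValueError("depth parameters must be non-negative")


@dataclass
class SampleTruth:
    sample_id: str
    alleles: tuple[str, str]  # labels as drawn, incl. pseudo-alleles
    injected: dict[int, list[str]]  # hap index -> injected variant tokens
    depth: float
    structural: list[StructuralStatus]


@dataclass
class GroundTruthLedger:
    """Per-sample record of everything the generator decided."""

    config: SimulationConfig
    samples: dict[str, SampleTruth] = field(default_factory=dict)

    def injected_variant_counts(self) -> dict[str, int]:
        """Token -> number of haplotypes it was injected into."""
        counts: dict[str, int] = {}
        for truth in self.samples.values():
            for tokens in truth.injected.values():
                for t in tokens:
                    counts[t] = counts.get(t, 0) + 1
        return counts

    def n_injections(self) -> int:
        return sum(self.injected_variant_counts().values())

    def true_allele_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for truth in self.samples.values():
            for label in truth.alleles:
                counts[label] = counts.get(label, 0) + 1
        return counts

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene": self.config.gene,
            "n_individuals": self.config.n_individuals,
            "seed": self.config.seed,
            "novel_injection_rate": self.config.novel_injection_rate,
            "samples": {
                s: {
                    "alleles": list(t.alleles),
                    "injected": {str(k): v for k, v in t.injected.items()},
                    "depth": t.depth,
                    "structural": [
                        {
                            "kind": e.kind.value,
                            "carrier_hap": e.carrier_hap,
                            "multiplicity": e.multiplicity,
                        }
                        for e in t.structural
                    ],
                }
                for s, t in self.samples.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


@dataclass
class SimulatedCohort:
    observations: list[HaplotypeObservation]
    structural: dict[str, list[StructuralStatus]]
    depths: dict[str, float]
    ledger: GroundTruthLedger
    table: DefinitionTable

    @property
    def deleted_haps(self) -> dict[str, list[int]]:
        return {
            s: [e.carrier_hap for e in evts if e.kind is StructuralKind.DELETION]
            for s, evts in self.structural.items()
        }


def _novel_pool(table: DefinitionTable) -> list[VariantKey]:
    start = max(
        (v.gene_pos for v in table.all_variant_keys()), default=1000
    ) + _NOVEL_POOL_OFFSET
    return [
        VariantKey(gene_pos=start + i, ref_base="A", alt_base="G")
        for i in range(_NOVEL_POOL_SIZE)
    ]


def simulate_cohort(
    config: SimulationConfig, table: Optional[DefinitionTable] = None
) -> SimulatedCohort:
    """Draw a diploid cohort under Hardy–Weinberg from ``config``.

    Every named allele in the frequency vector (after stripping a
    duplication suffix) must exist in the definition table; a violation is
    reported before any sampling.  Fully reproducible: the same config and
    seed give byte-identical emitted files.
    """
    table = table if table is not None else builtin_table(config.gene)
    labels = list(config.allele_freqs)
    for label in labels:
        name, _copies = parse_allele_label(label)
        table.allele(name)  # raises KeyError if absent
    freqs = np.array([config.allele_freqs[a] for a in labels], dtype=float)
    freqs = freqs / freqs.sum()  # guard residual float error; validated ~1 already

    rng = np.random.default_rng(config.seed)
    draws = rng.choice(len(labels), size=(config.n_individuals, 2), p=freqs)
    depths = np.clip(
        rng.normal(config.depth_mean, config.depth_sd, config.n_individuals),
        0.0, None,
    )
    pool = _novel_pool(table)

    observations: list[HaplotypeObservation] = []
    structural: dict[str, list[StructuralStatus]] = {}
    depth_map: dict[str, float] = {}
    ledger = GroundTruthLedger(config=config)
    width = len(str(config.n_individuals))
    for i in range(config.n_individuals):
        sample = f"SIM{i + 1:0{width}d}"
        depth_map[sample] = float(depths[i])
        events: list[StructuralStatus] = []
        injected: dict[int, list[str]] = {}
        drawn: list[str] = []
        for hap in (1, 2):
            label = labels[draws[i, hap - 1]]
            drawn.append(label)
            name, copies = parse_allele_label(label)
            allele = table.allele(name)
            if allele.structural is StructuralKind.DELETION:
                events.append(
                    StructuralStatus(kind=StructuralKind.DELETION, carrier_hap=hap)
                )
                variants: frozenset[VariantKey] = frozenset()
            else:
                if copies >= 2:
                    events.append(
                        StructuralStatus(
                            kind=StructuralKind.DUPLICATION,
                            carrier_hap=hap,
                            multiplicity=copies,
                        )
                    )
                variants = allele.core_variants
                if (
                    config.novel_injection_rate > 0
                    and rng.random() < config.novel_injection_rate
                ):
                    novel = pool[int(rng.integers(len(pool)))]
                    variants = variants | {novel}
                    injected[hap] = [novel.token]
            observations.append(
                HaplotypeObservation(
                    sample_id=sample,
                    hap_index=hap,
                    variants=variants,
                    mean_depth=depth_map[sample],
                )
            )
        if events:
            structural[sample] = events
        ledger.samples[sample] = SampleTruth(
            sample_id=sample,
            alleles=(drawn[0], drawn[1]),
            injected=injected,
            depth=depth_map[sample],
            structural=events,
        )
    return SimulatedCohort(
        observations=observations,
        structural=structural,
        depths=depth_map,
        ledger=ledger,
        table=table,
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Emit the cohort as phased VCF + structural/depth sidecars + ledger JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene = cohort.table.gene.lower()
    paths = {
        "vcf": outdir / f"{gene}.phased.vcf",
        "structural": outdir / f"{gene}.structural.tsv",
        "depth": outdir / f"{gene}.depth.tsv",
        "ledger": outdir / f"{gene}.ledger.json",
    }
    pgx_io.write_phased_vcf(
        cohort.observations,
        paths["vcf"],
        gene=cohort.table.gene,
        reference_id=cohort.table.reference_id,
        deleted_haps=cohort.deleted_haps,
    )
    pgx_io.write_structural_tsv(cohort.structural, paths["structural"])
    pgx_io.write_depth_tsv(cohort.depths, paths["depth"])
    cohort.ledger.to_json(paths["ledger"])
    return paths
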