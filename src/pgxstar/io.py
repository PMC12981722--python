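"""Readers and writers for the package's on-disk interchange formats.

Haplotypes travel either as a minimal phased VCF (one pseudo-contig named
after the gene reference sequence, 1-based gene coordinates, phased GT
with "|") or as a plain haplotype TSV of variant tokens.  Structural
(CNV) evidence, per-sample depth summaries and ground-truth ledgers are
sidecar TSV/JSON files — a deleted haplotype emits no variant records, so
its existence is conveyed only by the structural sidecar.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pysam

from .calling import HaplotypeObservation, StarCall
from .defs import StructuralKind, VariantKey
from .diplotype import StructuralStatus

__all__ = [
    "write_phased_vcf",
    "read_phased_vcf",
    "write_haplotype_tsv",
    "read_haplotype_tsv",
    "write_structural_tsv",
    "read_structural_tsv",
    "write_depth_tsv",
    "read_depth_tsv",
    "write_calls_tsv",
]

_CONTIG_LENGTH = 100_000  # generous pseudo-contig length for amplicon coordinates


def _contig_name(gene: str, reference_id: str) -> str:
    return reference_id or gene


def write_phased_vcf(
    observations: Sequence[HaplotypeObservation],
    path: str | Path,
    gene: str,
    reference_id: str = "",
    deleted_haps: Optional[Mapping[str, Sequence[int]]] = None,
) -> None:
    """Write haplotype observations as a minimal phased VCF.

    ``deleted_haps`` maps sample -> haplotype indices whose gene copy is
    deleted; those haplotypes are emitted as missing ("." ) genotype calls.
    An empty cohort still produces a valid header-only VCF.
    """
    deleted_haps = deleted_haps or {}
    by_sample: dict[str, dict[int, frozenset[VariantKey]]] = defaultdict(dict)
    for obs in observations:
        by_sample[obs.sample_id][obs.hap_index] = obs.variants
    samples = sorted(by_sample)
    all_variants = sorted(
        {v for obs in observations for v in obs.variants},
        key=lambda v: (v.gene_pos, v.ref_base, v.alt_base),
    )
    contig = _contig_name(gene, reference_id)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={_CONTIG_LENGTH}>",
        f"##pgxstar_gene={gene}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        + ("\tFORMAT\t" + "\t".join(samples) if samples else ""),
    ]
    for v in all_variants:
        gts = []
        for s in samples:
            alleles = []
            for hap in (1, 2):
                if hap in deleted_haps.get(s, ()):
                    alleles.append(".")
                else:
                    alleles.append("1" if v in by_sample[s].get(hap, ()) else "0")
            gts.append("|".join(alleles))
        lines.append(
            "\t".join(
                [contig, str(v.gene_pos), v.rsid or ".", v.ref_base, v.alt_base,
                 ".", "PASS", ".", "GT"] + gts
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_phased_vcf(
    path: str | Path,
    depth_by_sample: Optional[Mapping[str, float]] = None,
) -> list[HaplotypeObservation]:
    """Read a phased VCF back into per-haplotype observations.

    Every sample yields two observations (hap 1 and 2); a missing genotype
    on a haplotype contributes no variants (deletions are resolved from the
    structural sidecar, not the VCF).  Unphased heterozygous records are
    rejected — this caller consumes phase-resolved input only.
    """
    depth_by_sample = depth_by_sample or {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        variants: dict[str, dict[int, set[VariantKey]]] = {
            s: {1: set(), 2: set()} for s in samples
        }
        for rec in vcf:
            key = VariantKey(
                gene_pos=rec.pos,
                ref_base=rec.ref,
                alt_base=rec.alts[0],
                rsid=None if rec.id in (None, ".") else rec.id,
            )
            for s in samples:
                call = rec.samples[s]
                gt = call["GT"]
                if gt is None:
                    continue
                observed = [g for g in gt if g is not None]
                if len(set(observed)) > 1 and not call.phased:
                    raise ValueError(
                        f"{path}: unphased heterozygous genotype for {s} at "
                        f"position {rec.pos}"
                    )
                for hap, g in zip((1, 2), gt):
                    if g == 1:
                        variants[s][hap].add(key)
    return [
        HaplotypeObservation(
            sample_id=s,
            hap_index=hap,
            variants=frozenset(variants[s][hap]),
            mean_depth=float(depth_by_sample.get(s, 0.0)),
        )
        for s in samples
        for hap in (1, 2)
    ]


def write_haplotype_tsv(
    observations: Sequence[HaplotypeObservation], path: str | Path
) -> None:
    lines = ["sample\thap\tvariants"]
    for obs in observations:
        tokens = ";".join(v.token for v in sorted(obs.variants)) or "."
        lines.append(f"{obs.sample_id}\t{obs.hap_index}\t{tokens}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_haplotype_tsv(
    path: str | Path,
    depth_by_sample: Optional[Mapping[str, float]] = None,
) -> list[HaplotypeObservation]:
    depth_by_sample = depth_by_sample or {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != ["sample", "hap", "variants"]:
        raise ValueError(f"{path}: not a haplotype TSV")
    out = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        try:
            sample, hap, tokens = raw.split("\t")
            variants = frozenset(
                VariantKey.from_token(t)
                for t in tokens.split(";")
                if t and t != "."
            )
            out.append(
                HaplotypeObservation(
                    sample_id=sample,
                    hap_index=int(hap),
                    variants=variants,
                    mean_depth=float(depth_by_sample.get(sample, 0.0)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_structural_tsv(
    events: Mapping[str, Sequence[StructuralStatus]], path: str | Path
) -> None:
    lines = ["sample\tkind\tmultiplicity\tcarrier_hap"]
    for sample in sorted(events):
        for e in events[sample]:
            mult = "." if e.multiplicity is None else str(e.multiplicity)
            lines.append(f"{sample}\t{e.kind.value}\t{mult}\t{e.carrier_hap}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_structural_tsv(path: str | Path) -> dict[str, list[StructuralStatus]]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != [
        "sample", "kind", "multiplicity", "carrier_hap",
    ]:
        raise ValueError(f"{path}: not a structural-evidence TSV")
    events: dict[str, list[StructuralStatus]] = defaultdict(list)
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        try:
            sample, kind, mult, hap = raw.split("\t")
            events[sample].append(
                StructuralStatus(
                    kind=StructuralKind(kind),
                    multiplicity=None if mult == "." else int(mult),
                    carrier_hap=int(hap),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return dict(events)


def write_depth_tsv(depths: Mapping[str, float], path: str | Path) -> None:
    lines = ["sample\tmean_depth"]
    for sample in sorted(depths):
        lines.append(f"{sample}\t{depths[sample]:.2f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_depth_tsv(path: str | Path) -> dict[str, float]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != ["sample", "mean_depth"]:
        raise ValueError(f"{path}: not a depth TSV")
    out: dict[str, float] = {}
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        try:
            sample, depth = raw.split("\t")
            out[sample] = float(depth)
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_calls_tsv(calls: Sequence[StarCall], path: str | Path) -> None:
    """Per-haplotype star-call TSV (sample, hap, allele, suballele, novelty)."""
    lines = ["sample\thap\tallele\tsuballele\tnovel_suballele\tunexplained"]
    for c in calls:
        unexpl = ";".join(v.token for v in sorted(c.unexplained)) or "."
        lines.append(
            "\t".join(
                [c.sample_id, str(c.hap_index), c.allele, c.suballele or ".",
                 "yes" if c.is_novel_suballele else "no", unexpl]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
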