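"""End-to-end orchestration: QC → calling → diplotyping → phenotyping → stats.

Each stage consumes only the outputs of earlier stages, every intermediate
is written to the output directory as TSV/JSON, and a run manifest records
the configuration so a run can be replayed or inspected stage by stage.
Samples are retained per gene: failing one gene's amplicons does not drop
a sample from the other gene's analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io as pgx_io
from .calling import (
    DEFAULT_DEPTH_THRESHOLD,
    StarCall,
    collect_novel_candidates,
    match_haplotype,
    qc_filter,
)
from .cohort import (
    CohortSummary,
    FrequencyComparison,
    compare_to_reference,
    reference_fixture,
    summarise_cohort,
)
from .defs import (
    DefinitionTable,
    FunctionClass,
    builtin_table,
    load_definition_table,
)
from .diplotype import Diplotype, call_diplotype
from .phenotype import PhenotypeCall, PhenotypeClass, call_phenotype, reassign_function

__all__ = [
    "GeneInputs",
    "PipelineConfig",
    "GeneReport",
    "PipelineReport",
    "PipelineError",
    "run_pipeline",
    "render_tables",
]

logger = logging.getLogger("pgxstar")

_PHENOTYPE_ORDER = [
    (PhenotypeClass.ULTRA_RAPID, "Ultra-rapid"),
    (PhenotypeClass.RAPID, "Rapid"),
    (PhenotypeClass.NORMAL, "Normal"),
    (PhenotypeClass.INTERMEDIATE, "Intermediate"),
    (PhenotypeClass.POOR, "Poor"),
    (PhenotypeClass.UNCERTAIN, "Uncertain/unknown"),
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics and exit codes."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class GeneInputs:
    gene: str
    haplotypes: Path  # phased VCF (.vcf) or haplotype TSV (.tsv)
    depth: Optional[Path] = None
    structural: Optional[Path] = None
    definition_table: Optional[Path] = None  # None -> packaged builtin


@dataclass(frozen=True)
class PipelineConfig:
    genes: tuple[GeneInputs, ...]
    populations: tuple[str, ...] = ("oceanian", "european")
    qc_threshold: float = DEFAULT_DEPTH_THRESHOLD
    #: allele -> (new function class, new activity value) what-if overrides
    scenario: dict[str, tuple[FunctionClass, Optional[float]]] = field(
        default_factory=dict
    )
    outdir: Optional[Path] = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("at least one gene is required")
        if self.qc_threshold <= 0:
            raise ValueError("QC threshold must be positive")


@dataclass
class GeneReport:
    gene: str
    table: DefinitionTable
    qc_passed: list[str]
    qc_failed: list[str]
    calls: list[StarCall]
    diplotypes: list[Diplotype]
    phenotypes: list[PhenotypeCall]
    summary: CohortSummary
    comparisons: dict[str, list[FrequencyComparison]]
    novel_candidates: "object"  # pandas DataFrame
    scenario_phenotypes: Optional[list[PhenotypeCall]] = None
    scenario_summary: Optional[CohortSummary] = None


@dataclass
class PipelineReport:
    genes: dict[str, GeneReport]
    sample_counts: dict[str, int]
    overlap_count: int
    manifest: dict


def _load_table(inputs: GeneInputs) -> DefinitionTable:
    if inputs.definition_table is None:
        return builtin_table(inputs.gene)
    return load_definition_table(inputs.definition_table, inputs.gene)


def _run_gene(
    inputs: GeneInputs,
    config: PipelineConfig,
) -> GeneReport:
    gene = inputs.gene
    try:
        table = _load_table(inputs)
    except Exception as exc:
        raise PipelineError("definitions", f"{gene}: {exc}") from exc

    try:
        depths = (
            pgx_io.read_depth_tsv(inputs.depth) if inputs.depth is not None else {}
        )
    except Exception as exc:
        raise PipelineError("depth", f"{gene}: {exc}") from exc

    try:
        path = Path(inputs.haplotypes)
        if path.suffix == ".vcf":
            observations = pgx_io.read_phased_vcf(path, depth_by_sample=depths)
        else:
            observations = pgx_io.read_haplotype_tsv(path, depth_by_sample=depths)
    except Exception as exc:
        raise PipelineError("haplotypes", f"{gene}: {exc}") from exc

    all_samples = sorted({o.sample_id for o in observations})
    if depths:
        missing = [s for s in all_samples if s not in depths]
        if missing:
            raise PipelineError(
                "qc", f"{gene}: no depth record for samples {missing[:5]}"
            )
        passed, failed = qc_filter(
            {s: depths[s] for s in all_samples}, config.qc_threshold
        )
    else:  # no depth sidecar: everything passes
        passed, failed = list(all_samples), []
    if not passed:
        raise PipelineError("qc", f"{gene}: no sample passed depth QC")
    passed_set = set(passed)
    logger.info("%s: %d/%d samples passed QC", gene, len(passed), len(all_samples))

    try:
        structural = (
            pgx_io.read_structural_tsv(inputs.structural)
            if inputs.structural is not None
            else {}
        )
    except Exception as exc:
        raise PipelineError("structural", f"{gene}: {exc}") from exc

    try:
        calls = [
            match_haplotype(o, table)
            for o in observations
            if o.sample_id in passed_set
        ]
        by_sample: dict[str, dict[int, StarCall]] = {}
        for c in calls:
            by_sample.setdefault(c.sample_id, {})[c.hap_index] = c
        diplotypes = []
        for sample in sorted(by_sample):
            haps = by_sample[sample]
            if set(haps) != {1, 2}:
                raise PipelineError(
                    "diplotype", f"{gene}: sample {sample} lacks two haplotypes"
                )
            diplotypes.append(
                call_diplotype(
                    haps[1], haps[2], structural.get(sample), deletion_allele="*5"
                )
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("calling", f"{gene}: {exc}") from exc

    try:
        phenotypes = [call_phenotype(d, table) for d in diplotypes]
        summary = summarise_cohort(diplotypes, phenotypes, gene=gene)
    except Exception as exc:
        raise PipelineError("phenotype", f"{gene}: {exc}") from exc

    comparisons: dict[str, list[FrequencyComparison]] = {}
    for population in config.populations:
        try:
            refs = reference_fixture(gene, population)
        except Exception as exc:
            raise PipelineError("compare", f"{gene}: {exc}") from exc
        rows = []
        for allele, count in summary.allele_counts.items():
            freq_n = refs.get(allele)
            if freq_n is None:
                continue
            rows.append(
                compare_to_reference(
                    allele, count, summary.n_haplotypes, freq_n[0], freq_n[1]
                )
            )
        comparisons[population] = rows

    report = GeneReport(
        gene=gene,
        table=table,
        qc_passed=passed,
        qc_failed=failed,
        calls=calls,
        diplotypes=diplotypes,
        phenotypes=phenotypes,
        summary=summary,
        comparisons=comparisons,
        novel_candidates=collect_novel_candidates(calls),
    )

    scenario_alleles = [a for a in config.scenario if a in table.allele_names()]
    if scenario_alleles:
        scenario_table = table
        for allele in scenario_alleles:
            fn, activity = config.scenario[allele]
            scenario_table = reassign_function(scenario_table, allele, fn, activity)
        report.scenario_phenotypes = [
            call_phenotype(d, scenario_table) for d in diplotypes
        ]
        report.scenario_summary = summarise_cohort(
            diplotypes, report.scenario_phenotypes, gene=gene
        )
    return report


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage for every configured gene and emit the report bundle.

    On any stage error the partial output directory contents written by
    this run are removed and :class:`PipelineError` propagates with the
    stage name.
    """
    outdir = Path(config.outdir) if config.outdir is not None else None
    written: list[Path] = []
    try:
        reports = {g.gene: _run_gene(g, config) for g in config.genes}
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise

    sample_sets = {g: set(r.qc_passed) for g, r in reports.items()}
    overlap = (
        len(set.intersection(*sample_sets.values())) if len(sample_sets) > 1 else 0
    )
    manifest = {
        "genes": [g.gene for g in config.genes],
        "qc_threshold": config.qc_threshold,
        "populations": list(config.populations),
        "scenario": {
            a: [fn.value, activity]
            for a, (fn, activity) in config.scenario.items()
        },
        "sample_counts": {g: len(s) for g, s in sample_sets.items()},
        "overlap_count": overlap,
    }
    report = PipelineReport(
        genes=reports,
        sample_counts={g: len(s) for g, s in sample_sets.items()},
        overlap_count=overlap,
        manifest=manifest,
    )
    if outdir is not None:
        try:
            written = _write_bundle(report, outdir)
        except Exception as exc:
            for p in written:
                p.unlink(missing_ok=True)
            raise PipelineError("write", str(exc)) from exc
    return report


def _write_bundle(report: PipelineReport, outdir: Path) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path, text: str) -> None:
        path.write_text(text, encoding="utf-8")
        written.append(path)

    emit(outdir / "manifest.json", json.dumps(report.manifest, indent=1) + "\n")
    for gene, rep in report.genes.items():
        prefix = outdir / gene.lower()
        pgx_io.write_calls_tsv(rep.calls, f"{prefix}.calls.tsv")
        written.append(Path(f"{prefix}.calls.tsv"))
        emit(
            Path(f"{prefix}.qc.tsv"),
            "sample\tqc\n"
            + "".join(f"{s}\tpass\n" for s in rep.qc_passed)
            + "".join(f"{s}\tfail\n" for s in rep.qc_failed),
        )
        lines = ["sample\tdiplotype\tactivity_score\tphenotype"]
        for d, p in zip(rep.diplotypes, rep.phenotypes):
            score = "." if p.activity_score is None else f"{p.activity_score:g}"
            lines.append(f"{d.sample_id}\t{d.display}\t{score}\t{p.phenotype.value}")
        emit(Path(f"{prefix}.phenotypes.tsv"), "\n".join(lines) + "\n")
        if rep.scenario_phenotypes is not None:
            lines = ["sample\tdiplotype\tactivity_score\tphenotype"]
            for d, p in zip(rep.diplotypes, rep.scenario_phenotypes):
                score = "." if p.activity_score is None else f"{p.activity_score:g}"
                lines.append(
                    f"{d.sample_id}\t{d.display}\t{score}\t{p.phenotype.value}"
                )
            emit(Path(f"{prefix}.phenotypes.scenario.tsv"), "\n".join(lines) + "\n")
        rep.novel_candidates.to_csv(
            f"{prefix}.novel.tsv", sep="\t", index=False
        )
        written.append(Path(f"{prefix}.novel.tsv"))
        emit(Path(f"{prefix}.tables.txt"), render_tables(rep.summary, rep.comparisons))
        raw = {
            "summary": {
                "n_individuals": rep.summary.n_individuals,
                "n_haplotypes": rep.summary.n_haplotypes,
                "allele_counts": rep.summary.allele_counts,
                "allele_freqs": rep.summary.allele_freqs,
                "phenotype_counts": {
                    k.value: v for k, v in rep.summary.phenotype_counts.items()
                },
                "phenotype_freqs": {
                    k.value: v for k, v in rep.summary.phenotype_freqs.items()
                },
            },
            "comparisons": {
                pop: [
                    {
                        "allele": c.allele,
                        "chi2": c.chi2,
                        "p_value": c.p_value,
                        "stars": c.stars,
                        "ref_freq": c.ref_freq,
                    }
                    for c in rows
                ]
                for pop, rows in rep.comparisons.items()
            },
        }
        emit(Path(f"{prefix}.report.json"), json.dumps(raw, indent=1) + "\n")
    return written


def render_tables(
    summary: CohortSummary,
    comparisons: Optional[dict[str, list[FrequencyComparison]]] = None,
) -> str:
    """Render allele- and phenotype-frequency tables as aligned text.

    Frequencies are rounded to 3 decimal places at presentation time only;
    reference columns carry their significance stars; phenotype classes
    with zero observations render as ``0 0``, and the rapid class for
    CYP2D6 (where it does not exist) as ``n/a n/a``.
    """
    comparisons = comparisons or {}
    by_pop = {
        pop: {c.allele: c for c in rows} for pop, rows in comparisons.items()
    }
    lines = [f"{summary.gene} star allele frequencies "
             f"(n = {summary.n_haplotypes} haplotypes)"]
    header = ["allele", "count", "freq"] + [f"ref_{p}" for p in by_pop]
    rows = [header]
    for allele, count in summary.allele_counts.items():
        row = [allele, str(count), f"{count / summary.n_haplotypes:.3f}"]
        for pop in by_pop:
            comp = by_pop[pop].get(allele)
            if comp is None or comp.skipped:
                row.append("n.d.")
            else:
                row.append(f"{comp.ref_freq:.3f}{comp.stars}")
        rows.append(row)
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    for r in rows:
        lines.append("  ".join(c.ljust(w) for c, w in zip(r, widths)))

    if summary.phenotype_counts:
        lines.append("")
        lines.append(
            f"{summary.gene} inferred metaboliser phenotypes "
            f"(n = {summary.n_individuals} individuals)"
        )
        for cls, label in _PHENOTYPE_ORDER:
            if summary.gene == "CYP2D6" and cls is PhenotypeClass.RAPID:
                lines.append(f"{label}\tn/a n/a")
                continue
            count = summary.phenotype_counts.get(cls, 0)
            freq = count / summary.n_individuals if summary.n_individuals else 0.0
            if count == 0:
                lines.append(f"{label}\t0 0")
            else:
                lines.append(f"{label}\t{count} {freq:.3f}")
    return "\n".join(lines) + "\n"
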