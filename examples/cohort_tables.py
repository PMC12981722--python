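"""Rebuild the study's cohort frequency tables and reference comparisons.

Expands the packaged published haplotype counts (270 CYP2D6 and 146
CYP2C19 haplotypes) into diplotypes, summarises them, and renders the
allele-frequency tables with chi-square significance stars against the
ClinPGx Oceanian and European reference populations.  Stars mark alleles
whose cohort frequency differs from the reference (* p<0.05, ** p<0.01,
*** p<0.001).
"""

from pgxstar import compare_to_reference, reference_fixture
from pgxstar.cohort import diplotypes_from_counts, study_allele_counts, summarise_cohort
from pgxstar.pipeline import render_tables

for gene in ("CYP2D6", "CYP2C19"):
    counts = study_allele_counts(gene)
    summary = summarise_cohort(diplotypes_from_counts(counts), gene=gene)
    comparisons = {}
    for population in ("oceanian", "european"):
        refs = reference_fixture(gene, population)
        comparisons[population] = [
            compare_to_reference(
                allele, count, summary.n_haplotypes, *refs[allele]
            )
            for allele, count in summary.allele_counts.items()
            if allele in refs
        ]
    print(render_tables(summary, comparisons))
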