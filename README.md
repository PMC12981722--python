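# pgxstar

Star-allele calling, diplotype-to-phenotype translation and cohort
allele-frequency statistics for the pharmacogenes **CYP2D6** and **CYP2C19**.

CYP2D6 and CYP2C19 encode liver enzymes that metabolise a large share of
commonly prescribed drugs. Both genes are highly polymorphic, and named
haplotypes — *star alleles* such as CYP2D6\*2 or CYP2C19\*17, each defined by
a set of core variants — differ in enzymatic function. An individual's pair
of star alleles (the *diplotype*, written `*4/*5`) predicts their
metaboliser phenotype, which matters clinically: poor and ultra-rapid
metabolisers risk adverse reactions or treatment failure at standard doses.
`pgxstar` is aimed at researchers analysing targeted long-read (amplicon)
sequencing of these genes in population cohorts, particularly cohorts whose
raw data cannot be publicly deposited: every analysis step runs equally on
real phased haplotypes or on synthetic cohorts drawn from published allele
frequencies.

## What it does

- **Allele definitions** (`pgxstar.defs`): a documented TSV dialect for
  star-allele/suballele definition tables (variant sets, function class,
  activity score), with packaged desk-scale tables for CYP2D6 and CYP2C19.
  Coordinates are 1-based on the gene reference sequence; GRCh38 positions
  are annotations, checked against the reverse-strand identity
  `gene_pos + grch38_pos = const` for CYP2D6.
- **Haplotype calling** (`pgxstar.calling`): assigns to each phased
  haplotype the star allele with the largest core-variant set contained in
  it, then the best suballele; leftover variants are flagged as candidate
  novel suballeles. Depth QC keeps samples with mean amplicon depth
  strictly above 100×.
- **Diplotypes and CNV** (`pgxstar.diplotype`): whole-gene deletion (\*5)
  and duplication (`xN`) evidence from a diagnostic amplicon is merged with
  the two haplotype calls into a canonical `A/B` diplotype.
- **Phenotype** (`pgxstar.phenotype`): CYP2D6 uses the additive activity
  score AS = Σ alleles (an `xN` allele contributes N× its value) binned as
  poor (AS = 0), intermediate (0 < AS < 1.25), normal (1.25 ≤ AS ≤ 2.25),
  ultra-rapid (AS > 2.25); any uncertain/unknown-function allele makes the
  call *uncertain*. CYP2C19 uses a categorical rule table on function-class
  pairs (including the *rapid* class for \*1/\*17). `reassign_function`
  supports what-if scenarios such as treating \*71 as nonfunctional.
- **Cohort statistics** (`pgxstar.cohort`): haplotype-denominated allele
  frequencies, phenotype frequencies, and Pearson chi-square 2×2
  comparisons against packaged ClinPGx Oceanian/European reference
  frequencies with the `*`/`**`/`***` significance convention.
- **Synthetic cohorts** (`pgxstar.simulate`): diploid cohorts drawn under
  Hardy–Weinberg from a star-allele frequency vector (structural
  pseudo-alleles included), expanded to phased variant sets, with optional
  novel-variant injection and a complete ground-truth ledger; emitted as
  phased VCF + TSV sidecars.
- **Pipeline & CLI** (`pgxstar.pipeline`, `pgxstar` command): QC → calling
  → diplotyping → phenotyping → summaries → reference comparison as one
  reproducible run with TSV/JSON reports.

## Worked example

```python
from pgxstar import FunctionClass, builtin_table, call_phenotype, reassign_function
from pgxstar.diplotype import Diplotype

table = builtin_table("CYP2D6")
for a, b in [("*4", "*5"), ("*1x2", "*1"), ("*71", "*1")]:
    p = call_phenotype(Diplotype("demo", a, b), table)
    print(a, b, p.activity_score, p.phenotype.value)

scenario = reassign_function(table, "*71", FunctionClass.NO_FUNCTION, 0.0)
print(call_phenotype(Diplotype("demo", "*71", "*1"), scenario).phenotype.value)
```

prints

```
*4 *5 0.0 poor
*1x2 *1 3.0 ultra_rapid
*71 *1 None uncertain
intermediate
```

`*4/*5` combines a nonfunctional allele with a whole-gene deletion: total
activity 0, a poor metaboliser. `*1x2/*1` carries three functional gene
copies (2 + 1 = 3), an ultra-rapid metaboliser. `*71/*1` cannot be scored
while \*71's function is unresolved — but under the scenario table in which
\*71 is nonfunctional, the same diplotype scores 1 and becomes an
intermediate metaboliser.

The scripts in `examples/` each demonstrate one capability end to end
(calling, phenotypes, cohort tables, simulation + parameter recovery).

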