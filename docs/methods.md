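# Methods

## Model and scope

`pgxstar` implements the genotype-to-phenotype half of a pharmacogene
amplicon-sequencing study: it starts from *phased haplotypes* (the variant
content of each parental gene copy, as produced by long-read consensus
pipelines) and ends at cohort-level frequency tables and reference
comparisons. Everything upstream — basecalling, alignment, phasing,
consensus polishing — is out of scope, as is hybrid-gene (CYP2D6/2D7
fusion) detection.

A *star allele* is a named haplotype defined by a set of core variants; a
*suballele* adds non-core variants on the same core. The package's
definition tables are deliberately desk-scale: they contain the alleles a
cohort analysis needs, with core-variant sets large enough to discriminate
the alleles in the table, not the full PharmVar catalogue. Two practical
consequences are documented rather than hidden:

- Core sets are *discriminating subsets*. For example \*2 is keyed on
  rs16947 (R296C) and rs1135840 (S486T), \*10 on rs1065852 (P34S) alone
  and \*4 on rs1065852 plus the rs3892097 splice defect, so that \*4's
  core strictly contains \*10's and the maximal-core rule resolves them.
  Full PharmVar definitions carry more positions; a haplotype from a
  different catalogue may therefore show benign "unexplained" variants.
- Gene-reference positions for variants whose position the packaged
  sources did not print directly are plausible placements within the
  correct gene region, derived where possible from well-known GRCh38
  coordinates through the reverse-strand constant (below). They are
  internally consistent and sufficient for matching, but are fixture
  approximations, not PharmVar ground truth.

## Coordinates

All matching uses 1-based positions on the gene reference sequence
(CYP2D6: NG_008376.4/LRG_303, position 1 = sequence start). GRCh38
positions are optional annotations. CYP2D6 lies on the reverse strand of
chromosome 22, so for every dual-annotated variant
`gene_pos + grch38_pos` must equal one gene-wide constant (42,135,811 for
the packaged table); `check_coordinate_consistency` enforces this and is
the fixture-integrity check. CYP2C19 fixtures carry no GRCh38 annotations
(forward strand; the identity does not apply), so the check reports an
insufficient-data error there by design.

## Haplotype matching

`match_haplotype` scores every non-structural allele whose core set is
contained in the haplotype by `(|core|, −|unexplained|, −star number)` and
takes the maximum; the default allele (\*1, empty core) is always a
candidate, so a variant-free or unmatched haplotype falls back to it.
The best suballele is then the largest non-empty suballele set contained
in the residual variants (ties to the lowest numeric suffix). Whatever
remains is `unexplained` and marks the call as a novel-suballele
candidate. Matching is exact on `(gene_pos, ref, alt)`; no indel-window or
fuzzy matching is attempted, because amplicon consensus variants are
assumed normalised upstream. Because star numbers are unique within a
table the tie-break chain always resolves; the ambiguity error is retained
as a guard against malformed tables. The fallback-to-default rule for a
haplotype carrying only part of an allele's core is this package's choice;
manual curation in the source studies may have resolved such cases
differently.

Depth QC keeps samples with mean amplicon depth **strictly greater than**
100 reads (the threshold is a parameter; the strict inequality mirrors the
">100×" convention of the lab protocol this models).

## Structural alleles

The whole-gene deletion \*5 and duplications are not called from small
variants: the lab assay this models detects them with a separate 3.5 kb
diagnostic amplicon. They therefore enter as per-sample structural
evidence (kind, carrier haplotype, multiplicity). A deletion replaces the
carrier haplotype's call — and it is an inconsistency error for that
haplotype to show variants — while a duplication suffixes the carrier
label (`*1x2`). In frequency tables a duplicated allele is denominated as
**one** haplotype (the denominator is always 2n), matching how published
cohort tables count `*1x2`. Canonical diplotype order is ascending star
number with a duplicated label before its plain counterpart, giving the
conventional `*1x2/*1` display.

## Phenotype translation

CYP2D6 uses the standardised additive activity-score system: per-allele
values (0, 0.25, 0.5, 1) summed over the diplotype, an `xN` allele
contributing N× its value. Bins: poor = 0, intermediate (0, 1.25), normal
[1.25, 2.25], ultra-rapid > 2.25. The bin edges come from the standardised
CPIC convention; boundary values are inclusive on the normal range exactly
as written. Any allele of uncertain or unknown function (here \*71, \*108,
\*186) makes the score undefined and the phenotype *uncertain* — unknown
function is deliberately treated the same as uncertain, since the cohort
tables this reproduces merge them into one class.

CYP2C19 has no activity score. Phenotype is a closed rule table on the
unordered pair of function classes: two no-function → poor; no-function
with normal or increased → intermediate; normal/normal → normal;
normal/increased → rapid; increased/increased → ultra-rapid.
Decreased-function CYP2C19 alleles are outside the rule table (none occur
in the packaged catalogue) and raise an error rather than guessing.

`reassign_function` returns a modified copy of a definition table for
scenario analysis (e.g. \*71 → no function, activity 0). The packaged
allele model enforces that uncertain/unknown function never carries a
numeric activity value, in both directions of reassignment.

## Cohort statistics

Allele frequencies are counts over 2n haplotypes, phenotype frequencies
counts over n individuals; both are kept at full precision internally and
rounded to 3 decimals only when rendered. The study-versus-reference
comparison builds the 2×2 haplotype-count table
`[[k, 2n−k], [round(f·2m), 2m−round(f·2m)]]` from the study count k and a
reference frequency f reported for m individuals, and applies Pearson's
chi-square (1 df) via `scipy.stats.chi2_contingency`, without continuity
correction by default. Both choices are exposed: `yates=True` switches the
correction on, and `ref_n_is_individuals=False` treats the reference n as
haplotypes. Reference n values are interpreted as individuals because the
aggregate source reports cohort sizes; the published tables do not say
which convention their test used, so only verdicts robust to every variant
of the construction (the extreme `***` contrasts at very large m) are
asserted in tests. A reference frequency recorded as "n.d." yields a
skipped comparison; a reference frequency of exactly 0 with a positive
study count keeps all margins positive and produces a finite statistic.
No multiple-testing adjustment is applied (stars are per-allele, matching
the presentation this reproduces).

## Synthetic cohorts

The generator emulates a diploid amplicon-sequencing cohort whose raw data
cannot be shared: each individual draws two alleles i.i.d. from a
star-allele frequency vector (Hardy–Weinberg equilibrium; genes are
simulated independently; no linkage, inbreeding or household structure).
The default frequency vector is the published cohort's haplotype counts
divided by their total (printed 3-decimal frequencies sum to 1.001, counts
are exact). Structural pseudo-alleles in the vector (`*5`, `*1x2`) become
per-sample structural evidence; a deleted haplotype emits no variant
records, only the sidecar flag, mirroring the diagnostic-amplicon design.
Haplotype variant content is the chosen allele's core set (suballeles are
not sampled); novel variants are injected per non-deleted haplotype with
probability `novel_injection_rate` at reserved positions ≥ 500 bases past
the last catalogued variant, so injected and catalogued variants can never
collide and every downstream novel call is attributable. Per-sample depth
is Normal(mean, sd) truncated at 0, default mean 1000× and sd 200× —
comfortably above the 100× QC threshold, as in a typical successful
amplicon run. Every decision is logged in a ground-truth ledger, and
identical config + seed reproduces byte-identical output files.

What passing synthetic tests shows — and does not. The generator produces
clean, pre-normalised, correctly phased haplotypes with complete depth
metadata. It does not emulate nanopore error profiles, phasing errors,
partial amplicon dropout, hybrid genes, or suballele linkage; agreement on
synthetic cohorts therefore validates the calling/translation/statistics
logic, not robustness to upstream artefacts.

## Problem sizes and numerical choices

The end-to-end recovery experiment simulates 5,000 individuals (10,000
haplotypes), at which the 3-binomial-SE band is ±1.3% for the commonest
allele; the exhaustive matcher-versus-oracle check enumerates all ~110,000
haplotypes of up to 6 variants over the CYP2D6 table's 22-variant
universe. Frequency sums are validated to 1 ± 1e−9; chi-square equivalence
to the Σ(O−E)²/E oracle is asserted to 1e−9. Rounding to printed precision
uses Python's round-half-even; no reproduced table value sits on a half
boundary.

## Known limitations

- Allele catalogues are study-scale fixtures, not PharmVar exports; calls
  on haplotypes from richer catalogues may flag benign variants as novel.
- Structural-event phase (hap 1 vs 2) is taken from input evidence and
  never inferred; which copy of a duplication carries which suballele is
  not modelled beyond a suballele note.
- CYP2C19 rules cover only the function classes present in the packaged
  catalogue; extending to decreased-function alleles requires widening the
  rule table.
- Borderline significance stars depend on unknowable details of the
  original test construction and are not asserted; both documented
  construction options are available to the user.
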