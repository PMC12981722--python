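"""Assign star alleles to a few phased CYP2D6 haplotypes.

Builds three haplotypes by hand — the *2-defining pair rs16947/rs1135840,
an empty (reference) haplotype, and a *2 haplotype carrying an extra
intronic variant that is not part of any catalogued (sub)allele — and
prints the call for each.  The third call is flagged as a candidate novel
suballele: the haplotype matches the *2 core but one variant is left
unexplained.
"""

from pgxstar import HaplotypeObservation, builtin_table, match_haplotype
from pgxstar.defs import VariantKey

table = builtin_table("CYP2D6")
rs16947 = table.variant_by_rsid("rs16947")
rs1135840 = table.variant_by_rsid("rs1135840")
uncatalogued = VariantKey(gene_pos=9750, ref_base="A", alt_base="G")

haplotypes = {
    "star2 core": {rs16947, rs1135840},
    "reference": set(),
    "star2 + extra variant": {rs16947, rs1135840, uncatalogued},
}
for label, variants in haplotypes.items():
    hap = HaplotypeObservation("demo", 1, frozenset(variants), mean_depth=850)
    call = match_haplotype(hap, table)
    print(
        f"{label:24s} -> {call.label:6s} "
        f"novel_suballele={call.is_novel_suballele} "
        f"unexplained={[v.token for v in sorted(call.unexplained)]}"
    )
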