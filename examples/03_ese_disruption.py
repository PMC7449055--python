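"""Allele-specific exonic splice enhancer (ESE) disruption.

Scans a 23-nt exon-8 context for panel hexamers on both alleles of the
AA>GC dinucleotide substitution.  The K allele carries two overlapping
enhancer hexamers (AAGAAG, AGAAGG) spanning the variant; the substitution
destroys both and creates none — the proposed mechanism for reduced
splicing efficiency on the A allele.
"""

from junctionqtl.ese_scan import apply_variant, default_panel, scan_ese, variant_motif_delta
from junctionqtl.io_core import VariantSpec
from junctionqtl.synthetic_data import dgat1_exon8_geometry

geom = dgat1_exon8_geometry()
context = geom["k_allele_context_23nt"]
offset = geom["context_offset"]
variant = VariantSpec(
    geom["chrom"], geom["variant_pos"], geom["variant_ref"], geom["variant_alt"]
)

print(f"K-allele context ({geom['chrom']}:{offset}..{offset + len(context) - 1}):")
print(" ", context)
rel = variant.pos - offset
print(" ", " " * rel + "^^", f"AA>GC at {variant.pos}")

lost, gained, counts = variant_motif_delta(
    context, variant, default_panel(), genomic_offset=offset
)
print(f"\npanel hexamers overlapping the variant: K allele {counts['ref']}, "
      f"A allele {counts['alt']}")
for hit in lost:
    print(f"  destroyed by AA>GC: {hit.motif} at {hit.genomic_start}-{hit.genomic_start + 5}")
print(f"hexamers created by the substitution: {len(gained)}")

alt_context = apply_variant(context, rel, variant.ref, variant.alt)
print(f"\nA-allele context:\n  {alt_context}")
print("full-scan hits on A allele:", [h.motif for h in scan_ese(alt_context, default_panel())])
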