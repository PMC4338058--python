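"""Extract trimmed intergenic regions from a small annotated genome.

Builds a toy linear genome with two genes, extracts the gap between them,
and shows the 40 bp trimming and 120 bp length rules at work.
"""

from srna_seeker import AnnotatedGenome, GeneFeature, extract_igrs, igr_sequences

genome = AnnotatedGenome(
    "toy", "ACGT" * 500, is_circular=False,
    features=[
        GeneFeature("geneA", "CDS", 100, 500, "+", "protein A"),
        GeneFeature("geneB", "CDS", 900, 1500, "-", "protein B"),
    ],
)

for igr in extract_igrs(genome):
    print(f"{igr.igr_id}: raw gap [{igr.raw_start}, {igr.raw_end}) -> "
          f"trimmed [{igr.start}, {igr.end}), length {igr.length} bp, "
          f"flanks {igr.flank_strands}")

print(igr_sequences(genome, [r for r in extract_igrs(genome) if r.has_both_flanks])
      .split("\n")[0])
print("The raw 400 bp gap loses 40 bp per side (promoter/UTR/terminator "
      "territory of the flanking ORFs) and survives the >=120 bp filter.")
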