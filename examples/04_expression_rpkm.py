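"""Deduplicate aligned reads, count them per feature and compute RPKM.

Three exact-duplicate reads collapse to one; counting assigns a read to a
feature only when at least half the read overlaps it; RPKM normalizes by
library size (millions) and feature length (kb).
"""

from srna_seeker import ReadAlignment, dedup, quantify

reads = [
    ReadAlignment("r1", 120, 170, "+", "control"),
    ReadAlignment("r1_dup", 120, 170, "+", "control"),   # PCR duplicate
    ReadAlignment("r1_dup2", 120, 170, "+", "control"),  # PCR duplicate
    ReadAlignment("r2", 300, 350, "-", "control"),
    ReadAlignment("r3", 480, 530, "+", "control"),       # only 20/50 in geneA
]
features = [("geneA", 100, 500), ("geneB", 900, 1500)]

print(f"{len(reads)} reads -> {len(dedup(reads))} after PCR-duplicate removal")

table = quantify(reads, features)
print(table.df.to_string(index=False))
print("\ngeneA counts 2 (not 3: duplicates removed; not including r3: only "
      "40% of it overlaps). RPKM = count / (mapped_millions * length_kb).")
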