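"""Scan a sequence for sigma-70 promoters and intrinsic terminators.

Plants a consensus promoter (TTGACA..17nt..TATAAT) and a strong hairpin
terminator (8 bp GC stem + 8 nt U-tract) in random background, scans both
strands and reports the complete-transcriptional-unit decision.
"""

import numpy as np

from srna_seeker import call_unit, scan_promoters, scan_terminators
from srna_seeker.igr_extraction import IGRecord

rng = np.random.default_rng(0)
bg = lambda n: "".join(rng.choice(list("ACGT"), size=n))

promoter = "TTGACA" + bg(17) + "TATAAT"
stem = "GCGGCGGC"
terminator = stem + "GAAA" + stem[::-1].translate(str.maketrans("ACGT", "TGCA")) + "T" * 8
seq = bg(60) + promoter + bg(80) + terminator + bg(60)

promoters = scan_promoters(seq, "+") + scan_promoters(seq, "-")
terminators = scan_terminators(seq, "+") + scan_terminators(seq, "-")

for h in promoters:
    print(f"promoter  strand {h.strand} pos {h.position:4d} score {h.score:6.2f} "
          f"(spacer {h.details['spacer_len']})")
for h in terminators:
    print(f"terminator strand {h.strand} pos {h.position:4d} score {h.score:6.2f} "
          f"(stem {h.details['stem_len']}, hairpin {h.details['hairpin_score']}, "
          f"tail {h.details['tail_score']:.1f})")

igr = IGRecord("IGR-demo", 0, len(seq), 0, len(seq), None, None)
unit = call_unit(igr, promoters, terminators)
print(f"\ncomplete transcriptional unit: {unit.complete_unit} "
      f"(strand {unit.unit_strand})")
print("A promoter upstream of a terminator on the same strand marks this "
      "region as a candidate sRNA locus.")
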