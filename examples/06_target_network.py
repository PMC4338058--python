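"""Predict sRNA targets by antisense seed matching and summarize the network.

An sRNA carrying a 12 nt segment exactly complementary to a gene's
translation-initiation window (-30..+20 around the start codon) is predicted
to regulate it; genes hit by two or more sRNAs are co-regulated.
"""

from srna_seeker.annotation_io import revcomp
from srna_seeker import build_network, cog_tally, coregulation_stats, predict_targets

srna1 = "AUGGCAUCCGGAUUGCACCGUAGGCAUCCUAA".replace("U", "T") * 3
seed = srna1[10:22]
windows = [
    ("ftsX", "A" * 20 + revcomp(seed) + "A" * 18),   # planted target
    ("pyrG", "A" * 25 + revcomp(seed)[:13] + "A" * 12),
    ("unrelated", "CT" * 25),
]
srna2 = "G" * 20 + srna1[8:24] + "G" * 20  # shares the ftsX-pairing region
edges = list(predict_targets(srna1, windows, srna_id="sRNA-1"))
edges += predict_targets(srna2, windows, srna_id="sRNA-2")

net = build_network(edges)
for e in net.edges():
    print(f"{e.srna_id} -> {e.gene_id}: seed {e.seed_len} nt, score "
          f"{e.hybrid_score}, position {e.position_in_mrna} vs start codon")

stats = coregulation_stats(net)
print(f"\ntargets: {stats.n_targets}, co-regulated (>=2 sRNAs): "
      f"{stats.n_coregulated_ge2}, max in-degree {stats.max_in_degree} "
      f"at {stats.genes_at_max}")

tally = cog_tally(sorted(net.gene_in_degree),
                  {"ftsX": "D", "pyrG": "F"})
print(f"COG tally: {tally.counts} ({tally.n_with_cog}/{tally.n_total} labeled)")
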