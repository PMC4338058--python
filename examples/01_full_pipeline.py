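"""Run the whole discovery pipeline on a simulated genome.

Simulates a 50 kb circular genome with 11 planted intergenic sRNAs and 21
decoy IGRs, four stress-condition read sets, then runs IGR extraction,
signal scanning, quantification, sRNA calling, differential expression and
target prediction, and scores recovery against the planted truth.
"""

from srna_seeker import PipelineConfig, run_pipeline, score_recovery

cfg = PipelineConfig(outdir="example_run", seed=7)
res = run_pipeline(cfg)

print(f"IGRs extracted:        {len(res.igrs)}")
print(f"high-confidence sRNAs: {len(res.calls)}")
rec = score_recovery(res)
print(f"recovery vs planted truth: precision={rec['precision']:.2f} "
      f"recall={rec['recall']:.2f}")
print("\nsRNA catalogue (first rows):")
print((res.outdir / "srna_catalogue.tsv").read_text().split("\n", 4)[:4])
print("\nPer-condition fold changes of the called sRNAs are in "
      f"{res.outdir}/srna_fold_changes.tsv; a precision/recall of 1.0 means "
      "every planted sRNA was recovered and no decoy slipped through.")
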