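"""End-to-end orchestration: simulate/load -> IGRs -> signals -> quantify ->
call sRNAs -> differential expression -> target network.

Every stage writes its output under the run directory; ``manifest.json``
echoes the effective parameters and the seed so a run is reproducible
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .annotation_io import (
    AnnotatedGenome,
    ReadAlignment,
    read_alignments,
    read_annotation,
    read_genome,
    write_alignments,
    write_annotation,
    write_genome_fasta,
)
from .config import PipelineConfig
from .diffexpr import median_normalize, overlap_summary, select_degs
from .expression import ExpressionTable, quantify
from .igr_extraction import IGRecord, extract_igrs, igr_sequences, write_igr_gff
from .signal_finder import UnitCall, call_unit, scan_igr
from .srna_caller import (
    SrnaCall,
    attach_rpkms,
    call_srnas,
    fold_changes,
    merge_calls,
    render_catalogue,
    render_fold_changes,
)
from .synthetic_data import (
    GroundTruth,
    simulate_genome,
    simulate_reads,
    write_sample_fastq,
)
from .target_network import (
    RegulationNetwork,
    build_network,
    coregulation_stats,
    extract_start_windows,
    predict_targets,
)
from .annotation_io import revcomp

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    outdir: Path
    genome: AnnotatedGenome
    igrs: list[IGRecord]
    unit_calls: dict[str, UnitCall]
    expr: ExpressionTable
    expr_norm: ExpressionTable
    calls: list[SrnaCall]
    per_sample_calls: dict[str, list[SrnaCall]]
    fold_rows: list
    degs: dict[str, pd.DataFrame]
    overlaps: Optional[pd.DataFrame]
    network: RegulationNetwork
    truth: Optional[GroundTruth] = None
    signals: pd.DataFrame = field(default_factory=pd.DataFrame)


def _signals_frame(per_igr: dict[str, tuple[list, list]]) -> pd.DataFrame:
    rows = []
    for igr_id, (promoters, terminators) in per_igr.items():
        for sig in promoters + terminators:
            rows.append(
                {
                    "igr_id": igr_id,
                    "kind": sig.kind,
                    "strand": sig.strand,
                    "position": sig.position,
                    "score": round(sig.score, 4),
                }
            )
    return pd.DataFrame(rows, columns=["igr_id", "kind", "strand", "position", "score"])


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth: Optional[GroundTruth] = None
    if config.simulate:
        sim = config.sim
        sim.seed = config.seed
        genome, truth = simulate_genome(sim)
        reads_by_sample = simulate_reads(genome, truth, sim)
        write_genome_fasta(genome, outdir / "genome.fa")
        write_annotation(genome, outdir / "genes.gff3")
        truth.to_json(outdir / "truth.json")
        for sample, reads in reads_by_sample.items():
            write_alignments(reads, genome.genome_id, outdir / f"{sample}.bed")
            if config.emit_fastq:
                write_sample_fastq(genome, reads, outdir / f"{sample}.fastq", sim)
    else:
        genome = read_genome(config.genome_fasta)
        read_annotation(config.annotation_gff, genome)
        reads_by_sample = {
            sample: read_alignments(path, sample)
            for sample, path in config.samples.items()
        }

    # --- IGR extraction -------------------------------------------------- #
    igrs = extract_igrs(genome, trim=config.trim, min_len=config.min_len)
    write_igr_gff(genome, igrs, outdir / "igrs.gff3")
    (outdir / "igrs.fa").write_text(igr_sequences(genome, igrs))

    # --- transcription signals ------------------------------------------- #
    per_igr_signals: dict[str, tuple[list, list]] = {}
    unit_calls: dict[str, UnitCall] = {}
    for igr in igrs:
        seq = genome.fetch(igr.start, igr.end)
        promoters, terminators = scan_igr(
            seq,
            promoter_threshold=config.promoter_threshold,
            terminator_params=config.terminator,
        )
        per_igr_signals[igr.igr_id] = (promoters, terminators)
        unit_calls[igr.igr_id] = call_unit(igr, promoters, terminators)
    signals = _signals_frame(per_igr_signals)
    signals.to_csv(outdir / "signals.tsv", sep="\t", index=False)

    # --- quantification --------------------------------------------------- #
    all_reads: list[ReadAlignment] = []
    for sample in sorted(reads_by_sample):
        all_reads.extend(reads_by_sample[sample])
    features = [f for f in genome.features if f.kind == "CDS"] + list(igrs)
    expr = quantify(all_reads, features)
    expr.to_tsv(outdir / "expression.tsv")

    # --- sRNA calling ------------------------------------------------------ #
    per_sample_calls = {
        sample: call_srnas(igrs, unit_calls, expr, sample, margin=config.margin)
        for sample in sorted(reads_by_sample)
    }
    calls = merge_calls(per_sample_calls)

    # --- normalization, fold changes, differential expression ------------- #
    expr_norm = median_normalize(expr)
    expr_norm.to_tsv(outdir / "expression_normalized.tsv")
    attach_rpkms(calls, expr_norm)
    conditions = [s for s in sorted(reads_by_sample) if s != config.control]
    fold_rows = fold_changes(calls, expr_norm, config.control, conditions)
    (outdir / "srna_catalogue.tsv").write_text(render_catalogue(calls))
    (outdir / "srna_fold_changes.tsv").write_text(render_fold_changes(fold_rows))

    degs = {
        cond: select_degs(
            expr_norm, config.control, cond,
            lfc_cutoff=config.log2fc_cutoff, p_cutoff=config.p_cutoff,
        )
        for cond in conditions
    }
    if degs:
        pd.concat(degs.values()).to_csv(outdir / "degs.tsv", sep="\t", index=False)
    overlaps = overlap_summary(degs) if len(degs) >= 2 else None
    if overlaps is not None:
        overlaps.to_csv(outdir / "deg_overlap.tsv", sep="\t", index=False)

    # --- target prediction and network ------------------------------------ #
    windows = extract_start_windows(genome)
    edges = []
    for call in calls:
        lo, hi = min(call.start, call.end), max(call.start, call.end)
        transcript = genome.fetch(lo, hi)
        if call.strand == "-":
            transcript = revcomp(transcript)
        edges.extend(
            predict_targets(
                transcript, windows,
                seed_min=config.target_seed_min,
                score_min=config.target_score_min,
                srna_id=call.srna_id,
            )
        )
    network = build_network(edges)
    network.to_edgelist_tsv(outdir / "targets.tsv")
    network.write_graphml(outdir / "network.graphml")
    stats = coregulation_stats(network)
    (outdir / "network_stats.json").write_text(
        json.dumps(
            {
                "n_targets": stats.n_targets,
                "n_coregulated_ge2": stats.n_coregulated_ge2,
                "max_in_degree": stats.max_in_degree,
                "genes_at_max": stats.genes_at_max,
            },
            indent=1,
        )
    )

    manifest = {
        "package": "srna-seeker",
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "n_igrs": len(igrs),
        "n_srnas": len(calls),
        "samples": sorted(reads_by_sample),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    return PipelineResult(
        outdir=outdir,
        genome=genome,
        igrs=igrs,
        unit_calls=unit_calls,
        expr=expr,
        expr_norm=expr_norm,
        calls=calls,
        per_sample_calls=per_sample_calls,
        fold_rows=fold_rows,
        degs=degs,
        overlaps=overlaps,
        network=network,
        truth=truth,
        signals=signals,
    )


def score_recovery(result: PipelineResult) -> dict[str, float]:
    """Precision/recall of the called sRNAs against planted truth.

    Matching is by exact trimmed-interval identity.  Only meaningful on
    simulated runs.
    """
    if result.truth is None:
        raise ValueError("recovery scoring needs a simulated run with ground truth")
    igr_to_key = result.truth.match_igrs(result.igrs)
    planted_keys = {p.key for p in result.truth.planted}
    called_ids = {c.srna_id for c in result.calls}
    called_keys = {igr_to_key.get(i) for i in called_ids}
    tp = len(called_keys & planted_keys)
    fp = len(called_ids) - tp
    fn = len(planted_keys) - tp
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall}
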