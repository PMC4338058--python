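"""Seeded synthetic genomes and stress-condition read sets.

The generator emulates the study design every downstream stage assumes: a
small circular bacterial genome (default 50 kb, GC 0.60) with ~45 CDS genes
and a few tRNA/rRNA features, 11 planted intergenic sRNAs (each carrying a
consensus sigma-70 promoter and a strong intrinsic terminator inside its
IGR, expressed well above both flanking genes), a panel of decoy IGRs each
violating exactly one calling rule (no promoter / no terminator / low
expression), and four condition libraries (control, acid, bile, simulated
GIT) with negative-binomial count noise and configurable fold changes.
Planted sRNA fold changes default to the published 11 x 3 stress matrix so
the expression analysis has a known truth to recover.

Reads are emitted as already-aligned 50 nt intervals (BED) — alignment is
out of scope — at distinct (position, strand) slots per feature, with an
exact-duplicate fraction layered on top to emulate PCR duplication; the
deduplication stage therefore recovers exactly the drawn counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import datasets
from .annotation_io import AnnotatedGenome, GeneFeature, ReadAlignment, revcomp
from .igr_extraction import IGRecord

log = logging.getLogger(__name__)

DEFAULT_CONDITIONS = ("control", "acid", "bile", "git")

PROMOTER_CONSENSUS_35 = "TTGACA"
PROMOTER_CONSENSUS_10 = "TATAAT"
CONSENSUS_SPACER = 17

READ_LEN = 50

DECOY_CLASSES = ("no_promoter", "no_terminator", "low_expression")


@dataclass
class SimConfig:
    seed: int = 0
    genome_len: int = 50_000
    gc: float = 0.60
    n_genes: int = 45
    n_planted_srnas: int = 11
    n_decoy_igrs: int = 21
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    # Depth is bounded by the distinct-(position, strand) capacity of the
    # features: reads occupy distinct 50 nt slots (PCR duplicates are layered
    # on separately), so per-feature counts — including the largest planted
    # fold change — must stay below 2 * (length - 49).  7,000 reads/sample
    # on this genome keeps every feature comfortably below capacity.
    reads_per_sample: int = 7_000
    nb_dispersion: float = 25.0  # NB size parameter; CV^2 = 1/mean + 1/size
    duplicate_fraction: float = 0.2
    fastq_fail_fraction: float = 0.1
    fold_change_map: Optional[dict] = None  # {(feature_key, condition): fold}

    def __post_init__(self) -> None:
        if self.n_genes < self.n_planted_srnas + self.n_decoy_igrs + 4:
            raise ValueError("too few genes to host the requested IGR slots")


@dataclass
class PlantedFeature:
    key: str
    start: int  # trimmed IGR interval, genome coordinates
    end: int
    strand: str
    kind: str  # "srna" or a decoy class


@dataclass
class GroundTruth:
    """Everything the tests need to score pipeline output."""

    planted: list[PlantedFeature] = field(default_factory=list)
    decoys: list[PlantedFeature] = field(default_factory=list)
    base_rpkm: dict[str, float] = field(default_factory=dict)
    fold_change_map: dict = field(default_factory=dict)  # (key, condition) -> fold
    srna_published_row: dict[str, str] = field(default_factory=dict)
    deg_truth: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    planted_target_edges: list[tuple[str, str]] = field(default_factory=list)

    def interval_index(self) -> dict[tuple[int, int], str]:
        return {(p.start, p.end): p.key for p in self.planted + self.decoys}

    def match_igrs(self, igrs: Sequence[IGRecord]) -> dict[str, str]:
        """Map extracted IGR ids to truth keys by exact trimmed interval."""
        index = self.interval_index()
        return {
            igr.igr_id: index[(igr.start, igr.end)]
            for igr in igrs
            if (igr.start, igr.end) in index
        }

    def expected_mean(self, key: str, condition: str) -> float:
        return self.base_rpkm.get(key, 0.0) * self.fold_change_map.get(
            (key, condition), 1.0
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": [asdict(p) for p in self.planted],
            "decoys": [asdict(p) for p in self.decoys],
            "base_rpkm": self.base_rpkm,
            "fold_change_map": {
                f"{k}::{c}": v for (k, c), v in self.fold_change_map.items()
            },
            "srna_published_row": self.srna_published_row,
            "deg_truth": self.deg_truth,
            "planted_target_edges": self.planted_target_edges,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _promoter_block(rng: np.random.Generator, gc: float) -> str:
    spacer = _random_seq(rng, CONSENSUS_SPACER, gc)
    return PROMOTER_CONSENSUS_35 + spacer + PROMOTER_CONSENSUS_10


def _terminator_block(rng: np.random.Generator) -> str:
    stem = "".join(rng.choice(list("GC"), size=8))
    return stem + "GAAA" + revcomp(stem) + "T" * 8


def _cassette(
    rng: np.random.Generator,
    trimmed_len: int,
    gc: float,
    with_promoter: bool,
    with_terminator: bool,
) -> str:
    """Sequence of one trimmed IGR, promoter upstream of terminator ('+')."""
    prom = _promoter_block(rng, gc) if with_promoter else _random_seq(rng, 29, gc)
    term = _terminator_block(rng) if with_terminator else _random_seq(rng, 28, gc)
    body = _random_seq(rng, 60, gc)
    head = _random_seq(rng, 5, gc)
    core = head + prom + body + term
    if len(core) > trimmed_len:
        raise ValueError("trimmed IGR too short for the signal cassette")
    return core + _random_seq(rng, trimmed_len - len(core), gc)


def simulate_genome(cfg: SimConfig) -> tuple[AnnotatedGenome, GroundTruth]:
    """Build the genome, its annotation and the planted ground truth.

    Deterministic for a fixed config: re-running reproduces the genome
    byte-for-byte.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n_special = cfg.n_planted_srnas + cfg.n_decoy_igrs + 1  # +1 tRNA-exclusion gap
    if n_special > cfg.n_genes - 4:
        raise ValueError(
            "not enough inter-gene gaps for the requested sRNAs and decoys; "
            "increase n_genes / genome_len"
        )

    gene_lens = rng.integers(540, 640, size=cfg.n_genes)
    gene_strands = rng.choice(["+", "-"], size=cfg.n_genes, p=[0.6, 0.4])

    # gap i sits between gene i and gene i+1; specials occupy a consecutive
    # run starting at gap 2 so that genes 0..1 and the tail genes stay free
    # of special flanks (those free genes host the planted DEGs).
    special_gaps = list(range(2, 2 + n_special))
    trim = 40

    # decide gap raw lengths
    gap_raw: dict[int, int] = {}
    for g in range(cfg.n_genes - 1):
        if g in special_gaps:
            gap_raw[g] = int(rng.integers(560, 620))
        else:
            gap_raw[g] = int(rng.integers(60, 100))  # trimmed < 120 -> dropped

    # classes per special gap, in order: sRNAs, then decoys cycling classes,
    # then the tRNA-exclusion gap
    slot_plan: list[tuple[str, str]] = []  # (kind, key)
    for i in range(cfg.n_planted_srnas):
        slot_plan.append(("srna", f"srna-{i + 1:02d}"))
    for i in range(cfg.n_decoy_igrs):
        cls = DECOY_CLASSES[i % len(DECOY_CLASSES)]
        slot_plan.append((cls, f"decoy-{cls}-{i + 1:02d}"))
    slot_plan.append(("trna_exclusion", "trna-gap"))
    slot_by_gap = dict(zip(special_gaps, slot_plan))

    srna_strands = {
        f"srna-{i + 1:02d}": ("-" if i in (5, 6) else "+")
        for i in range(cfg.n_planted_srnas)
    }

    truth = GroundTruth()
    features: list[GeneFeature] = []
    parts: list[str] = []
    cursor = 0

    def append(seq: str) -> int:
        nonlocal cursor
        parts.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    append(_random_seq(rng, 25, cfg.gc))  # pad so the wrap gap stays tiny

    gene_ids = [f"gene-{i + 1:03d}" for i in range(cfg.n_genes)]
    for i in range(cfg.n_genes):
        start = append(_random_seq(rng, int(gene_lens[i]), cfg.gc))
        features.append(
            GeneFeature(
                feature_id=gene_ids[i],
                kind="CDS",
                start=start,
                end=cursor,
                strand=str(gene_strands[i]),
                product=f"synthetic protein {i + 1}",
            )
        )
        if i == cfg.n_genes - 1:
            break
        raw = gap_raw[i]
        gap_start = cursor
        slot = slot_by_gap.get(i)
        if slot is None:
            append(_random_seq(rng, raw, cfg.gc))
            continue
        kind, key = slot
        trimmed_len = raw - 2 * trim
        if kind == "trna_exclusion":
            # a tRNA inside the would-be IGR: extraction must drop it
            append(_random_seq(rng, 100, cfg.gc))
            t_start = append(_random_seq(rng, 75, cfg.gc))
            features.append(
                GeneFeature(f"trna-x", "tRNA", t_start, cursor, "+", "tRNA (planted)")
            )
            append(_random_seq(rng, raw - 175, cfg.gc))
            continue
        strand = srna_strands.get(key, "+")
        cas = _cassette(
            rng,
            trimmed_len,
            cfg.gc,
            with_promoter=kind in ("srna", "no_terminator", "low_expression"),
            with_terminator=kind in ("srna", "no_promoter", "low_expression"),
        )
        if strand == "-":
            cas = revcomp(cas)
        append(_random_seq(rng, trim, cfg.gc))
        append(cas)
        append(_random_seq(rng, trim, cfg.gc))
        planted = PlantedFeature(
            key=key,
            start=gap_start + trim,
            end=gap_start + raw - trim,
            strand=strand,
            kind="srna" if kind == "srna" else kind,
        )
        (truth.planted if kind == "srna" else truth.decoys).append(planted)

    # two structured-RNA features in free tail gaps (exclusion-rule fodder)
    t_start = append(_random_seq(rng, 75, cfg.gc))
    features.append(GeneFeature("trna-1", "tRNA", t_start, cursor, "+", "tRNA"))
    append(_random_seq(rng, 90, cfg.gc))
    r_start = append(_random_seq(rng, 300, cfg.gc))
    features.append(GeneFeature("rrna-1", "rRNA", r_start, cursor, "+", "5S rRNA"))

    if cursor > cfg.genome_len - 30:
        raise ValueError(
            f"genome content ({cursor} bp) exceeds genome_len {cfg.genome_len}; "
            "increase genome_len"
        )
    append(_random_seq(rng, cfg.genome_len - cursor, cfg.gc))

    sequence = "".join(parts)
    genome = AnnotatedGenome(
        genome_id=f"synthetic-{cfg.seed}",
        sequence=sequence,
        is_circular=True,
        features=sorted(features, key=lambda f: f.start),
    )
    genome.validate()

    # ------------------------------------------------------------------ #
    # expression truth
    gene_base = {g: float(rng.uniform(40, 60)) for g in gene_ids}
    truth.base_rpkm.update(gene_base)

    def flank_bases(p: PlantedFeature) -> tuple[float, float]:
        lefts = [f for f in features if f.kind == "CDS" and f.end <= p.start]
        rights = [f for f in features if f.kind == "CDS" and f.start >= p.end]
        left = max(lefts, key=lambda f: f.end)
        right = min(rights, key=lambda f: f.start)
        return gene_base[left.feature_id], gene_base[right.feature_id]

    for p in truth.planted:
        truth.base_rpkm[p.key] = 2.0 * max(flank_bases(p))
    for p in truth.decoys:
        l, r = flank_bases(p)
        if p.kind == "low_expression":
            truth.base_rpkm[p.key] = 0.25 * min(l, r)
        else:
            truth.base_rpkm[p.key] = 1.6 * max(l, r)

    # fold changes: planted sRNAs echo the published stress matrix
    fold_map: dict = {}
    published = datasets.load_published_fold_changes()
    pub_ids = list(published.index)
    for i, p in enumerate(truth.planted):
        row = pub_ids[i % len(pub_ids)]
        truth.srna_published_row[p.key] = row
        for cond in cfg.conditions:
            if cond in published.columns:
                fold_map[(p.key, cond)] = float(published.loc[row, cond])

    # planted DEGs among genes that flank no special gap
    free_genes = gene_ids[:2] + gene_ids[2 + n_special + 1 :]
    deg_pool = list(free_genes)
    non_control = [c for c in cfg.conditions if c != "control"]
    truth.deg_truth = {c: {"up": [], "down": []} for c in non_control}
    if len(deg_pool) >= 10 and non_control:
        up_genes, down_genes = deg_pool[:5], deg_pool[5:10]
        for ci, cond in enumerate(non_control):
            # staggered membership so condition DEG sets overlap but differ
            ups = up_genes[: 3 + (ci % 3)]
            downs = down_genes[: 3 + ((ci + 1) % 3)]
            for g in ups:
                fold_map[(g, cond)] = 4.0
            for g in downs:
                fold_map[(g, cond)] = 0.25
            truth.deg_truth[cond]["up"] = list(ups)
            truth.deg_truth[cond]["down"] = list(downs)

    if cfg.fold_change_map:
        fold_map.update(cfg.fold_change_map)
    truth.fold_change_map = fold_map

    _plant_target_seeds(genome, truth, rng)
    return genome, truth


def _plant_target_seeds(genome: AnnotatedGenome, truth: GroundTruth,
                        rng: np.random.Generator) -> None:
    """Embed exact antisense seeds of two planted sRNAs into gene start
    windows (plus-strand genes only), including one shared target."""
    if len(truth.planted) < 2:
        return
    plus_genes = [f for f in genome.features
                  if f.kind == "CDS" and f.strand == "+" and f.start > 60]
    if len(plus_genes) < 5:
        return
    seq = list(genome.sequence)
    chosen = {truth.planted[0].key: plus_genes[:3],
              truth.planted[1].key: plus_genes[2:5]}  # gene #3 shared
    # distinct in-window offsets per sRNA so the shared gene keeps both seeds:
    # +6 sits just inside the CDS; -28 sits in the 40 bp trim margin upstream,
    # outside any trimmed IGR.
    offsets = {truth.planted[0].key: 6, truth.planted[1].key: -28}
    for srna_key, genes in chosen.items():
        p = next(x for x in truth.planted if x.key == srna_key)
        transcript = genome.sequence[p.start : p.end]
        if p.strand == "-":
            transcript = revcomp(transcript)
        # 12-mer from the cassette body (after the 34 nt head+promoter)
        seed = transcript[40:52]
        anti = revcomp(seed)
        for gene in genes:
            pos = gene.start + offsets[srna_key]
            seq[pos : pos + len(anti)] = anti
            truth.planted_target_edges.append((srna_key, gene.feature_id))
    genome.sequence = "".join(seq)


def simulate_reads(
    genome: AnnotatedGenome,
    truth: GroundTruth,
    cfg: SimConfig,
) -> dict[str, list[ReadAlignment]]:
    """Per-condition aligned 50 nt reads with NB count noise.

    Per feature f and condition c the target count is negative-binomial with
    mean proportional to base_rpkm[f] * fold[f, c] * length[f], scaled so a
    sample totals ~``reads_per_sample`` reads.  Reads occupy distinct
    (start, strand) slots inside the feature; a ``duplicate_fraction`` of
    exact copies is appended afterwards.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    intervals: dict[str, tuple[int, int]] = {
        f.feature_id: (f.start, f.end)
        for f in genome.features
        if f.kind == "CDS"
    }
    for p in truth.planted + truth.decoys:
        intervals[p.key] = (p.start, p.end)

    samples: dict[str, list[ReadAlignment]] = {}
    for cond in cfg.conditions:
        weights = {
            key: truth.expected_mean(key, cond) * (iv[1] - iv[0])
            for key, iv in intervals.items()
        }
        total_w = sum(weights.values())
        reads: list[ReadAlignment] = []
        k = 0
        for key in sorted(intervals):
            start, end = intervals[key]
            mean = cfg.reads_per_sample * weights[key] / total_w
            if mean <= 0:
                continue
            size = cfg.nb_dispersion
            count = int(rng.negative_binomial(size, size / (size + mean)))
            if count == 0:
                continue
            capacity = 2 * max(end - start - READ_LEN + 1, 0)
            if capacity == 0:
                continue
            if count > capacity:
                log.warning("%s: count %d capped at slot capacity %d",
                            key, count, capacity)
                count = capacity
            slots = rng.choice(capacity, size=count, replace=False)
            for slot in np.sort(slots):
                pos = start + int(slot) // 2
                strand = "+" if slot % 2 == 0 else "-"
                reads.append(
                    ReadAlignment(
                        read_id=f"{cond}_r{k}",
                        start=pos,
                        end=pos + READ_LEN,
                        strand=strand,
                        sample_id=cond,
                    )
                )
                k += 1
        n_dup = int(round(cfg.duplicate_fraction * len(reads)))
        if n_dup:
            for i in rng.choice(len(reads), size=n_dup):
                src = reads[int(i)]
                reads.append(
                    ReadAlignment(
                        read_id=f"{cond}_dup{k}",
                        start=src.start,
                        end=src.end,
                        strand=src.strand,
                        sample_id=cond,
                    )
                )
                k += 1
        samples[cond] = reads
    return samples


def write_sample_fastq(
    genome: AnnotatedGenome,
    reads: Sequence[ReadAlignment],
    path: str | Path,
    cfg: SimConfig,
) -> None:
    """Optional raw-read FASTQ with a configurable QC-failing fraction.

    Failing reads get 40% of bases at Q10 (under the 80%-above-Q20 rule);
    a further small fraction gets Q2 ends to exercise end-trimming.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    with open(path, "w") as fh:
        for r in reads:
            seq = genome.fetch(r.start, r.end)
            if r.strand == "-":
                seq = revcomp(seq)
            u = rng.random()
            if u < cfg.fastq_fail_fraction:
                quals = ["+" if i % 5 < 2 else "D" for i in range(len(seq))]  # Q10/Q35
            elif u < cfg.fastq_fail_fraction + 0.05:
                quals = ["D"] * len(seq)
                quals[0] = quals[-1] = "#"  # Q2 ends, trimmed downstream
            else:
                quals = ["D"] * len(seq)
            fh.write(f"@{r.read_id}\n{seq}\n+\n{''.join(quals)}\n")
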