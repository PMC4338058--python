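"""sRNA target prediction and the sRNA -> target regulation network.

Targets are predicted by antisense seed complementarity: a maximal perfect
reverse-complement match of at least ``seed_min`` nt between the sRNA and
the translation-initiation window of an mRNA (30 nt upstream to 20 nt
downstream of the start codon, the canonical region where base-pairing
sRNAs occlude the ribosome binding site).  Each matched pair scores 2
(G:C) or 1 (A:T); one best edge is kept per (sRNA, gene).  Network-level
statistics (distinct targets, co-regulated genes, maximum in-degree) and
COG category tallies from supplied labels summarize the bipartite graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import networkx as nx
import numpy as np

from .annotation_io import AnnotatedGenome, revcomp

log = logging.getLogger(__name__)

DEFAULT_SEED_MIN = 8
DEFAULT_SCORE_MIN = 10.0
WINDOW_UPSTREAM = 30
WINDOW_DOWNSTREAM = 20

#: One-letter functional categories recognized for COG tallies.
COG_LETTERS = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


@dataclass(frozen=True)
class TargetEdge:
    srna_id: str
    gene_id: str
    seed_start_in_srna: int
    seed_len: int
    hybrid_score: float
    position_in_mrna: int  # offset of the seed start relative to the start codon


@dataclass
class RegulationNetwork:
    """Bipartite sRNA -> gene graph with degree maps."""

    graph: nx.DiGraph
    srna_degree: dict[str, int] = field(default_factory=dict)
    gene_in_degree: dict[str, int] = field(default_factory=dict)

    def edges(self) -> list[TargetEdge]:
        return [d["edge"] for _, _, d in self.graph.edges(data=True)]

    def to_edgelist_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("srna_id\tgene_id\tscore\tseed_len\tposition\n")
            for e in sorted(self.edges(), key=lambda e: (e.srna_id, e.gene_id)):
                fh.write(
                    f"{e.srna_id}\t{e.gene_id}\t{e.hybrid_score}\t"
                    f"{e.seed_len}\t{e.position_in_mrna}\n"
                )

    def write_graphml(self, path: str | Path) -> None:
        g = nx.DiGraph()
        for node, data in self.graph.nodes(data=True):
            g.add_node(node, kind=data.get("kind", ""))
        for u, v, d in self.graph.edges(data=True):
            e: TargetEdge = d["edge"]
            g.add_edge(u, v, score=e.hybrid_score, seed_len=e.seed_len,
                       position=e.position_in_mrna)
        nx.write_graphml(g, str(path))


class CoregulationStats(NamedTuple):
    n_targets: int
    n_coregulated_ge2: int
    max_in_degree: int
    genes_at_max: list[str]


@dataclass
class CogTally:
    counts: dict[str, int]
    n_with_cog: int
    n_total: int


def extract_start_windows(
    genome: AnnotatedGenome,
    upstream: int = WINDOW_UPSTREAM,
    downstream: int = WINDOW_DOWNSTREAM,
) -> list[tuple[str, str]]:
    """Translation-initiation windows (mRNA sense) for every CDS feature."""
    L = genome.length
    windows = []
    for f in genome.features:
        if f.kind != "CDS":
            continue
        if f.strand == "+":
            lo, hi = f.start - upstream, f.start + downstream
            if lo < 0:
                lo = lo + L if genome.is_circular else 0
                seq = genome.fetch(lo, lo + upstream + downstream)
            else:
                seq = genome.fetch(lo, hi)
        else:
            lo, hi = f.end - downstream, f.end + upstream
            if hi > L and not genome.is_circular:
                hi = L
            seq = revcomp(genome.fetch(max(lo, 0), hi))
        windows.append((f.feature_id, seq))
    return windows


def _base_scores(segment: str) -> float:
    return float(sum(2.0 if b in "GC" else 1.0 for b in segment))


def predict_targets(
    srna_seq: str,
    mrna_windows: Sequence[tuple[str, str]],
    seed_min: int = DEFAULT_SEED_MIN,
    score_min: float = DEFAULT_SCORE_MIN,
    srna_id: str = "sRNA",
) -> list[TargetEdge]:
    """Seed-complementarity target prediction for one sRNA.

    Finds maximal perfect matches between the sRNA and the reverse
    complement of each window (equivalently, perfect sRNA:mRNA antisense
    duplexes), keeps those of length >= ``seed_min`` and score >=
    ``score_min``, and reports the best edge per gene (highest score, ties
    to the longest then leftmost seed).
    """
    srna = srna_seq.upper().replace("U", "T")
    n = len(srna)
    edges: list[TargetEdge] = []
    sa = np.frombuffer(srna.encode(), dtype=np.uint8)
    for gene_id, window in mrna_windows:
        window = window.upper().replace("U", "T")
        m = len(window)
        if m < seed_min:
            log.warning("%s: window shorter than seed_min, skipped", gene_id)
            continue
        rc = revcomp(window)
        rb = np.frombuffer(rc.encode(), dtype=np.uint8)
        eq = sa[:, None] == rb[None, :]
        best: Optional[TargetEdge] = None
        # walk diagonals of the match matrix for maximal runs
        for d in range(-(n - 1), m):
            diag = np.diagonal(eq, offset=d)
            if diag.size < seed_min or not diag.any():
                continue
            run = 0
            for t in range(diag.size + 1):
                if t < diag.size and diag[t]:
                    run += 1
                    continue
                if run >= seed_min:
                    # srna index range of this run
                    i_end = t - 1 + max(-d, 0) if d < 0 else t - 1
                    i_start = i_end - run + 1
                    j_start = i_start + d
                    seg = srna[i_start : i_start + run]
                    score = _base_scores(seg)
                    if score >= score_min:
                        # rc-window coords -> window coords -> start-codon offset
                        win_start = m - (j_start + run)
                        edge = TargetEdge(
                            srna_id=srna_id,
                            gene_id=gene_id,
                            seed_start_in_srna=i_start,
                            seed_len=run,
                            hybrid_score=score,
                            position_in_mrna=win_start - WINDOW_UPSTREAM,
                        )
                        if best is None or (edge.hybrid_score, edge.seed_len,
                                            -edge.seed_start_in_srna) > (
                                best.hybrid_score, best.seed_len,
                                -best.seed_start_in_srna):
                            best = edge
                run = 0
        if best is not None:
            edges.append(best)
    return edges


def build_network(edges: Iterable[TargetEdge]) -> RegulationNetwork:
    """Assemble the bipartite regulation graph and its degree maps."""
    g = nx.DiGraph()
    for e in edges:
        g.add_node(e.srna_id, kind="srna")
        g.add_node(e.gene_id, kind="gene")
        g.add_edge(e.srna_id, e.gene_id, edge=e)
    srna_degree = {
        n: g.out_degree(n) for n, d in g.nodes(data=True) if d["kind"] == "srna"
    }
    gene_in_degree = {
        n: g.in_degree(n) for n, d in g.nodes(data=True) if d["kind"] == "gene"
    }
    return RegulationNetwork(graph=g, srna_degree=srna_degree,
                             gene_in_degree=gene_in_degree)


def coregulation_stats(network: RegulationNetwork) -> CoregulationStats:
    """Distinct targets, co-regulated (in-degree >= 2) genes, max in-degree."""
    degs = network.gene_in_degree
    if not degs:
        return CoregulationStats(0, 0, 0, [])
    max_deg = max(degs.values())
    return CoregulationStats(
        n_targets=len(degs),
        n_coregulated_ge2=sum(1 for d in degs.values() if d >= 2),
        max_in_degree=max_deg,
        genes_at_max=sorted(g for g, d in degs.items() if d == max_deg),
    )


def cog_tally(
    targets: Iterable[str],
    cog_labels: Mapping[str, str],
) -> CogTally:
    """Per-category counts of target genes carrying COG letters.

    ``cog_labels`` maps gene id -> one or more category letters (a gene may
    carry several).  Unknown letters are warned about and bucketed under
    'other'.
    """
    counts: dict[str, int] = {}
    n_with = 0
    targets = list(targets)
    for gene in targets:
        letters = cog_labels.get(gene, "")
        if not letters:
            continue
        n_with += 1
        for letter in letters:
            if letter not in COG_LETTERS:
                log.warning("unknown COG category %r for %s", letter, gene)
                letter = "other"
            counts[letter] = counts.get(letter, 0) + 1
    return CogTally(counts=counts, n_with_cog=n_with, n_total=len(targets))


def read_cog_labels(path: str | Path) -> dict[str, str]:
    """TSV of gene_id<TAB>letters -> mapping."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, letters = line.split("\t")[:2]
            labels[gene] = letters
    return labels
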