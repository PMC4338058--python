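"""Candidate intergenic region (IGR) extraction.

The rule set: take the gaps between annotated protein-coding features
(both strands pooled), delete 40 bp from each side of every gap (to strip
promoters/UTRs/terminators belonging to the flanking ORFs), keep trimmed
intervals of at least 120 bp, drop any that overlap a tRNA or rRNA feature,
and drop duplicates.  On a circular genome the gap spanning the origin is a
single IGR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .annotation_io import AnnotatedGenome, GeneFeature

log = logging.getLogger(__name__)

DEFAULT_TRIM = 40
DEFAULT_MIN_LEN = 120

#: Feature kinds that bound gaps (tRNA/rRNA participate only in the
#: exclusion scan, mirroring an ORF-derived IGR definition).
_OCCUPYING_KINDS = ("CDS", "other")
_EXCLUDED_KINDS = ("tRNA", "rRNA")


@dataclass
class IGRecord:
    """A trimmed intergenic interval with its flanking genes.

    ``raw_start``/``raw_end`` bound the untrimmed gap; ``start``/``end`` the
    trimmed interval.  On a circular genome the origin-spanning record has
    ``end > genome length`` (coordinates continue past the origin).
    """

    igr_id: str
    raw_start: int
    raw_end: int
    start: int
    end: int
    upstream_gene: Optional[GeneFeature]
    downstream_gene: Optional[GeneFeature]
    wraps: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def flank_strands(self) -> tuple[Optional[str], Optional[str]]:
        return (
            self.upstream_gene.strand if self.upstream_gene else None,
            self.downstream_gene.strand if self.downstream_gene else None,
        )

    @property
    def has_both_flanks(self) -> bool:
        return self.upstream_gene is not None and self.downstream_gene is not None


def _merge_blocks(features: list[GeneFeature]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping features into occupied blocks."""
    blocks: list[tuple[int, int]] = []
    for f in sorted(features, key=lambda f: (f.start, f.end)):
        if blocks and f.start <= blocks[-1][1]:
            blocks[-1] = (blocks[-1][0], max(blocks[-1][1], f.end))
        else:
            blocks.append((f.start, f.end))
    return blocks


def _overlaps_mod(start: int, end: int, f: GeneFeature, genome_len: int) -> bool:
    """Does [start, end) (possibly extending past the origin) overlap f?"""
    for s, e in ((start, end), (start - genome_len, end - genome_len)):
        if s < f.end and e > f.start:
            return True
    return False


def extract_igrs(
    genome: AnnotatedGenome,
    trim: int = DEFAULT_TRIM,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[IGRecord]:
    """Extract candidate IGRs from the annotation.

    Returns records numbered ``IGR-1``, ``IGR-2``, ... in genome order.
    Linear-genome edge gaps (missing one flank) are retained but flagged via
    ``has_both_flanks``; downstream sRNA calling excludes them.
    """
    occupying = [f for f in genome.sorted_features() if f.kind in _OCCUPYING_KINDS]
    excluded = [f for f in genome.features if f.kind in _EXCLUDED_KINDS]
    if not occupying:
        log.warning("genome %s has no gene features; no IGRs", genome.genome_id)
        return []

    blocks = _merge_blocks(occupying)
    L = genome.length

    def left_flank(pos: int) -> Optional[GeneFeature]:
        cands = [f for f in occupying if f.end <= pos]
        return max(cands, key=lambda f: f.end) if cands else None

    def right_flank(pos: int) -> Optional[GeneFeature]:
        cands = [f for f in occupying if f.start >= pos]
        return min(cands, key=lambda f: f.start) if cands else None

    gaps: list[tuple[int, int, bool]] = []  # (raw_start, raw_end, wraps)
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        if s2 > e1:
            gaps.append((e1, s2, False))
    if genome.is_circular:
        wrap_start, wrap_end = blocks[-1][1], blocks[0][0] + L
        if wrap_end > wrap_start:
            gaps.append((wrap_start, wrap_end, True))
    else:
        if blocks[0][0] > 0:
            gaps.insert(0, (0, blocks[0][0], False))
        if blocks[-1][1] < L:
            gaps.append((blocks[-1][1], L, False))

    records: list[IGRecord] = []
    seen: set[tuple[int, int]] = set()
    for raw_start, raw_end, wraps in gaps:
        start, end = raw_start + trim, raw_end - trim
        if end - start < min_len:
            continue
        if any(_overlaps_mod(start, end, f, L) for f in excluded):
            continue
        key = (start % L, end if not wraps else end - L)
        if key in seen:
            continue
        seen.add(key)
        if wraps:
            up = occupying[-1] if occupying else None
            down = occupying[0] if occupying else None
        else:
            up, down = left_flank(raw_start), right_flank(raw_end)
            if genome.is_circular:
                up = up or (occupying[-1] if occupying else None)
                down = down or (occupying[0] if occupying else None)
        records.append(
            IGRecord(
                igr_id="",  # assigned after sorting
                raw_start=raw_start,
                raw_end=raw_end,
                start=start,
                end=end,
                upstream_gene=up,
                downstream_gene=down,
                wraps=wraps,
            )
        )

    records.sort(key=lambda r: (r.start % L, r.end))
    for k, rec in enumerate(records, start=1):
        rec.igr_id = f"IGR-{k}"
    return records


def igr_sequences(genome: AnnotatedGenome, igrs: list[IGRecord]) -> str:
    """Forward-strand FASTA of the trimmed IGR intervals.

    Headers carry 1-based inclusive coordinates, e.g. ``>IGR-3 541-860``.
    """
    chunks: list[str] = []
    for igr in igrs:
        seq = genome.fetch(igr.start, igr.end)
        chunks.append(f">{igr.igr_id} {igr.start + 1}-{igr.end}")
        for i in range(0, len(seq), 70):
            chunks.append(seq[i : i + 70])
    return "\n".join(chunks) + ("\n" if chunks else "")


def write_igr_gff(genome: AnnotatedGenome, igrs: list[IGRecord],
                  gff_path) -> None:
    """GFF3 of trimmed IGR intervals (1-based inclusive out)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for igr in igrs:
            fh.write(
                "\t".join(
                    [
                        genome.genome_id, "srna_seeker", "intergenic_region",
                        str(igr.start + 1), str(igr.end), ".", ".", ".",
                        f"ID={igr.igr_id};raw_start={igr.raw_start + 1};"
                        f"raw_end={igr.raw_end}",
                    ]
                )
                + "\n"
            )
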