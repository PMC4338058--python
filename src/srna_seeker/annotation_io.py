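"""Genome / annotation / alignment I-O and the internal coordinate convention.

All coordinates inside the package are 0-based half-open ``[start, end)``.
GFF3 (1-based inclusive) and BED6 (already 0-based half-open) are converted
at the boundary, never inside the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

log = logging.getLogger(__name__)

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "other")

#: GFF3 types that describe the replicon itself, not genes.
_NON_GENE_TYPES = {"region", "chromosome", "contig", "source", "sequence_assembly"}

_IUPAC = set("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed input files."""


class CoordinateError(ValueError):
    """Raised when a feature or alignment falls outside the genome."""


@dataclass(frozen=True)
class GeneFeature:
    """A single annotated feature on the replicon.

    ``kind`` is one of CDS / tRNA / rRNA / other; ``start``/``end`` follow the
    internal 0-based half-open convention.
    """

    feature_id: str
    kind: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"feature {self.feature_id}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """A single (by default circular) bacterial replicon plus its features."""

    genome_id: str
    sequence: str
    is_circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def sorted_features(self) -> list[GeneFeature]:
        return sorted(self.features, key=lambda f: (f.start, f.end))

    def validate(self) -> None:
        for f in self.features:
            if f.end > self.length:
                raise CoordinateError(
                    f"feature {f.feature_id} [{f.start}, {f.end}) exceeds genome "
                    f"length {self.length}"
                )

    def fetch(self, start: int, end: int) -> str:
        """Forward-strand sequence of ``[start, end)``; ``end`` may wrap past
        the origin on a circular genome (``end > length``)."""
        if end <= self.length:
            return self.sequence[start:end]
        if not self.is_circular:
            raise CoordinateError(f"interval [{start}, {end}) exceeds linear genome")
        return self.sequence[start:] + self.sequence[: end - self.length]


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned read as a genomic interval."""

    read_id: str
    start: int
    end: int
    strand: str
    sample_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CoordinateError(
                f"read {self.read_id}: end {self.end} <= start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeSummary:
    length_bp: int
    gc_fraction: float
    n_genes: int
    n_trna: int
    n_rrna: int
    coding_fraction: float


def read_genome(fasta_path: str | Path) -> AnnotatedGenome:
    """Load the first record of a FASTA file as an AnnotatedGenome.

    The sequence is upper-cased and RNA U is converted to T.  Multi-record
    files are accepted with a warning; only the first record is used.
    """
    path = Path(fasta_path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if len(records) > 1:
        log.warning(
            "%s: %d records found, using the first (%s)",
            path, len(records), records[0].id,
        )
    rec = records[0]
    seq = str(rec.seq).upper().replace("U", "T")
    bad = set(seq) - _IUPAC
    if bad:
        raise FormatError(f"{path}: non-nucleotide characters {sorted(bad)}")
    return AnnotatedGenome(genome_id=rec.id, sequence=seq)


def read_annotation(gff_path: str | Path, genome: AnnotatedGenome) -> AnnotatedGenome:
    """Attach features from a GFF3 file to ``genome`` (returns ``genome``).

    GFF3 1-based inclusive coordinates become internal 0-based half-open:
    ``start_internal = start_gff - 1``, ``end_internal = end_gff``.
    """
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[GeneFeature] = []
    for i, f in enumerate(db.all_features()):
        if f.featuretype in _NON_GENE_TYPES:
            continue
        kind = f.featuretype if f.featuretype in ("CDS", "tRNA", "rRNA") else "other"
        start, end = f.start - 1, f.end
        if end > genome.length:
            raise CoordinateError(
                f"feature {f.id or i} [{f.start}, {f.end}] exceeds genome length "
                f"{genome.length}"
            )
        product = (f.attributes.get("product") or [""])[0]
        features.append(
            GeneFeature(
                feature_id=f.id or f"feature-{i + 1}",
                kind=kind,
                start=start,
                end=end,
                strand=f.strand if f.strand in ("+", "-") else "+",
                product=product,
            )
        )
    genome.features = sorted(features, key=lambda f: (f.start, f.end))
    genome.validate()
    return genome


def write_annotation(genome: AnnotatedGenome, gff_path: str | Path) -> None:
    """Write features back to GFF3 (1-based inclusive)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in genome.sorted_features():
            attrs = f"ID={f.feature_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                "\t".join(
                    [
                        genome.genome_id,
                        "srna_seeker",
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_genome_fasta(genome: AnnotatedGenome, fasta_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.genome_id}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i : i + 70] + "\n")


def _interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    cur_start = cur_end = None
    for s, e in sorted(intervals):
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def summarize_genome(genome: AnnotatedGenome) -> GenomeSummary:
    """Length, GC fraction, gene counts and coding fraction.

    GC fraction excludes N (and other ambiguity codes) from the denominator.
    """
    seq = genome.sequence
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    gc = (counts["G"] + counts["C"]) / denom if denom else 0.0
    cds = [(f.start, f.end) for f in genome.features if f.kind == "CDS"]
    coding = _interval_union_length(cds) / genome.length if genome.length else 0.0
    return GenomeSummary(
        length_bp=genome.length,
        gc_fraction=gc,
        n_genes=len(genome.features),
        n_trna=sum(1 for f in genome.features if f.kind == "tRNA"),
        n_rrna=sum(1 for f in genome.features if f.kind == "rRNA"),
        coding_fraction=coding,
    )


def read_alignments(bed_path: str | Path, sample_id: str) -> list[ReadAlignment]:
    """Parse a BED6 file of aligned reads (0-based half-open, as BED is).

    Lines with fewer than 6 columns raise a FormatError naming the line.
    A '.' strand defaults to '+' with a warning (coverage counting downstream
    is unstranded).
    """
    out: list[ReadAlignment] = []
    strandless = 0
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(
                    f"{bed_path}: line {lineno}: expected 6 BED columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{bed_path}: line {lineno}: {exc}") from None
            strand = cols[5]
            if strand not in ("+", "-"):
                strand = "+"
                strandless += 1
            out.append(
                ReadAlignment(
                    read_id=cols[3], start=start, end=end,
                    strand=strand, sample_id=sample_id,
                )
            )
    if strandless:
        log.warning("%s: %d strandless lines defaulted to '+'", bed_path, strandless)
    return out


def write_alignments(alignments: Sequence[ReadAlignment], genome_id: str,
                     bed_path: str | Path) -> None:
    with open(bed_path, "w") as fh:
        for a in alignments:
            fh.write(f"{genome_id}\t{a.start}\t{a.end}\t{a.read_id}\t0\t{a.strand}\n")
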