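"""Checks against the real KLDS 2.0603 reference genome (accession CP007423).

The genome itself is not bundled (it is ~1.9 MB); users who want to
reproduce the published genome-level numbers place the FASTA and GFF3 under
``data/reference/`` (``CP007423.fasta`` / ``CP007423.gff3``, e.g. via NCBI
efetch) and run :func:`verify_reference_genome`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .annotation_io import read_annotation, read_genome, summarize_genome
from .igr_extraction import extract_igrs

#: Published values for CP007423: length (bp), GC (%), IGR count.
PUBLISHED_LENGTH_BP = 1_946_899
PUBLISHED_GC_PERCENT = 60.48
PUBLISHED_N_IGRS = 514

DEFAULT_FASTA = Path("data/reference/CP007423.fasta")
DEFAULT_GFF = Path("data/reference/CP007423.gff3")


@dataclass(frozen=True)
class ReferenceCheck:
    length_bp: int
    gc_percent: float
    n_igrs: int
    mean_igr_length: float

    @property
    def length_matches(self) -> bool:
        return self.length_bp == PUBLISHED_LENGTH_BP

    @property
    def gc_matches(self) -> bool:
        return abs(self.gc_percent - PUBLISHED_GC_PERCENT) < 0.005

    @property
    def igr_count_matches(self) -> bool:
        return self.n_igrs == PUBLISHED_N_IGRS


def verify_reference_genome(
    fasta_path: str | Path = DEFAULT_FASTA,
    gff_path: str | Path = DEFAULT_GFF,
) -> ReferenceCheck:
    """Recompute genome length, GC% and IGR count from local reference files."""
    genome = read_genome(fasta_path)
    read_annotation(gff_path, genome)
    summary = summarize_genome(genome)
    igrs = extract_igrs(genome)
    mean_len = sum(r.length for r in igrs) / len(igrs) if igrs else 0.0
    return ReferenceCheck(
        length_bp=summary.length_bp,
        gc_percent=100 * summary.gc_fraction,
        n_igrs=len(igrs),
        mean_igr_length=mean_len,
    )
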