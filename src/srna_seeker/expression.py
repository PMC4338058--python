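"""Read QC, PCR-duplicate removal, feature counting and RPKM.

Quantification follows the classic RPKM definition

    RPKM = count / ((total_mapped / 1e6) * (length_bp / 1e3))

where ``total_mapped`` is the number of deduplicated alignments in the
sample (library-level), not the per-feature sum.  A read is assigned to
every feature its interval overlaps by at least half of the read's length;
assignment is strand-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

from .annotation_io import FormatError, GeneFeature, ReadAlignment
from .igr_extraction import IGRecord

log = logging.getLogger(__name__)

MIN_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class QcReport:
    sample_id: str
    reads_in: int
    reads_clean: int

    @property
    def fraction_kept(self) -> float:
        return self.reads_clean / self.reads_in if self.reads_in else 0.0


@dataclass
class ExpressionTable:
    """Per-(feature, sample) counts and RPKM.

    ``df`` columns: feature_id, sample_id, count, length_bp, rpkm.
    ``total_mapped`` maps sample_id -> deduplicated library size.
    """

    df: pd.DataFrame
    total_mapped: dict[str, int]

    def value(self, feature_id: str, sample_id: str, column: str = "rpkm") -> float:
        sel = self.df[(self.df.feature_id == feature_id) & (self.df.sample_id == sample_id)]
        if sel.empty:
            raise KeyError(f"no record for ({feature_id}, {sample_id})")
        return float(sel[column].iloc[0])

    def pivot(self, column: str = "rpkm") -> pd.DataFrame:
        return self.df.pivot(index="feature_id", columns="sample_id", values=column)

    def samples(self) -> list[str]:
        return sorted(self.df.sample_id.unique())

    def copy(self) -> "ExpressionTable":
        return ExpressionTable(self.df.copy(), dict(self.total_mapped))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def _trim_ends(quals: Sequence[int], trim_q: int) -> tuple[int, int]:
    lo, hi = 0, len(quals)
    while lo < hi and quals[lo] <= trim_q:
        lo += 1
    while hi > lo and quals[hi - 1] <= trim_q:
        hi -= 1
    return lo, hi


def qc_filter(
    fastq_path: str | Path,
    out_path: Optional[str | Path] = None,
    sample_id: Optional[str] = None,
    min_frac_q20: float = 0.8,
    min_len: int = 20,
    trim_q: int = 2,
) -> QcReport:
    """Quality-filter a Phred+33 FASTQ file.

    Ends with quality <= ``trim_q`` are trimmed first; a read is then kept
    iff its length is strictly greater than ``min_len`` and at least
    ``min_frac_q20`` of its bases have quality strictly above 20.  Clean
    reads are written to ``out_path`` when given.
    """
    sample_id = sample_id or Path(fastq_path).stem
    reads_in = reads_clean = 0
    out_fh = open(out_path, "w") if out_path else None
    try:
        for rec in SeqIO.parse(str(fastq_path), "fastq"):
            reads_in += 1
            quals = rec.letter_annotations["phred_quality"]
            lo, hi = _trim_ends(quals, trim_q)
            trimmed = rec[lo:hi]
            tq = trimmed.letter_annotations["phred_quality"]
            if len(tq) <= min_len:
                continue
            if sum(q > 20 for q in tq) / len(tq) < min_frac_q20:
                continue
            reads_clean += 1
            if out_fh is not None:
                SeqIO.write(trimmed, out_fh, "fastq")
    except ValueError as exc:
        raise FormatError(f"{fastq_path}: {exc}") from exc
    finally:
        if out_fh is not None:
            out_fh.close()
    return QcReport(sample_id=sample_id, reads_in=reads_in, reads_clean=reads_clean)


def dedup(alignments: Sequence[ReadAlignment]) -> list[ReadAlignment]:
    """Collapse PCR duplicates: one alignment kept per (start, end, strand).

    Input order is otherwise preserved (first occurrence wins).
    """
    seen: set[tuple[int, int, str]] = set()
    out: list[ReadAlignment] = []
    for a in alignments:
        key = (a.start, a.end, a.strand)
        if key not in seen:
            seen.add(key)
            out.append(a)
    return out


FeatureLike = Union[GeneFeature, IGRecord, tuple]


def _feature_interval(f: FeatureLike) -> tuple[str, int, int]:
    if isinstance(f, GeneFeature):
        return f.feature_id, f.start, f.end
    if isinstance(f, IGRecord):
        return f.igr_id, f.start, f.end
    fid, start, end = f
    return str(fid), int(start), int(end)


def count_features(
    alignments: Sequence[ReadAlignment],
    features: Sequence[FeatureLike],
) -> ExpressionTable:
    """Count deduplicated alignments per feature, per sample.

    A read counts toward every feature whose interval covers at least
    ``MIN_OVERLAP_FRACTION`` of the read's length (strand-agnostic;
    multi-assignment allowed).  ``total_mapped`` per sample is the number of
    alignments in that sample, not the per-feature sum.
    """
    ivals = [_feature_interval(f) for f in features]
    tree = IntervalTree()
    for fid, start, end in ivals:
        tree[start:end] = fid

    samples = sorted({a.sample_id for a in alignments})
    counts: dict[tuple[str, str], int] = {}
    totals: dict[str, int] = {s: 0 for s in samples}
    for a in alignments:
        totals[a.sample_id] += 1
        need = MIN_OVERLAP_FRACTION * a.length
        for iv in tree.overlap(a.start, a.end):
            overlap = min(a.end, iv.end) - max(a.start, iv.begin)
            if overlap >= need:
                counts[(iv.data, a.sample_id)] = counts.get((iv.data, a.sample_id), 0) + 1

    rows = [
        {
            "feature_id": fid,
            "sample_id": s,
            "count": counts.get((fid, s), 0),
            "length_bp": end - start,
            "rpkm": 0.0,
        }
        for fid, start, end in ivals
        for s in samples
    ]
    return ExpressionTable(df=pd.DataFrame(rows), total_mapped=totals)


def rpkm(table: ExpressionTable) -> ExpressionTable:
    """Fill the rpkm column in place (and return the table)."""
    def _one(row: pd.Series) -> float:
        if row["count"] == 0:
            return 0.0
        total = table.total_mapped.get(row["sample_id"], 0)
        if total <= 0:
            raise ValueError(
                f"sample {row['sample_id']} has nonzero counts but no mapped total"
            )
        return row["count"] / ((total / 1e6) * (row["length_bp"] / 1e3))

    table.df["rpkm"] = table.df.apply(_one, axis=1)
    return table


def quantify(
    alignments: Sequence[ReadAlignment],
    features: Sequence[FeatureLike],
) -> ExpressionTable:
    """dedup -> count -> RPKM for a mixed-sample alignment list."""
    by_sample: dict[str, list[ReadAlignment]] = {}
    for a in alignments:
        by_sample.setdefault(a.sample_id, []).append(a)
    deduped: list[ReadAlignment] = []
    for sample in sorted(by_sample):
        deduped.extend(dedup(by_sample[sample]))
    return rpkm(count_features(deduped, features))
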