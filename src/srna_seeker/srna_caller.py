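"""Promotion of IGRs to high-confidence sRNAs and catalogue rendering.

The joint calling rule: an IGR is an sRNA in a sample iff it holds a
complete transcriptional unit (promoter upstream of terminator on one
strand) AND its RPKM is at least 15% above the RPKM of *both* flanking
genes in the same sample.  The final sRNA set is the union of per-sample
calls.  Catalogue rows polarize coordinates by strand (minus-strand rows
print start > end) and carry a three-glyph orientation string: left flank,
sRNA, right flank, each '→' (plus strand) or '←' (minus strand).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .expression import ExpressionTable
from .igr_extraction import IGRecord
from .signal_finder import UnitCall

log = logging.getLogger(__name__)

DEFAULT_MARGIN = 0.15

_GLYPH = {"+": "→", "-": "←"}


@dataclass
class SrnaCall:
    """An IGR promoted to a high-confidence sRNA."""

    srna_id: str
    start: int  # polarized: for '-' strand start > end, as printed
    end: int
    strand: str
    upstream_gene: str
    downstream_gene: str
    orientation: str
    rpkm_by_sample: dict[str, float] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return abs(self.end - self.start)


@dataclass
class FoldChangeRow:
    srna_id: str
    fold_vs_control: dict[str, float]  # condition -> ratio; inf flags ctrl=0

    def is_flagged(self, condition: str) -> bool:
        return not math.isfinite(self.fold_vs_control[condition])


def _orientation(igr: IGRecord, strand: str) -> str:
    left, right = igr.flank_strands
    return (_GLYPH.get(left or "+", "?")
            + _GLYPH[strand]
            + _GLYPH.get(right or "+", "?"))


def call_srnas(
    igrs: Sequence[IGRecord],
    unit_calls: Mapping[str, UnitCall],
    expr: ExpressionTable,
    sample_id: str,
    margin: float = DEFAULT_MARGIN,
) -> list[SrnaCall]:
    """Apply the complete-unit AND 15%-above-both-flanks rule in one sample.

    The expression comparison is inclusive (IGR RPKM >= (1 + margin) x flank
    RPKM), so an IGR exactly at the threshold is called.  IGRs lacking a
    flanking gene (linear-genome edge gaps) are excluded with a warning.
    """
    rpkm = expr.pivot("rpkm")
    calls: list[SrnaCall] = []
    for igr in igrs:
        unit = unit_calls.get(igr.igr_id)
        if unit is None or not unit.complete_unit:
            continue
        if not igr.has_both_flanks:
            log.warning("%s: missing a flanking gene; excluded from calling", igr.igr_id)
            continue
        try:
            own = float(rpkm.loc[igr.igr_id, sample_id])
            left = float(rpkm.loc[igr.upstream_gene.feature_id, sample_id])
            right = float(rpkm.loc[igr.downstream_gene.feature_id, sample_id])
        except KeyError as exc:
            raise KeyError(f"{igr.igr_id}: missing expression for {exc}") from None
        if own < (1.0 + margin) * left or own < (1.0 + margin) * right:
            continue
        strand = unit.unit_strand
        start, end = (igr.start, igr.end) if strand == "+" else (igr.end, igr.start)
        calls.append(
            SrnaCall(
                srna_id=igr.igr_id,
                start=start,
                end=end,
                strand=strand,
                upstream_gene=igr.upstream_gene.product or igr.upstream_gene.feature_id,
                downstream_gene=igr.downstream_gene.product or igr.downstream_gene.feature_id,
                orientation=_orientation(igr, strand),
                rpkm_by_sample={sample_id: own},
            )
        )
    return calls


def merge_calls(per_sample_calls: Mapping[str, Sequence[SrnaCall]]) -> list[SrnaCall]:
    """Union of per-sample calls by sRNA id; a call in any sample suffices.

    Per-sample RPKMs are merged onto the union records.  Conflicting strands
    for the same id across samples raise an error.
    """
    merged: dict[str, SrnaCall] = {}
    for sample in sorted(per_sample_calls):
        for call in per_sample_calls[sample]:
            prev = merged.get(call.srna_id)
            if prev is None:
                merged[call.srna_id] = SrnaCall(
                    srna_id=call.srna_id,
                    start=call.start,
                    end=call.end,
                    strand=call.strand,
                    upstream_gene=call.upstream_gene,
                    downstream_gene=call.downstream_gene,
                    orientation=call.orientation,
                    rpkm_by_sample=dict(call.rpkm_by_sample),
                )
            else:
                if prev.strand != call.strand:
                    raise ValueError(
                        f"{call.srna_id}: conflicting strand across samples "
                        f"({prev.strand} vs {call.strand})"
                    )
                prev.rpkm_by_sample.update(call.rpkm_by_sample)
    return sorted(merged.values(), key=lambda c: min(c.start, c.end))


def attach_rpkms(calls: Sequence[SrnaCall], expr: ExpressionTable) -> None:
    """Fill every sample's RPKM onto the calls (e.g. after normalization)."""
    rpkm = expr.pivot("rpkm")
    for call in calls:
        for sample in rpkm.columns:
            call.rpkm_by_sample[sample] = float(rpkm.loc[call.srna_id, sample])


def fold_changes(
    calls: Sequence[SrnaCall],
    expr_normalized: ExpressionTable,
    control: str,
    conditions: Optional[Sequence[str]] = None,
) -> list[FoldChangeRow]:
    """Treatment/control RPKM ratios per sRNA on normalized expression.

    A zero control RPKM yields an infinite (flagged) ratio, excluded from
    summaries by callers.
    """
    rpkm = expr_normalized.pivot("rpkm")
    if control not in rpkm.columns:
        raise KeyError(f"control sample {control!r} not in expression table")
    conds = list(conditions) if conditions is not None else [
        c for c in rpkm.columns if c != control
    ]
    rows = []
    for call in calls:
        ctrl = float(rpkm.loc[call.srna_id, control])
        folds = {}
        for c in conds:
            treat = float(rpkm.loc[call.srna_id, c])
            folds[c] = treat / ctrl if ctrl > 0 else math.inf
        rows.append(FoldChangeRow(srna_id=call.srna_id, fold_vs_control=folds))
    return rows


def render_catalogue(calls: Sequence[SrnaCall]) -> str:
    """TSV catalogue of the calls, one row per distinct sRNA id."""
    header = ["srna_id", "start", "end", "strand", "length",
              "upstream_gene", "downstream_gene", "orientation"]
    seen: set[str] = set()
    lines = ["\t".join(header)]
    for c in calls:
        if c.srna_id in seen:
            continue
        seen.add(c.srna_id)
        lines.append(
            "\t".join(
                [c.srna_id, str(c.start), str(c.end), c.strand, str(c.length),
                 c.upstream_gene, c.downstream_gene, c.orientation]
            )
        )
    return "\n".join(lines) + "\n"


def render_fold_changes(rows: Sequence[FoldChangeRow]) -> str:
    """TSV of per-condition fold changes, ratios rounded to 2 decimals."""
    conds: list[str] = []
    for r in rows:
        for c in r.fold_vs_control:
            if c not in conds:
                conds.append(c)
    lines = ["\t".join(["srna_id"] + conds)]
    for r in rows:
        vals = []
        for c in conds:
            v = r.fold_vs_control.get(c, math.nan)
            vals.append("inf" if not math.isfinite(v) else f"{v:.2f}")
        lines.append("\t".join([r.srna_id] + vals))
    return "\n".join(lines) + "\n"
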