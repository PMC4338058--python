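"""Differential expression without replicates.

Per-sample RPKMs are median-normalized (each sample scaled so that its
median over expressed features equals the geometric mean of the sample
medians).  Significance comes from an exact conditional binomial test on
the deduplicated counts (Audic-Claverie style): conditional on the summed
count n = a + b, a is Binomial(n, T_a / (T_a + T_b)) under the null of equal
relative expression, and the two-sided p-value sums the probabilities of
all outcomes no more likely than the observed one.  Differentially
expressed features satisfy |log2 FC| > 1 and p < 0.05; a Benjamini-Hochberg
column is reported for information but does not enter the status call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionTable

LOG2FC_CUTOFF = 1.0
P_CUTOFF = 0.05
PSEUDOCOUNT = 0.5  # RPKM added to both sides of the ratio


@dataclass(frozen=True)
class DeResult:
    feature_id: str
    condition: str
    log2fc: float
    p_value: float
    status: str  # up | down | ns


def median_normalize(expr: ExpressionTable) -> ExpressionTable:
    """Scale each sample's RPKMs so medians over expressed features agree.

    The common target is the geometric mean of the per-sample medians
    (medians taken over features with RPKM > 0).  Counts are left untouched.
    """
    out = expr.copy()
    samples = out.samples()
    if len(samples) < 2:
        raise ValueError("median normalization needs at least two samples")
    medians = {}
    for s in samples:
        vals = out.df.loc[(out.df.sample_id == s) & (out.df.rpkm > 0), "rpkm"]
        if vals.empty:
            raise ValueError(f"sample {s} has no expressed features")
        medians[s] = float(vals.median())
    reference = float(np.exp(np.mean([math.log(m) for m in medians.values()])))
    for s in samples:
        out.df.loc[out.df.sample_id == s, "rpkm"] *= reference / medians[s]
    return out


def test_de(count_a: int, count_b: int, total_a: int, total_b: int) -> float:
    """Two-sided exact conditional test for a single-library contrast.

    Under the null, given n = count_a + count_b, count_a follows
    Binomial(n, total_a / (total_a + total_b)).  p sums the probabilities of
    all outcomes whose probability does not exceed that of the observation.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    if count_a > total_a or count_b > total_b:
        raise ValueError("counts cannot exceed library totals")
    n = count_a + count_b
    if n == 0:
        return 1.0
    p0 = total_a / (total_a + total_b)
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    observed = pmf[count_a]
    # tolerance guards against ties lost to floating point
    p = float(pmf[pmf <= observed * (1 + 1e-7)].sum())
    return min(p, 1.0)


def _status(log2fc: float, p: float,
            lfc_cutoff: float = LOG2FC_CUTOFF, p_cutoff: float = P_CUTOFF) -> str:
    if p < p_cutoff and log2fc > lfc_cutoff:
        return "up"
    if p < p_cutoff and log2fc < -lfc_cutoff:
        return "down"
    return "ns"


def select_degs(
    expr_normalized: ExpressionTable,
    control: str,
    condition: str,
    lfc_cutoff: float = LOG2FC_CUTOFF,
    p_cutoff: float = P_CUTOFF,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-feature fold change and exact-test p-value versus control.

    Returns a DataFrame with columns feature_id, condition, log2fc, p_value,
    bh_fdr, status.  log2fc uses normalized RPKM with a pseudocount for
    stability at zeros; the p-value uses the raw deduplicated counts.
    """
    rpkm = expr_normalized.pivot("rpkm")
    counts = expr_normalized.pivot("count")
    for s in (control, condition):
        if s not in rpkm.columns:
            raise KeyError(f"sample {s!r} not in expression table")
    t_ctrl = expr_normalized.total_mapped[control]
    t_cond = expr_normalized.total_mapped[condition]
    rows = []
    for fid in rpkm.index:
        log2fc = math.log2(
            (rpkm.loc[fid, condition] + pseudocount)
            / (rpkm.loc[fid, control] + pseudocount)
        )
        p = test_de(int(counts.loc[fid, condition]), int(counts.loc[fid, control]),
                    t_cond, t_ctrl)
        rows.append({"feature_id": fid, "condition": condition,
                     "log2fc": log2fc, "p_value": p})
    df = pd.DataFrame(rows)
    df["bh_fdr"] = multipletests(df.p_value, method="fdr_bh")[1]
    df["status"] = [
        _status(l, p, lfc_cutoff, p_cutoff) for l, p in zip(df.log2fc, df.p_value)
    ]
    return df


def deg_sets(results: pd.DataFrame) -> dict[str, set[str]]:
    """{'up': ids, 'down': ids} from a select_degs frame."""
    return {
        direction: set(results.loc[results.status == direction, "feature_id"])
        for direction in ("up", "down")
    }


def overlap_summary(
    results_by_condition: Mapping[str, pd.DataFrame],
    reference: Optional[str] = None,
) -> pd.DataFrame:
    """Pairwise DEG overlap counts against a reference condition.

    For each condition A and direction, reports |A|, |R|, |A ∩ R| and the
    shared fraction |A ∩ R| / |A| (the denominator is the *condition's* DEG
    count, stated explicitly via the column name).
    """
    conditions = sorted(results_by_condition)
    if len(conditions) < 2:
        raise ValueError("overlap summary needs at least two conditions")
    reference = reference or conditions[-1]
    ref_sets = deg_sets(results_by_condition[reference])
    rows = []
    for cond in conditions:
        if cond == reference:
            continue
        sets = deg_sets(results_by_condition[cond])
        for direction in ("up", "down"):
            a, r = sets[direction], ref_sets[direction]
            shared = len(a & r)
            rows.append(
                {
                    "condition": cond,
                    "reference": reference,
                    "direction": direction,
                    "n_condition_degs": len(a),
                    "n_reference_degs": len(r),
                    "n_shared": shared,
                    "fraction_of_condition_shared": shared / len(a) if a else 0.0,
                }
            )
    return pd.DataFrame(rows)


def simulate_null_rejection_rate(
    n_reps: int = 10_000,
    mean_count: float = 200.0,
    alpha: float = P_CUTOFF,
    seed: int = 0,
) -> float:
    """Empirical type-I error of ``test_de`` under an equal-proportion null.

    Each replicate draws a pair of Poisson(mean_count) counts for two
    equal-size libraries and tests them at level ``alpha``.  Replicates are
    grouped by the summed count so each distinct null distribution is
    evaluated once.
    """
    rng = np.random.default_rng(seed)
    a = rng.poisson(mean_count, size=n_reps)
    b = rng.poisson(mean_count, size=n_reps)
    n_values = a + b
    rejected = 0
    for n in np.unique(n_values):
        if n == 0:
            continue
        pmf = stats.binom.pmf(np.arange(n + 1), int(n), 0.5)
        mask = n_values == n
        observed = np.unique(a[mask])
        # same definition as test_de, evaluated once per distinct outcome
        pvals = {
            int(k): float(np.minimum(pmf[pmf <= pmf[k] * (1 + 1e-7)].sum(), 1.0))
            for k in observed
        }
        rejected += sum(1 for k in a[mask] if pvals[int(k)] < alpha)
    return rejected / n_reps
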