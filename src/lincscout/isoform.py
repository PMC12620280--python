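"""Alternative start-/termination-exon usage from exon-level counts.

Multi-TSS lncRNAs initiate transcription from mutually exclusive first
exons and may terminate at alternative last exons. Usage is quantified per
sample from exon-level counts: expression per exon is length-normalized
log2(CPM + 1) (for statistics and plotting) while the usage *share* is
computed on the linear length-normalized CPM scale so shares over an exon
set sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

__all__ = ["UsageResult", "exon_usage", "compare_usage", "ComparisonResult"]


@dataclass
class UsageResult:
    """Long-form usage table plus the number of samples dropped by the
    all-positive filter."""

    table: pd.DataFrame  # columns: sample_id, exon_id, normalized_expression, usage_share
    n_dropped: int
    exon_set: tuple[str, ...]

    def wide(self, column: str = "normalized_expression") -> pd.DataFrame:
        return self.table.pivot(index="sample_id", columns="exon_id", values=column)


def exon_usage(
    exon_counts: ExpressionMatrix,
    exon_lengths: Mapping[str, int],
    exon_set: Sequence[str],
    min_expr_filter: str = "all_positive",
) -> UsageResult:
    """Per-sample usage of a declared exon set (e.g. the start exons).

    With ``min_expr_filter='all_positive'`` only samples with CPM > 0 in
    every exon of the set are retained (the number dropped is reported);
    ``'none'`` keeps all samples. ``usage_share`` for a sample with zero
    total signal over the set is NaN.
    """
    exon_set = tuple(exon_set)
    if not exon_set:
        raise ValueError("exon_set must be non-empty")
    missing = [e for e in exon_set if e not in exon_counts.counts.index]
    if missing:
        raise ValueError(f"exons not in count matrix: {missing}")

    cpm = exon_counts.cpm().loc[list(exon_set)]
    kb = pd.Series({e: exon_lengths[e] / 1e3 for e in exon_set})
    lin = cpm.div(kb, axis=0)                  # length-normalized CPM per kb
    logn = np.log2(lin + 1.0)

    if min_expr_filter == "all_positive":
        keep = (cpm > 0).all(axis=0)
    elif min_expr_filter == "none":
        keep = pd.Series(True, index=cpm.columns)
    else:
        raise ValueError(f"unknown filter {min_expr_filter!r}")
    n_dropped = int((~keep).sum())
    lin, logn = lin.loc[:, keep], logn.loc[:, keep]

    totals = lin.sum(axis=0)
    shares = lin.div(totals.where(totals > 0), axis=1)

    rows = []
    for s in lin.columns:
        for e in exon_set:
            rows.append(
                {
                    "sample_id": s,
                    "exon_id": e,
                    "normalized_expression": float(logn.loc[e, s]),
                    "usage_share": float(shares.loc[e, s]),
                }
            )
    return UsageResult(table=pd.DataFrame(rows), n_dropped=n_dropped, exon_set=exon_set)


@dataclass
class ComparisonResult:
    design: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: exon_a, exon_b, statistic, p, p_adj


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    d = x - y
    if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(x, y)
    if np.isnan(p):  # constant non-zero difference
        return float("inf"), 0.0
    return float(t), float(p)


def compare_usage(usage: UsageResult, design: str | None = None) -> ComparisonResult:
    """Test for differential exon usage across the set.

    Two-exon sets: paired two-sided t-test across samples on the normalized
    expression. Larger sets: one-way repeated-measures ANOVA (samples as
    subjects) followed by pairwise paired t-tests, Holm-adjusted.
    """
    wide = usage.wide()
    exons = list(usage.exon_set)
    if len(exons) < 2:
        raise ValueError("need >=2 exons to compare usage")
    if len(wide) < 3:
        raise ValueError("need >=3 samples for the comparison")
    if design is None:
        design = "paired_two" if len(exons) == 2 else "repeated_multi"

    pairs = [(a, b) for i, a in enumerate(exons) for b in exons[i + 1:]]
    rows = []
    for a, b in pairs:
        t, p = _paired_t(wide[a].to_numpy(), wide[b].to_numpy())
        rows.append({"exon_a": a, "exon_b": b, "statistic": t, "p": p})
    pw = pd.DataFrame(rows)
    pw["p_adj"] = multipletests(pw["p"], method="holm")[1]

    if design == "paired_two":
        stat, p = pw.loc[0, "statistic"], pw.loc[0, "p"]
        return ComparisonResult("paired_two", float(stat), float(p), pw)
    if design != "repeated_multi":
        raise ValueError(f"unknown design {design!r}")

    import pingouin as pg

    long = usage.table.rename(columns={"normalized_expression": "expr"})
    if long.groupby("sample_id")["expr"].transform("std").fillna(0).eq(0).all():
        return ComparisonResult("repeated_multi", 0.0, 1.0, pw)
    aov = pg.rm_anova(
        data=long, dv="expr", within="exon_id", subject="sample_id", detailed=False
    )
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    return ComparisonResult(
        "repeated_multi", float(aov["F"].iloc[0]), float(aov[pcol].iloc[0]), pw
    )
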