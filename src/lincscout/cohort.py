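"""Cohort-level characterization of a target transcript.

Covers expressor binning of log2(CPM+1) values, nonparametric subgroup
association (Kruskal-Wallis with Dunn's post-hoc), Pearson correlation
ranking against the transcriptome, Kaplan-Meier / log-rank survival with
censoring at allogeneic stem-cell transplantation, multivariable
proportional-hazards regression, and two small quantitation utilities
(qPCR delta-delta-CT and spike-normalized fraction distributions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurvivalRecord",
    "bin_expressors",
    "group_association",
    "correlation_rank",
    "median_split",
    "apply_transplant_censoring",
    "km_logrank",
    "ph_multivariable",
    "ddct",
    "fraction_distribution",
]

BINS = ("zero", "low_nonexpr", "expressor_low", "expressor_high")


# ---------------------------------------------------------------------------
# Expressor binning
# ---------------------------------------------------------------------------

def bin_expressors(values: Sequence[float]) -> tuple[list[str], pd.DataFrame]:
    """Bin log2(CPM+1) values into the four expressor classes.

    Bins partition [0, inf): exactly 0 -> ``zero``; (0, 0.5] ->
    ``low_nonexpr``; (0.5, 2] -> ``expressor_low``; (2, inf) ->
    ``expressor_high``. The first two classes are non-expressors, the last
    two expressors. Boundaries are left-open/right-closed.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("expression values must be >= 0")
    labels = np.select(
        [v == 0, v <= 0.5, v <= 2.0], ["zero", "low_nonexpr", "expressor_low"],
        default="expressor_high",
    ).tolist()
    counts = pd.Series(labels).value_counts().reindex(BINS, fill_value=0)
    summary = pd.DataFrame(
        {"count": counts, "fraction": counts / max(len(labels), 1)}
    )
    summary["class"] = ["non-expressor", "non-expressor", "expressor", "expressor"]
    return labels, summary


# ---------------------------------------------------------------------------
# Subgroup association: Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def _dunn_pairwise(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's z-tests on mean ranks with tie correction, Holm-adjusted."""
    ranks = stats.rankdata(values)
    n = len(values)
    # tie correction term: sum(t^3 - t) / (12 (n - 1))
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    labels = pd.unique(groups)
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
            )
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            p = 2 * stats.norm.sf(abs(z)) if se > 0 else 1.0
            rows.append({"group_a": a, "group_b": b, "z": z, "p": p})
    pw = pd.DataFrame(rows)
    pw["p_adj"] = multipletests(pw["p"], method="holm")[1]
    return pw


def group_association(
    values: Sequence[float], groups: Sequence[str]
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise post-hoc.

    Returns (H, p, pairwise table). All values identical across groups is a
    valid degenerate input and returns H=0, p=1.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need >=2 groups")
    if any((g == lab).sum() == 0 for lab in labels):
        raise ValueError("empty group")
    pw = _dunn_pairwise(v, g)
    if np.all(v == v[0]):
        return 0.0, 1.0, pw
    h, p = stats.kruskal(*[v[g == lab] for lab in labels])
    return float(h), float(p), pw


# ---------------------------------------------------------------------------
# Correlation ranking
# ---------------------------------------------------------------------------

def correlation_rank(target: pd.Series, expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of every gene (row of *expr*) against *target*.

    Returns a table sorted by r descending with two-sided p (t distribution
    with n-2 df) and BH q. Zero-variance genes are reported with NaN r and
    excluded from the ranking order (pushed to the end).
    """
    samples = list(target.index)
    if len(samples) < 3:
        raise ValueError("need >=3 samples")
    x = target.to_numpy(dtype=float)
    mat = expr[samples].to_numpy(dtype=float)
    xc = x - x.mean()
    mc = mat - mat.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum())
    sm = np.sqrt((mc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc @ xc) / (sm * sx)
    r = np.where(sm == 0, np.nan, np.clip(r, -1.0, 1.0))
    n = len(samples)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = np.where(np.isnan(r), np.nan, 2 * stats.t.sf(np.abs(t), df=n - 2))
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    out = pd.DataFrame({"r": r, "p": p}, index=expr.index)
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    if valid.any():
        q[valid.to_numpy()] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    out["q"] = q
    return out.sort_values("r", ascending=False, na_position="last")


def top_bottom(ranked: pd.DataFrame, k: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k positively and bottom-k negatively correlated genes."""
    valid = ranked[ranked["r"].notna()]
    return valid.head(k), valid.tail(k).iloc[::-1]


def median_split(values: pd.Series) -> pd.Series:
    """Dichotomize at the cohort median; ties at the median go 'high'.

    The split is identical for CPM and log2(CPM+1) inputs since the
    transform is monotone.
    """
    med = values.median()
    return pd.Series(
        np.where(values >= med, "high", "low"), index=values.index, name="stratum"
    )


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalRecord:
    """Time-to-event record; transplant_time, when earlier than the event
    time, censors the record at transplantation."""

    sample_id: str
    time: float
    event: bool
    transplant_time: float | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.sample_id}: time must be > 0")


def apply_transplant_censoring(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Effective (time, event) after censoring at allo-HSCT, as a DataFrame."""
    rows = []
    for r in records:
        time, event = r.time, r.event
        if r.transplant_time is not None and r.transplant_time < r.time:
            time, event = r.transplant_time, False
        rows.append({"sample_id": r.sample_id, "time": time, "event": event,
                     **r.covariates})
    return pd.DataFrame(rows).set_index("sample_id")


def km_logrank(
    records: Sequence[SurvivalRecord], strata: Mapping[str, str] | pd.Series
) -> tuple[dict[str, pd.DataFrame], float | None, float | None]:
    """Kaplan-Meier curves per stratum and the log-rank test across strata.

    Transplant censoring is applied first. Returns (curves, chi2, p);
    chi2/p are None when no events occurred (log-rank undefined).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    df = apply_transplant_censoring(records)
    df["stratum"] = pd.Series(dict(strata)).reindex(df.index)
    if df["stratum"].isna().any():
        raise ValueError("every record needs a stratum label")
    counts = df["stratum"].value_counts()
    if (counts == 0).any():
        raise ValueError("stratum with zero records")

    curves = {}
    for label, sub in df.groupby("stratum"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=str(label))
        curves[str(label)] = kmf.survival_function_

    if int(df["event"].sum()) == 0:
        return curves, None, None
    res = multivariate_logrank_test(df["time"], df["stratum"], df["event"])
    return curves, float(res.test_statistic), float(res.p_value)


def ph_multivariable(
    records: Sequence[SurvivalRecord], covariates: Sequence[str]
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) after transplant censoring.

    Returns a table with HR = exp(coef), Wald 95% CI and p per covariate.
    Raises on constant covariates or non-convergence.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = apply_transplant_censoring(records)
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValueError(f"missing covariates: {missing}")
    sub = df[["time", "event", *covariates]].astype(float)
    for c in covariates:
        if sub[c].nunique() < 2:
            raise ValueError(f"covariate {c} is constant")
    if int(sub["event"].sum()) < len(covariates):
        raise ValueError("fewer events than covariates")

    cph = CoxPHFitter()
    try:
        cph.fit(sub, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    s = cph.summary
    return pd.DataFrame(
        {
            "coef": s["coef"],
            "HR": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )


# ---------------------------------------------------------------------------
# Small quantitation utilities
# ---------------------------------------------------------------------------

def ddct(
    ct_target: float, ct_control: float, ct_target_ref: float, ct_control_ref: float
) -> float:
    """Relative quantity by the delta-delta-CT method: RQ = 2^-ddCT with
    ddCT = (Ct_target - Ct_control) - (Ct_target_ref - Ct_control_ref)."""
    for v in (ct_target, ct_control, ct_target_ref, ct_control_ref):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct_value = (ct_target - ct_control) - (ct_target_ref - ct_control_ref)
    return float(2.0 ** (-ddct_value))


def fraction_distribution(
    signal: Sequence[float], spike: Sequence[float]
) -> np.ndarray:
    """Spike-normalized percent-of-total per gradient fraction.

    normalized_i = signal_i / spike_i; percents renormalize to sum to 100.
    """
    sig = np.asarray(signal, dtype=float)
    sp = np.asarray(spike, dtype=float)
    if sig.shape != sp.shape:
        raise ValueError("signal and spike must align")
    zero = np.where(sp <= 0)[0]
    if len(zero):
        raise ValueError(f"non-positive spike in fraction(s) {zero.tolist()}")
    norm = sig / sp
    total = norm.sum()
    if total <= 0:
        raise ValueError("total normalized signal must be positive")
    return 100.0 * norm / total
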