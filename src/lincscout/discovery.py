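"""Candidate-lincRNA discovery cascade.

The cascade flags every assembled transcript against eight independent
criteria — spliced length > 200 bp, intergenic location, mean expression
>= 0.5 RPKM across all samples, DNase-I hypersensitivity and H3K4me3
support at the TSS, multi-exon structure, no abnormally long exon, and
differential expression between the two sample groups (BH-FDR < 0.05 and
fold change > 1.5 on the CPM scale). Flags are computed without
short-circuiting so failure attribution is complete; a transcript is a
candidate iff every flag is true.

Differential expression is a two-sided Welch t-test on log2(CPM + 1) with
Benjamini-Hochberg correction. The fold change is computed on the CPM scale
with a pseudocount of 1 CPM; log2FC > 0 means higher expression in group A.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from .genome import GeneAnnotation, GenomicInterval, PeakSet, TranscriptModel, classify_location

logger = logging.getLogger(__name__)

__all__ = [
    "CascadeParams",
    "CandidateRecord",
    "differential_expression",
    "splicing_structure_filter",
    "epigenomic_support",
    "run_cascade",
]

CRITERIA = (
    "length_gt_200",
    "intergenic",
    "mean_rpkm_ge_0.5",
    "dnase_support",
    "h3k4me3_support",
    "multi_exon",
    "exon_size_ok",
    "de_significant",
)


@dataclass
class CascadeParams:
    """Thresholds of the discovery cascade (defaults are the study values)."""

    min_length_bp: int = 200          # candidates must be strictly longer
    min_mean_rpkm: float = 0.5        # inclusive, mean over ALL samples
    fdr: float = 0.05
    min_abs_fc: float = 1.5           # linear fold change, either direction
    max_exon_bp: int = 10_000         # "abnormally long exon" bound
    tss_window: int = 1_000           # bp each side of the TSS
    location_mode: str = "gene_span"  # introns count as genic
    stranded: bool = False
    group_a: str = "AML"
    group_b: str = "NBM"


@dataclass
class CandidateRecord:
    transcript_id: str
    flags: dict[str, bool]
    log2fc: float
    p_value: float
    q_value: float

    @property
    def passes_all(self) -> bool:
        return all(self.flags.values())


def differential_expression(
    m: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fdr: float = 0.05,
    min_abs_fc: float = 1.5,
) -> pd.DataFrame:
    """Per-feature Welch t-test on log2(CPM+1) with BH correction.

    Returns a DataFrame indexed by feature with columns ``log2FC`` (group A
    over group B, pseudocount 1 CPM), ``p``, ``q`` and ``called``
    (q < fdr AND linear |FC| > min_abs_fc).
    """
    sa = m.samples_in_group(group_a)
    sb = m.samples_in_group(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(sa)} ({group_a}) "
            f"and {len(sb)} ({group_b})"
        )
    cpm = m.cpm()
    log_a, log_b = np.log2(cpm[sa] + 1.0), np.log2(cpm[sb] + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    # zero variance in both groups: p=1 if means equal, else a hard separation
    degenerate = np.isnan(p)
    if degenerate.any():
        eq = np.isclose(log_a.mean(axis=1), log_b.mean(axis=1))
        p = np.where(degenerate, np.where(eq, 1.0, 0.0), p)
        t = np.where(np.isnan(t), 0.0, t)
    log2fc = np.log2((cpm[sa].mean(axis=1) + 1.0) / (cpm[sb].mean(axis=1) + 1.0))
    q = multipletests(p, method="fdr_bh")[1]
    called = (q < fdr) & (np.abs(log2fc) > math.log2(min_abs_fc))
    return pd.DataFrame(
        {"log2FC": log2fc, "t": t, "p": p, "q": q, "called": called},
        index=m.feature_ids,
    )


def splicing_structure_filter(
    t: TranscriptModel, max_exon_bp: int = 10_000
) -> tuple[bool, bool]:
    """(multi_exon, exon_size_ok) — the splicing-plausibility checks.

    Single-exon transcripts and transcripts with an abnormally long exon
    likely represent retained introns rather than spliced products.
    """
    return t.n_exons >= 2, t.max_exon_length <= max_exon_bp


def epigenomic_support(
    t: TranscriptModel,
    dnase: PeakSet,
    h3k4me3: PeakSet,
    tss_window: int = 1_000,
) -> tuple[bool, bool]:
    """Whether each track has >=1 peak within [TSS - window, TSS + window)."""
    if tss_window < 0:
        raise ValueError("tss_window must be >= 0")
    start = max(0, t.tss - tss_window)
    window = GenomicInterval(t.chrom, start, t.tss + tss_window + 1)
    return dnase.any_overlap(window), h3k4me3.any_overlap(window)


def run_cascade(
    assembled: GeneAnnotation,
    reference: GeneAnnotation,
    m: ExpressionMatrix,
    tracks: Mapping[str, PeakSet],
    params: CascadeParams | None = None,
) -> tuple[list[CandidateRecord], dict]:
    """Run the full discovery cascade over the assembled transcripts.

    Returns the per-transcript records (sorted by transcript_id) and an
    attrition report: per-criterion failure counts, the number of
    transcripts evaluated and the candidate list.
    """
    params = params or CascadeParams()
    de = differential_expression(
        m, params.group_a, params.group_b, fdr=params.fdr, min_abs_fc=params.min_abs_fc
    )
    rpkm_mean = m.rpkm({t.transcript_id: t.spliced_length for t in assembled
                        if t.transcript_id in m.counts.index}
                       | {f: 1 for f in m.feature_ids
                          if f not in assembled}).mean(axis=1)

    records: list[CandidateRecord] = []
    skipped: list[str] = []
    for tid in sorted(assembled.transcripts):
        t = assembled.transcripts[tid]
        if tid not in m.counts.index:
            logger.warning("transcript %s missing from counts; excluded", tid)
            skipped.append(tid)
            continue
        multi_exon, exon_ok = splicing_structure_filter(t, params.max_exon_bp)
        dnase_ok, h3k4_ok = epigenomic_support(
            t, tracks["dnase"], tracks["h3k4me3"], params.tss_window
        )
        flags = {
            "length_gt_200": t.spliced_length > params.min_length_bp,
            "intergenic": classify_location(
                t, reference, mode=params.location_mode, stranded=params.stranded
            )
            == "intergenic",
            "mean_rpkm_ge_0.5": bool(rpkm_mean[tid] >= params.min_mean_rpkm),
            "dnase_support": dnase_ok,
            "h3k4me3_support": h3k4_ok,
            "multi_exon": multi_exon,
            "exon_size_ok": exon_ok,
            "de_significant": bool(de.loc[tid, "called"]),
        }
        records.append(
            CandidateRecord(
                transcript_id=tid,
                flags=flags,
                log2fc=float(de.loc[tid, "log2FC"]),
                p_value=float(de.loc[tid, "p"]),
                q_value=float(de.loc[tid, "q"]),
            )
        )

    attrition = {c: sum(not r.flags[c] for r in records) for c in CRITERIA}
    candidates = [r.transcript_id for r in records if r.passes_all]
    report = {
        "n_assembled": len(assembled),
        "n_evaluated": len(records),
        "n_skipped_missing_counts": len(skipped),
        "skipped": skipped,
        "failures_per_criterion": attrition,
        "n_candidates": len(candidates),
        "candidates": candidates,
        "fold_change_direction": f"log2FC > 0 means higher in {params.group_a}",
    }
    return records, report


def records_to_frame(records: list[CandidateRecord]) -> pd.DataFrame:
    """Flatten cascade records into a TSV-ready table."""
    rows = []
    for r in records:
        row = {"transcript_id": r.transcript_id, **r.flags,
               "log2FC": r.log2fc, "p": r.p_value, "q": r.q_value,
               "passes_all": r.passes_all}
        rows.append(row)
    return pd.DataFrame(rows).set_index("transcript_id")
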