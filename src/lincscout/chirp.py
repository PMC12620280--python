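"""ChIRP-seq post-processing.

Replicate consensus of called peaks, assignment of each peak to one genomic
feature category (promoter / 5'UTR / 3'UTR / exon / intron / downstream /
distal intergenic, with a fixed precedence), chromatin-state enrichment by
peak shuffling, peak-to-gene mapping, and hypergeometric gene-set overlap
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneAnnotation, GenomicInterval, PeakSet, overlaps

__all__ = [
    "PeakAnnotation",
    "GeneSet",
    "replicate_consensus",
    "annotate_peak",
    "annotate_peaks",
    "state_enrichment",
    "peaks_to_genes",
    "set_overlap_test",
    "three_way_overlap",
]

CATEGORIES = (
    "promoter",
    "five_utr",
    "three_utr",
    "exon",
    "intron",
    "downstream",
    "distal_intergenic",
)


@dataclass
class PeakAnnotation:
    peak: GenomicInterval
    category: str
    nearest_gene: str | None
    distance_to_tss: int | None  # signed, transcription-direction aware


@dataclass
class GeneSet:
    name: str
    members: frozenset[str]

    def __init__(self, name: str, members) -> None:
        self.name = name
        self.members = frozenset(members)

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Replicate consensus
# ---------------------------------------------------------------------------

def _coalesce(peaks: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or identical intervals (per chromosome)."""
    out: list[GenomicInterval] = []
    for p in sorted(peaks, key=lambda x: (x.chrom, x.start, x.end)):
        if out and out[-1].chrom == p.chrom and p.start < out[-1].end:
            last = out.pop()
            out.append(
                GenomicInterval(p.chrom, last.start, max(last.end, p.end))
            )
        else:
            out.append(GenomicInterval(p.chrom, p.start, p.end))
    return out


def replicate_consensus(
    rep1: PeakSet,
    rep2: PeakSet,
    min_overlap_bp: int = 1,
    merge: str = "union",
) -> PeakSet:
    """Peaks reproducible across two biological replicates.

    A rep1 peak is retained iff it overlaps at least one rep2 peak by
    ``min_overlap_bp``; the reported coordinates are the union (default) or
    intersection of the overlapping replicate peaks, and overlapping output
    peaks are coalesced.
    """
    if merge not in ("union", "intersection"):
        raise ValueError(f"unknown merge policy {merge!r}")
    rep2_by_chrom = rep2.by_chrom()
    kept: list[GenomicInterval] = []
    for p in rep1.peaks:
        partners = [
            q
            for q in rep2_by_chrom.get(p.chrom, [])
            if p.overlap_length(q) >= min_overlap_bp
        ]
        if not partners:
            continue
        if merge == "union":
            start = min(p.start, *(q.start for q in partners))
            end = max(p.end, *(q.end for q in partners))
            kept.append(GenomicInterval(p.chrom, start, end))
        else:
            kept.extend(
                GenomicInterval(p.chrom, max(p.start, q.start), min(p.end, q.end))
                for q in partners
            )
    return PeakSet(name=f"{rep1.name}_consensus", peaks=_coalesce(kept))


# ---------------------------------------------------------------------------
# Peak annotation
# ---------------------------------------------------------------------------

def _tss_region(t, promoter_bp: int) -> GenomicInterval:
    start = max(0, t.tss - promoter_bp)
    return GenomicInterval(t.chrom, start, t.tss + promoter_bp + 1)


def _downstream_region(t, downstream_bp: int) -> GenomicInterval | None:
    if t.strand == "-":
        start, end = max(0, t.exons[0].start - downstream_bp), t.exons[0].start
    else:
        start, end = t.exons[-1].end, t.exons[-1].end + downstream_bp
    if start >= end:
        return None
    return GenomicInterval(t.chrom, start, end)


def annotate_peak(
    p: GenomicInterval,
    ann: GeneAnnotation,
    promoter_bp: int = 3_000,
    downstream_bp: int = 3_000,
    precedence: Sequence[str] = CATEGORIES,
) -> PeakAnnotation:
    """Assign one feature category to a peak.

    Categories, tested in precedence order (promoter first, distal last):
    promoter = within ``promoter_bp`` either side of a TSS; 5'/3' UTR =
    overlapping an annotated UTR; exon = overlapping an exon excluding its
    UTR parts; intron = inside a gene body but not exonic; downstream =
    within ``downstream_bp`` past a TES; else distal intergenic. The nearest
    gene (by TSS distance) and the signed distance to that TSS
    (positive = peak downstream of the TSS in transcription direction) are
    reported for every peak.
    """
    hits: dict[str, bool] = {c: False for c in CATEGORIES}
    nearest_gene, nearest_dist = None, None
    mid = p.midpoint
    for t in ann:
        if t.chrom != p.chrom:
            continue
        signed = mid - t.tss if t.strand != "-" else t.tss - mid
        if nearest_dist is None or abs(signed) < abs(nearest_dist):
            nearest_gene, nearest_dist = t.gene_id, signed
        if overlaps(p, _tss_region(t, promoter_bp)):
            hits["promoter"] = True
        for u in t.utr5:
            if overlaps(p, u):
                hits["five_utr"] = True
        for u in t.utr3:
            if overlaps(p, u):
                hits["three_utr"] = True
        utr_all = list(t.utr5) + list(t.utr3)
        for e in t.exons:
            if not overlaps(p, e):
                continue
            # exonic overlap outside the UTR parts of this exon
            covered = sum(
                max(0, min(p.end, u.end, e.end) - max(p.start, u.start, e.start))
                for u in utr_all
            )
            if p.overlap_length(e) > covered:
                hits["exon"] = True
        for intron in t.introns():
            if overlaps(p, intron):
                hits["intron"] = True
        ds = _downstream_region(t, downstream_bp)
        if ds is not None and overlaps(p, ds):
            hits["downstream"] = True
    for cat in precedence:
        if cat != "distal_intergenic" and hits[cat]:
            return PeakAnnotation(p, cat, nearest_gene, nearest_dist)
    return PeakAnnotation(p, "distal_intergenic", nearest_gene, nearest_dist)


def annotate_peaks(
    peaks: PeakSet,
    ann: GeneAnnotation,
    promoter_bp: int = 3_000,
    downstream_bp: int = 3_000,
) -> list[PeakAnnotation]:
    return [
        annotate_peak(p, ann, promoter_bp=promoter_bp, downstream_bp=downstream_bp)
        for p in peaks
    ]


def annotation_summary(annots: Sequence[PeakAnnotation]) -> pd.Series:
    counts = pd.Series([a.category for a in annots]).value_counts()
    return counts.reindex(CATEGORIES, fill_value=0)


# ---------------------------------------------------------------------------
# Chromatin-state enrichment
# ---------------------------------------------------------------------------

def _validate_partition(states: pd.DataFrame) -> dict[str, int]:
    """Check the state segments tile each chromosome exactly once; return
    chromosome lengths."""
    lengths = {}
    for chrom, sub in states.groupby("chrom"):
        sub = sub.sort_values("start")
        pos = int(sub["start"].iloc[0])
        if pos != 0:
            raise ValueError(f"states on {chrom} do not start at 0")
        for s, e in zip(sub["start"], sub["end"]):
            if int(s) != pos:
                raise ValueError(f"states on {chrom} have a gap/overlap at {pos}")
            pos = int(e)
        lengths[chrom] = pos
    return lengths


def state_enrichment(
    peaks: PeakSet,
    states: pd.DataFrame,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Enrichment of peaks across a chromatin-state partition.

    *states* has columns chrom/start/end/state and must partition every
    chromosome. A peak belongs to the state containing its midpoint.
    Expected counts come from ``n_shuffles`` uniform random placements of
    equally long peaks over the same chromosomes (two-sided empirical p,
    add-one corrected); with ``n_shuffles=0`` the analytic expectation
    (state coverage fraction x peak count) is used and p is NaN.
    """
    lengths = _validate_partition(states)
    labels = sorted(states["state"].unique())

    def count_by_state(mids: Mapping[str, np.ndarray]) -> pd.Series:
        counts = pd.Series(0, index=labels, dtype=int)
        for chrom, sub in states.groupby("chrom"):
            m = mids.get(chrom)
            if m is None or len(m) == 0:
                continue
            sub = sub.sort_values("start")
            idx = np.searchsorted(sub["end"].to_numpy(), m, side="right")
            idx = np.clip(idx, 0, len(sub) - 1)
            for state, cnt in zip(*np.unique(sub["state"].to_numpy()[idx],
                                             return_counts=True)):
                counts[state] += int(cnt)
        return counts

    obs_mids = {
        chrom: np.array([p.midpoint for p in plist])
        for chrom, plist in peaks.by_chrom().items()
    }
    observed = count_by_state(obs_mids)
    n_peaks = len(peaks)

    genome = sum(lengths.values())
    coverage = states.assign(width=states["end"] - states["start"]).groupby(
        "state"
    )["width"].sum().reindex(labels) / genome

    if n_shuffles == 0:
        expected = coverage * n_peaks
        fold = observed / expected.where(expected > 0)
        return pd.DataFrame(
            {"observed": observed, "expected": expected, "fold": fold,
             "p": np.nan}
        ).rename_axis("state")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = sorted(lengths)
    probs = np.array([lengths[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    peak_lens = np.array([p.length for p in peaks.peaks])
    null = np.zeros((n_shuffles, len(labels)), dtype=int)
    for i in range(n_shuffles):
        chosen = rng.choice(len(chroms), size=n_peaks, p=probs)
        mids: dict[str, list[int]] = {}
        for ci, plen in zip(chosen, peak_lens):
            chrom = chroms[ci]
            hi = max(1, lengths[chrom] - plen)
            start = int(rng.integers(0, hi))
            mids.setdefault(chrom, []).append(start + plen // 2)
        null[i] = count_by_state(
            {c: np.asarray(v) for c, v in mids.items()}
        ).to_numpy()

    expected = null.mean(axis=0)
    obs = observed.to_numpy()
    dev = np.abs(null - expected)
    p = (1.0 + (dev >= np.abs(obs - expected)).sum(axis=0)) / (n_shuffles + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = np.where(expected > 0, obs / expected, np.nan)
    return pd.DataFrame(
        {"observed": obs, "expected": expected, "fold": fold, "p": p},
        index=pd.Index(labels, name="state"),
    )


# ---------------------------------------------------------------------------
# Peak-to-gene mapping and set overlap
# ---------------------------------------------------------------------------

def peaks_to_genes(
    annots: Sequence[PeakAnnotation],
    name: str = "peak_genes",
    include_distal: bool = False,
) -> GeneSet:
    """Genes with >=1 assigned peak in a non-distal category (optionally
    including distal peaks via their nearest gene)."""
    members = {
        a.nearest_gene
        for a in annots
        if a.nearest_gene is not None
        and (include_distal or a.category != "distal_intergenic")
    }
    return GeneSet(name, members)


def set_overlap_test(a: GeneSet, b: GeneSet, universe_n: int) -> dict:
    """Upper-tail hypergeometric test of |a & b| given a universe of size N.

    p = P[X >= k] with X ~ Hypergeom(N, |a|, |b|). The universe must be
    stated explicitly; p depends strongly on it. Also reports the Jaccard
    index.
    """
    if len(a) > universe_n or len(b) > universe_n:
        raise ValueError("set larger than universe")
    k = len(a.members & b.members)
    if k > min(len(a), len(b)):
        raise ValueError("overlap exceeds smaller set")  # unreachable by construction
    p = float(stats.hypergeom.sf(k - 1, universe_n, len(a), len(b)))
    union = len(a.members | b.members)
    return {
        "set_a": a.name,
        "set_b": b.name,
        "n_a": len(a),
        "n_b": len(b),
        "k_overlap": k,
        "universe_n": universe_n,
        "p_hypergeom": p,
        "jaccard": k / union if union else 0.0,
    }


def three_way_overlap(a: GeneSet, b: GeneSet, c: GeneSet) -> dict:
    """Venn counts for three gene sets (7 disjoint regions + pair totals)."""
    A, B, C = a.members, b.members, c.members
    return {
        "n_a": len(A), "n_b": len(B), "n_c": len(C),
        "ab": len(A & B), "ac": len(A & C), "bc": len(B & C),
        "abc": len(A & B & C),
        "a_only": len(A - B - C),
        "b_only": len(B - A - C),
        "c_only": len(C - A - B),
        "ab_only": len((A & B) - C),
        "ac_only": len((A & C) - B),
        "bc_only": len((B & C) - A),
    }
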