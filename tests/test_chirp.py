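"""ChIRP post-processing: replicate consensus, feature annotation,
chromatin-state enrichment and gene-set overlap statistics, each checked
against an independent brute-force oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lincscout.chirp import (
    CATEGORIES,
    GeneSet,
    annotate_peak,
    annotate_peaks,
    annotation_summary,
    peaks_to_genes,
    replicate_consensus,
    set_overlap_test,
    state_enrichment,
    three_way_overlap,
)
from lincscout.genome import GeneAnnotation, GenomicInterval, PeakSet, TranscriptModel

from conftest import random_annotation


def _random_peaks(rng, n, genome_bp=500_000, n_chroms=2, name="x"):
    peaks = []
    for _ in range(n):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        start = int(rng.integers(0, genome_bp - 2000))
        peaks.append(GenomicInterval(chrom, start, start + int(rng.integers(50, 1500))))
    return PeakSet(name, peaks)


def _covered_bases(peaks) -> set:
    out = set()
    for p in peaks:
        out |= {(p.chrom, i) for i in range(p.start, p.end)}
    return out


class TestReplicateConsensus:
    def test_identical_replicates_idempotent(self):
        rng = np.random.default_rng(31)
        rep = _random_peaks(rng, 50)
        cons = replicate_consensus(rep, rep)
        assert _covered_bases(cons) == _covered_bases(rep)
        # output is coalesced: no two output peaks overlap
        for a, b in itertools.combinations(cons.peaks, 2):
            assert a.chrom != b.chrom or min(a.end, b.end) <= max(a.start, b.start)

    def test_disjoint_replicates_empty(self):
        r1 = PeakSet("a", [GenomicInterval("chr1", 0, 100)])
        r2 = PeakSet("b", [GenomicInterval("chr1", 200, 300)])
        assert len(replicate_consensus(r1, r2)) == 0

    def test_matches_brute_force_base_cover(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            r1 = _random_peaks(rng, 200, genome_bp=200_000)
            r2 = _random_peaks(rng, 200, genome_bp=200_000)
            cons = replicate_consensus(r1, r2, merge="union")
            expected = set()
            for p in r1:
                partners = [q for q in r2
                            if q.chrom == p.chrom
                            and min(p.end, q.end) - max(p.start, q.start) >= 1]
                if partners:
                    lo = min([p.start] + [q.start for q in partners])
                    hi = max([p.end] + [q.end for q in partners])
                    expected |= {(p.chrom, i) for i in range(lo, hi)}
            assert _covered_bases(cons) == expected

    def test_intersection_merge_within_both_replicates(self):
        r1 = PeakSet("a", [GenomicInterval("chr1", 100, 300)])
        r2 = PeakSet("b", [GenomicInterval("chr1", 200, 500)])
        cons = replicate_consensus(r1, r2, merge="intersection")
        assert [(p.start, p.end) for p in cons.peaks] == [(200, 300)]

    def test_min_overlap_bp_respected(self):
        r1 = PeakSet("a", [GenomicInterval("chr1", 100, 200)])
        r2 = PeakSet("b", [GenomicInterval("chr1", 195, 300)])
        assert len(replicate_consensus(r1, r2, min_overlap_bp=5)) == 1
        assert len(replicate_consensus(r1, r2, min_overlap_bp=6)) == 0


def _oracle_category(peak, ann, promoter_bp=3000, downstream_bp=3000):
    """Rasterized per-base category sets, queried in precedence order."""
    base_sets = {c: set() for c in CATEGORIES}
    for t in ann:
        if t.chrom != peak.chrom:
            continue
        base_sets["promoter"] |= set(
            range(max(0, t.tss - promoter_bp), t.tss + promoter_bp + 1))
        for u in t.utr5:
            base_sets["five_utr"] |= set(range(u.start, u.end))
        for u in t.utr3:
            base_sets["three_utr"] |= set(range(u.start, u.end))
        utr = set()
        for u in list(t.utr5) + list(t.utr3):
            utr |= set(range(u.start, u.end))
        for e in t.exons:
            base_sets["exon"] |= set(range(e.start, e.end)) - utr
        span = set(range(t.span.start, t.span.end))
        exonic = set()
        for e in t.exons:
            exonic |= set(range(e.start, e.end))
        base_sets["intron"] |= span - exonic
        if t.strand == "-":
            base_sets["downstream"] |= set(
                range(max(0, t.exons[0].start - downstream_bp), t.exons[0].start))
        else:
            base_sets["downstream"] |= set(
                range(t.exons[-1].end, t.exons[-1].end + downstream_bp))
    span = set(range(peak.start, peak.end))
    for cat in CATEGORIES[:-1]:
        if span & base_sets[cat]:
            return cat
    return "distal_intergenic"


class TestAnnotatePeak:
    @pytest.fixture()
    def big_gene(self):
        """One gene with long introns so every category is reachable."""
        exons = (GenomicInterval("chr1", 50_000, 50_400, "+"),
                 GenomicInterval("chr1", 70_000, 70_500, "+"),
                 GenomicInterval("chr1", 90_000, 90_600, "+"))
        return GeneAnnotation([TranscriptModel(
            "t1", "g1", exons, biotype="protein_coding",
            utr5=(GenomicInterval("chr1", 50_000, 50_100, "+"),),
            utr3=(GenomicInterval("chr1", 90_500, 90_600, "+"),))])

    def test_peak_one_kb_upstream_is_promoter(self, big_gene):
        p = GenomicInterval("chr1", 48_900, 49_100)  # centered 1 kb upstream
        assert annotate_peak(p, big_gene).category == "promoter"

    def test_far_peak_is_distal_intergenic(self, big_gene):
        p = GenomicInterval("chr1", 300_000, 300_400)  # >3 kb from TSS/TES
        assert annotate_peak(p, big_gene).category == "distal_intergenic"

    def test_deep_intron_peak_is_intron(self, big_gene):
        p = GenomicInterval("chr1", 60_000, 60_300)  # >3 kb past the TSS
        assert annotate_peak(p, big_gene).category == "intron"

    def test_downstream_peak(self, big_gene):
        p = GenomicInterval("chr1", 91_000, 91_200)  # <3 kb past the TES
        ann = annotate_peak(p, big_gene)
        # promoter window around TES side does not apply; downstream does,
        # but the 3'-most exon region is 3 kb from TSS so promoter never hits
        assert ann.category == "downstream"

    def test_utr_precedence_over_exon(self, big_gene):
        p = GenomicInterval("chr1", 90_520, 90_580)
        got = annotate_peak(p, big_gene, promoter_bp=100)
        assert got.category == "three_utr"

    def test_categories_partition_peak_set(self, bundle):
        from lincscout.chirp import replicate_consensus

        cons = replicate_consensus(bundle["chirp_rep1"], bundle["chirp_rep2"])
        annots = annotate_peaks(cons, bundle["reference"])
        assert annotation_summary(annots).sum() == len(cons)

    def test_matches_rasterized_oracle_on_random_fixture(self):
        rng = np.random.default_rng(41)
        for _ in range(5):
            ann = random_annotation(rng, n_genes=6, genome_bp=150_000, n_chroms=1)
            peaks = _random_peaks(rng, 20, genome_bp=150_000, n_chroms=1)
            for p in peaks:
                got = annotate_peak(p, ann).category
                assert got == _oracle_category(p, ann), (p, got)


class TestStateEnrichment:
    def _states(self, fractions: dict[str, float], chrom_bp=100_000):
        rows, pos = [], 0
        for state, frac in fractions.items():
            end = pos + int(frac * chrom_bp)
            rows.append({"chrom": "chr1", "start": pos, "end": end, "state": state})
            pos = end
        rows[-1]["end"] = chrom_bp
        return pd.DataFrame(rows)

    def test_analytic_fallback_expected_counts(self):
        states = self._states({"a": 0.1, "b": 0.9})
        peaks = PeakSet("x", [GenomicInterval("chr1", i * 1000, i * 1000 + 100)
                              for i in range(50)])
        out = state_enrichment(peaks, states, n_shuffles=0)
        assert out.loc["a", "expected"] == pytest.approx(5.0)
        assert out.loc["b", "expected"] == pytest.approx(45.0)

    def test_concentrated_peaks_fold_near_ten(self):
        states = self._states({"a": 0.1, "b": 0.9})
        rng = np.random.default_rng(43)
        peaks = PeakSet("x", [
            GenomicInterval("chr1", int(s), int(s) + 50)
            for s in rng.integers(0, 9_000, size=60)])  # all inside state a
        out = state_enrichment(peaks, states, n_shuffles=300, seed=1)
        assert out.loc["a", "fold"] == pytest.approx(10.0, rel=0.15)
        assert out.loc["a", "p"] < 0.01

    def test_uniform_peaks_fold_near_one(self):
        states = self._states({"a": 0.5, "b": 0.5})
        rng = np.random.default_rng(47)
        peaks = PeakSet("x", [
            GenomicInterval("chr1", int(s), int(s) + 50)
            for s in rng.integers(0, 99_000, size=400)])
        out = state_enrichment(peaks, states, n_shuffles=200, seed=2)
        assert np.allclose(out["fold"], 1.0, atol=0.15)

    def test_non_partition_rejected(self):
        states = pd.DataFrame([
            {"chrom": "chr1", "start": 0, "end": 50, "state": "a"},
            {"chrom": "chr1", "start": 60, "end": 100, "state": "b"}])
        with pytest.raises(ValueError):
            state_enrichment(PeakSet("x", []), states, n_shuffles=0)


class TestGeneSets:
    def test_no_peaks_empty_set(self):
        assert len(peaks_to_genes([])) == 0

    def test_gene_counted_once_for_multiple_peaks(self, bundle):
        cons = replicate_consensus(bundle["chirp_rep1"], bundle["chirp_rep2"])
        annots = annotate_peaks(cons, bundle["reference"])
        gs = peaks_to_genes(annots)
        assert len(gs.members) == len(set(gs.members))
        assert gs.members == frozenset(bundle["truth"].chirp_target_genes)

    def test_hypergeometric_closed_form(self):
        a = GeneSet("a", {"g1", "g2", "g3"})
        b = GeneSet("b", {"g1", "g2", "g3"})
        out = set_overlap_test(a, b, universe_n=10)
        assert out["k_overlap"] == 3
        assert out["p_hypergeom"] == pytest.approx(1 / 120)

    def test_zero_overlap_p_one(self):
        a = GeneSet("a", {"g1", "g2"})
        b = GeneSet("b", {"g3", "g4"})
        assert set_overlap_test(a, b, 10)["p_hypergeom"] == pytest.approx(1.0)

    def test_p_matches_exhaustive_enumeration_small_universes(self):
        for n in (5, 8):
            universe = list(range(n))
            for na in range(n + 1):
                a = GeneSet("a", set(universe[:na]))
                for nb in range(n + 1):
                    tail_counts = {}
                    total = 0
                    for combo in itertools.combinations(universe, nb):
                        k = len(a.members & set(combo))
                        tail_counts[k] = tail_counts.get(k, 0) + 1
                        total += 1
                    for k in range(max(0, na + nb - n), min(na, nb) + 1):
                        enum_p = sum(c for kk, c in tail_counts.items()
                                     if kk >= k) / total
                        b = GeneSet("b", set(universe[:k])
                                    | set(universe[na:na + nb - k]))
                        assert len(b) == nb
                        got = set_overlap_test(a, b, n)
                        assert got["k_overlap"] == k
                        assert got["p_hypergeom"] == pytest.approx(enum_p)

    def test_p_monotone_decreasing_in_overlap(self):
        n, na, nb = 30, 10, 12
        last = 2.0
        for k in range(min(na, nb) + 1):
            a = GeneSet("a", set(range(na)))
            b = GeneSet("b", set(range(k)) | set(range(na, na + nb - k)))
            p = set_overlap_test(a, b, n)["p_hypergeom"]
            assert p <= last + 1e-12
            last = p

    def test_set_larger_than_universe_rejected(self):
        with pytest.raises(ValueError):
            set_overlap_test(GeneSet("a", set(range(11))), GeneSet("b", set()), 10)

    def test_three_way_overlap_counts(self):
        a = GeneSet("a", {"1", "2", "3", "4"})
        b = GeneSet("b", {"3", "4", "5"})
        c = GeneSet("c", {"4", "5", "6"})
        out = three_way_overlap(a, b, c)
        assert out["abc"] == 1
        assert out["ab"] == 2 and out["bc"] == 2 and out["ac"] == 1
        assert out["a_only"] == 2 and out["c_only"] == 1
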