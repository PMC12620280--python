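"""Core genomic data model: intervals, transcripts, annotations, peak sets.

All internal coordinates are 0-based half-open ``[start, end)`` regardless of
source format. GTF (1-based closed) is converted on read and write; BED and
narrowPeak are native. Chromosome names are kept verbatim — no "chr"-prefix
harmonization is applied unless requested explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneAnnotation",
    "PeakSet",
    "overlaps",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def overlaps(
    a: GenomicInterval,
    b: GenomicInterval,
    min_bp: int = 1,
    stranded: bool = False,
) -> bool:
    """True iff *a* and *b* share >= ``min_bp`` bases (same chromosome).

    Strand is ignored unless ``stranded``; in stranded mode intervals on
    different explicit strands never overlap ('.' matches either strand).
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    if stranded and a.strand != b.strand and "." not in (a.strand, b.strand):
        return False
    return a.overlap_length(b) >= min_bp


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware exon-chain transcript.

    Exons are sorted by start, pairwise disjoint and share one chromosome and
    strand. TSS/TES follow transcription direction: on '-' the TSS is the
    last base of the rightmost exon.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "transcript"
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has zero exons")
        object.__setattr__(self, "exons", tuple(self.exons))
        object.__setattr__(self, "utr5", tuple(self.utr5))
        object.__setattr__(self, "utr3", tuple(self.utr3))
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons span multiple "
                "chromosomes or strands"
            )
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon chain not sorted "
                    "and disjoint"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def max_exon_length(self) -> int:
        return max(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def tss(self) -> int:
        """First transcribed base (0-based position)."""
        if self.strand == "-":
            return self.exons[-1].end - 1
        return self.exons[0].start

    @property
    def tes(self) -> int:
        """Last transcribed base (0-based position)."""
        if self.strand == "-":
            return self.exons[0].start
        return self.exons[-1].end - 1

    def introns(self) -> list[GenomicInterval]:
        out = []
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start > prev.end:
                out.append(
                    GenomicInterval(self.chrom, prev.end, cur.start, self.strand)
                )
        return out


class GeneAnnotation:
    """A collection of transcripts with per-gene spans and interval indexes.

    Gene spans are derived as (min start, max end) over each gene's
    transcripts. Two per-chromosome interval trees are maintained — gene
    spans and individual exons — so intergenic classification can run in
    either mode.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]) -> None:
        self.transcripts: dict[str, TranscriptModel] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript_id {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
        self.gene_spans: dict[str, GenomicInterval] = {}
        for t in self.transcripts.values():
            cur = self.gene_spans.get(t.gene_id)
            s = t.span
            if cur is None:
                self.gene_spans[t.gene_id] = s
            else:
                if cur.chrom != s.chrom:
                    raise ValueError(f"gene {t.gene_id} spans chromosomes")
                self.gene_spans[t.gene_id] = GenomicInterval(
                    cur.chrom,
                    min(cur.start, s.start),
                    max(cur.end, s.end),
                    cur.strand if cur.strand == s.strand else ".",
                )
        self._span_index: dict[str, IntervalTree] = {}
        self._exon_index: dict[str, IntervalTree] = {}
        for gid, span in self.gene_spans.items():
            self._span_index.setdefault(span.chrom, IntervalTree()).addi(
                span.start, span.end, (gid, span.strand)
            )
        for t in self.transcripts.values():
            tree = self._exon_index.setdefault(t.chrom, IntervalTree())
            for e in t.exons:
                tree.addi(e.start, e.end, (t.gene_id, e.strand))

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.gene_spans)

    def chromosomes(self) -> list[str]:
        return sorted({t.chrom for t in self})

    def query_genes(
        self,
        region: GenomicInterval,
        mode: str = "gene_span",
        stranded: bool = False,
    ) -> set[str]:
        """Gene ids whose span (or any exon) overlaps *region*."""
        index = self._span_index if mode == "gene_span" else self._exon_index
        if mode not in ("gene_span", "exonic"):
            raise ValueError(f"unknown mode {mode!r}")
        tree = index.get(region.chrom)
        if tree is None:
            return set()
        hits = set()
        for iv in tree.overlap(region.start, region.end):
            gid, strand = iv.data
            if stranded and strand != region.strand and "." not in (
                strand,
                region.strand,
            ):
                continue
            hits.add(gid)
        return hits


def classify_location(
    t: TranscriptModel,
    ann: GeneAnnotation,
    mode: str = "gene_span",
    stranded: bool = False,
) -> str:
    """Classify a transcript as ``intergenic`` or ``genic_overlap``.

    A transcript is intergenic iff none of its exons overlaps any annotated
    gene — the full gene interval in ``gene_span`` mode (introns count as
    genic), annotated exons only in ``exonic`` mode. The default is
    strand-agnostic gene-span overlap: a lincRNA must not touch any
    annotated locus on either strand.
    """
    if t.chrom not in {s.chrom for s in ann.gene_spans.values()}:
        logger.warning(
            "chromosome %s of transcript %s absent from annotation; "
            "treated as intergenic",
            t.chrom,
            t.transcript_id,
        )
        return "intergenic"
    for exon in t.exons:
        if ann.query_genes(exon, mode=mode, stranded=stranded):
            return "genic_overlap"
    return "intergenic"


@dataclass
class PeakSet:
    """A named collection of peaks, sorted within each chromosome."""

    name: str
    peaks: list[GenomicInterval] = field(default_factory=list)
    scores: list[float] | None = None
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.scores is not None:
            if len(self.scores) != len(self.peaks):
                raise ValueError("scores length must match peaks length")
            for s in self.scores:
                if not pd.notna(s) or s in (float("inf"), float("-inf")):
                    raise ValueError("peak scores must be finite")
        order = sorted(
            range(len(self.peaks)),
            key=lambda i: (self.peaks[i].chrom, self.peaks[i].start, self.peaks[i].end),
        )
        self.peaks = [self.peaks[i] for i in order]
        if self.scores is not None:
            self.scores = [self.scores[i] for i in order]

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.peaks)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out

    def any_overlap(self, region: GenomicInterval, min_bp: int = 1) -> bool:
        return any(overlaps(p, region, min_bp=min_bp) for p in self.peaks)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> GeneAnnotation:
    """Read a GTF file (1-based closed) into a :class:`GeneAnnotation`.

    Exon features are assembled into transcripts keyed by ``transcript_id``;
    ``five_prime_utr``/``three_prime_utr`` features, when present, populate
    the transcript's UTR intervals. Coordinates are converted to 0-based
    half-open on read.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
    except Exception as exc:  # gffutils reports the offending line
        raise ValueError(f"malformed GTF {path}: {exc}") from exc

    exons: dict[str, list] = {}
    meta: dict[str, dict] = {}
    utrs: dict[str, dict[str, list]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "five_prime_utr", "three_prime_utr"):
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise ValueError(
                f"GTF feature at {feat.seqid}:{feat.start} missing {exc}"
            ) from exc
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(iv)
            biotype = feat.attributes.get(
                "transcript_biotype", feat.attributes.get("gene_biotype", ["transcript"])
            )[0]
            meta[tid] = {"gene_id": gid, "biotype": biotype}
        else:
            key = "utr5" if feat.featuretype == "five_prime_utr" else "utr3"
            utrs.setdefault(tid, {"utr5": [], "utr3": []})[key].append(iv)

    transcripts = []
    for tid, exon_list in exons.items():
        exon_list.sort(key=lambda e: e.start)
        u = utrs.get(tid, {"utr5": [], "utr3": []})
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=meta[tid]["gene_id"],
                exons=tuple(exon_list),
                biotype=meta[tid]["biotype"],
                utr5=tuple(sorted(u["utr5"], key=lambda e: e.start)),
                utr3=tuple(sorted(u["utr3"], key=lambda e: e.start)),
            )
        )
    return GeneAnnotation(transcripts)


def write_gtf(ann: GeneAnnotation, path: str | Path, source: str = "lincscout") -> None:
    """Write a :class:`GeneAnnotation` as GTF (converting to 1-based closed)."""
    path = Path(path)
    with path.open("w") as fh:
        for tid in sorted(ann.transcripts):
            t = ann.transcripts[tid]
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_biotype "{t.biotype}";'
            )
            for kind, ivs in (
                ("exon", t.exons),
                ("five_prime_utr", t.utr5),
                ("three_prime_utr", t.utr3),
            ):
                for iv in ivs:
                    fh.write(
                        f"{iv.chrom}\t{source}\t{kind}\t{iv.start + 1}\t{iv.end}"
                        f"\t.\t{iv.strand}\t.\t{attrs}\n"
                    )


def read_bed(path: str | Path, name: str = "", replicate_id: str = "") -> PeakSet:
    """Read BED or narrowPeak (both 0-based half-open) into a :class:`PeakSet`.

    For narrowPeak input (>= 7 columns) the signalValue column is stored as
    the peak score; for plain BED with >= 5 columns the BED score column is
    used; 3-column BED yields scoreless peaks.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = name or path.stem
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return PeakSet(name=name, peaks=[], replicate_id=replicate_id)
    peaks, scores = [], []
    for row in df.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        if start >= end:
            raise ValueError(f"{path}: invalid interval {chrom}:{start}-{end}")
        strand = "."
        if len(row) >= 6 and str(row[5]) in ("+", "-"):
            strand = str(row[5])
        peaks.append(GenomicInterval(chrom, start, end, strand))
        if len(row) >= 7:
            scores.append(float(row[6]))
        elif len(row) >= 5:
            scores.append(float(row[4]))
    return PeakSet(
        name=name,
        peaks=peaks,
        scores=scores if len(scores) == len(peaks) else None,
        replicate_id=replicate_id,
    )


def write_bed(ps: PeakSet, path: str | Path, narrowpeak: bool = False) -> None:
    """Write a :class:`PeakSet` as BED6 or narrowPeak (BED6+4)."""
    path = Path(path)
    with path.open("w") as fh:
        for i, p in enumerate(ps.peaks):
            score = ps.scores[i] if ps.scores is not None else 0.0
            if narrowpeak:
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{ps.name}_{i}\t0\t{p.strand}"
                    f"\t{score:g}\t-1\t-1\t-1\n"
                )
            else:
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{ps.name}_{i}\t{score:g}"
                    f"\t{p.strand}\n"
                )
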