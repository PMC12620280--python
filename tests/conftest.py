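"""Shared fixtures: tiny hand-built annotations and one session-scoped
synthetic study bundle (seed 0) reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from lincscout.genome import GeneAnnotation, GenomicInterval, TranscriptModel
from lincscout.simulate import SimConfig, generate_all


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study at seed 0 (10 candidates, 5 decoys/class)."""
    return generate_all(SimConfig(seed=0))


@pytest.fixture()
def tiny_annotation() -> GeneAnnotation:
    """Two genes on chr1 (one per strand, with UTRs), one gene on chr2."""
    def coding(tid, gid, chrom, exon_coords, strand):
        exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_coords)
        first, last = exons[0], exons[-1]
        if strand == "+":
            utr5 = (GenomicInterval(chrom, first.start, first.start + 50, strand),)
            utr3 = (GenomicInterval(chrom, last.end - 50, last.end, strand),)
        else:
            utr5 = (GenomicInterval(chrom, last.end - 50, last.end, strand),)
            utr3 = (GenomicInterval(chrom, first.start, first.start + 50, strand),)
        return TranscriptModel(tid, gid, exons, biotype="protein_coding",
                               utr5=utr5, utr3=utr3)

    return GeneAnnotation([
        coding("tA", "geneA", "chr1", [(10_000, 10_400), (12_000, 12_500),
                                       (20_000, 20_600)], "+"),
        coding("tB", "geneB", "chr1", [(50_000, 50_300), (58_000, 58_400)], "-"),
        coding("tC", "geneC", "chr2", [(5_000, 5_200), (9_000, 9_300)], "+"),
    ])


def random_annotation(rng: np.random.Generator, n_genes: int = 15,
                      genome_bp: int = 500_000, n_chroms: int = 2) -> GeneAnnotation:
    """Random multi-exon annotation used by oracle-equivalence tests."""
    transcripts = []
    for i in range(n_genes):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        strand = str(rng.choice(["+", "-"]))
        pos = int(rng.integers(0, genome_bp - 20_000))
        exons = []
        for _ in range(int(rng.integers(1, 5))):
            length = int(rng.integers(100, 1000))
            exons.append(GenomicInterval(chrom, pos, pos + length, strand))
            pos += length + int(rng.integers(100, 3000))
        transcripts.append(
            TranscriptModel(f"t{i}", f"g{i}", tuple(exons))
        )
    return GeneAnnotation(transcripts)


def random_transcript(rng: np.random.Generator, genome_bp: int = 500_000,
                      n_chroms: int = 2) -> TranscriptModel:
    chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
    strand = str(rng.choice(["+", "-"]))
    pos = int(rng.integers(0, genome_bp - 10_000))
    exons = []
    for _ in range(int(rng.integers(1, 4))):
        length = int(rng.integers(80, 600))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(100, 2000))
    return TranscriptModel("query", "query_gene", tuple(exons))
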