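"""Synthetic study generator with planted ground truth.

Emulates the inputs of an AML-versus-normal-bone-marrow lncRNA discovery
study on a small multi-chromosome genome: a reference annotation of
multi-exon genes, an assembled-transcript set containing planted intergenic
multi-exon candidates plus decoys that each violate exactly one discovery
criterion, negative-binomial count matrices with planted fold changes,
TSS-supporting DNase/H3K4me3 tracks, two jittered ChIRP replicates with a
chromatin-state partition, an exponential-survival cohort with a planted
hazard ratio and mutation flags, and 4PL dose-response plates with a
planted differential drug-sensitivity score.

The genome is laid out in fixed-width slots: even slots host reference
genes, odd slots host novel transcripts, so intergenicity (and its
violation by the "genic" decoy class) holds by construction. All outputs
are pure functions of (config, seed); one root seed streams per-component
sub-seeds so stages can be regenerated independently.

Decoy classes and the single criterion each violates:

========================  =============================================
class                     violated criterion
========================  =============================================
``too_short``             spliced length <= 200 bp
``genic``                 overlaps a reference gene
``low_expression``        mean RPKM < 0.5 in both groups
``no_marks``              no DNase / H3K4me3 peak near the TSS
``single_exon``           one exon only
``monster_exon``          one exon longer than the plausibility bound
``not_DE``                log2 fold change = 0 between groups
========================  =============================================
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .drugs import DoseResponsePlate, dss, four_pl
from .expression import ExpressionMatrix
from .genome import GeneAnnotation, GenomicInterval, PeakSet, TranscriptModel
from .cohort import SurvivalRecord

DECOY_CLASSES = (
    "too_short",
    "genic",
    "low_expression",
    "no_marks",
    "single_exon",
    "monster_exon",
    "not_DE",
)

STATE_NAMES = ("active_tss", "enhancer", "transcribed", "polycomb", "quiescent")
STATE_PROBS = (0.05, 0.10, 0.20, 0.15, 0.50)

MUTATIONS = ("NPM1", "IDH2_R140", "IDH2_R172", "FLT3_ITD", "PML_RARA")


@dataclass
class SimConfig:
    """Study-scale parameters of the synthetic cohort."""

    # genome layout
    n_chroms: int = 3
    chrom_length: int = 2_000_000
    slot_bp: int = 12_000
    # annotation scale
    n_genes: int = 200
    n_candidates: int = 10
    n_decoys_per_class: int = 5
    # RNA-seq cohort
    n_samples_a: int = 20          # AML-like
    n_samples_b: int = 10          # NBM-like
    group_a: str = "AML"
    group_b: str = "NBM"
    dispersion: float = 0.02       # NB: var = mu + mu^2 * dispersion
    gene_mean_range: tuple[float, float] = (200.0, 2000.0)
    novel_mean_range: tuple[float, float] = (30.0, 100.0)
    low_expr_mean: float = 0.002
    log2fc_range: tuple[float, float] = (2.0, 4.0)
    # epigenomic tracks
    peak_halfwidth: int = 300
    tss_window: int = 1_000
    n_background_peaks: int = 150
    # ChIRP
    n_chirp_targets: int = 40
    n_chirp_noise: int = 25
    chirp_jitter: int = 50
    chirp_width: int = 400
    # chromatin states
    state_tile_bp: int = 50_000
    # clinical cohort
    n_patients: int = 300
    survival_beta: float = math.log(0.63)  # log HR, high vs low expressors
    baseline_hazard: float = 1.0 / 1000.0  # per day
    transplant_fraction: float = 0.25
    # drug screen
    target_sdss: float = 1.6
    n_null_drugs: int = 4
    drug_noise_sd: float = 1.0
    top_concentration_um: float = 15.0
    n_doses: int = 8
    dilution: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for name in ("n_genes", "n_candidates", "n_decoys_per_class",
                     "n_samples_a", "n_samples_b", "n_patients"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_gene_slots = self.n_chroms * (self.chrom_length // self.slot_bp) // 2
        n_novel = self.n_candidates + len(DECOY_CLASSES) * self.n_decoys_per_class
        if self.n_genes > n_gene_slots or n_novel > n_gene_slots:
            raise ValueError(
                "genome too small for the requested annotation; increase "
                "chrom_length or n_chroms"
            )

    def rngs(self) -> dict[str, np.random.Generator]:
        """Named per-component generators streamed from the root seed."""
        names = ("reference", "counts", "tracks", "chirp", "cohort", "drugs")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class TruthManifest:
    """Planted ground truth; fully determines cascade expectations."""

    seed: int
    planted_candidates: dict[str, float]          # transcript_id -> log2FC
    decoys: dict[str, str]                        # transcript_id -> violated criterion
    chirp_consensus: list[tuple[str, int, int]]   # (chrom, start, end)
    chirp_target_genes: list[str]
    survival_beta: float
    drug_dss: dict[str, dict[str, float]]         # drug -> group -> noiseless DSS
    differential_drug: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        d = json.loads(Path(path).read_text())
        d["chirp_consensus"] = [tuple(x) for x in d["chirp_consensus"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _slot_coords(cfg: SimConfig, slot: int) -> tuple[str, int]:
    per_chrom = cfg.chrom_length // cfg.slot_bp
    chrom = f"chr{slot // per_chrom + 1}"
    return chrom, (slot % per_chrom) * cfg.slot_bp


def _make_gene(cfg: SimConfig, slot: int, gid: str,
               rng: np.random.Generator) -> TranscriptModel:
    chrom, s0 = _slot_coords(cfg, slot)
    strand = rng.choice(["+", "-"])
    pos = s0 + 1000 + int(rng.integers(0, 500))
    n_ex = int(rng.integers(3, 6))
    exons = []
    for _ in range(n_ex):
        length = int(rng.integers(150, 401))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(300, 801))
    first, last = exons[0], exons[-1]
    if strand == "+":
        utr5 = (GenomicInterval(chrom, first.start, first.start + 100, strand),)
        utr3 = (GenomicInterval(chrom, last.end - 100, last.end, strand),)
    else:
        utr5 = (GenomicInterval(chrom, last.end - 100, last.end, strand),)
        utr3 = (GenomicInterval(chrom, first.start, first.start + 100, strand),)
    return TranscriptModel(f"{gid}.t1", gid, tuple(exons), biotype="protein_coding",
                           utr5=utr5, utr3=utr3)


def _make_novel(cfg: SimConfig, slot: int, tid: str, kind: str,
                rng: np.random.Generator,
                host: TranscriptModel | None = None) -> TranscriptModel:
    chrom, s0 = _slot_coords(cfg, slot)
    strand = rng.choice(["+", "-"])
    if kind == "genic":
        # planted inside/over the host gene's span
        assert host is not None
        pos = host.span.start + 10
        chrom, strand = host.chrom, host.strand
        ex1 = GenomicInterval(chrom, pos, pos + 200, strand)
        ex2 = GenomicInterval(chrom, ex1.end + 300, ex1.end + 500, strand)
        exons = (ex1, ex2)
    elif kind == "too_short":
        pos = s0 + 2000 + int(rng.integers(0, 500))
        ex1 = GenomicInterval(chrom, pos, pos + 80, strand)
        ex2 = GenomicInterval(chrom, ex1.end + 300, ex1.end + 400, strand)
        exons = (ex1, ex2)
    elif kind == "single_exon":
        pos = s0 + 2000 + int(rng.integers(0, 500))
        exons = (GenomicInterval(chrom, pos, pos + 800, strand),)
    elif kind == "monster_exon":
        pos = s0 + 500
        ex1 = GenomicInterval(chrom, pos, pos + 200, strand)
        ex2 = GenomicInterval(chrom, ex1.end + 300, ex1.end + 300 + 10_500, strand)
        exons = (ex1, ex2)
    else:  # candidate geometry (also low_expression / no_marks / not_DE)
        pos = s0 + 2000 + int(rng.integers(0, 500))
        exons = []
        for _ in range(int(rng.integers(3, 5))):
            length = int(rng.integers(150, 401))
            exons.append(GenomicInterval(chrom, pos, pos + length, strand))
            pos += length + int(rng.integers(200, 601))
        exons = tuple(exons)
    return TranscriptModel(tid, f"XLOC_{tid}", tuple(exons), biotype="lncRNA")


def generate_reference(cfg: SimConfig) -> tuple[GeneAnnotation, GeneAnnotation]:
    """Build the reference gene annotation and the assembled-transcript set.

    Returns ``(reference, assembled)``. Assembled transcript ids encode the
    planted role: ``CAND_xx`` for candidates and ``DECOY_<class>_xx`` for
    decoys.
    """
    rng = cfg.rngs()["reference"]
    per_chrom = cfg.chrom_length // cfg.slot_bp
    n_slots = cfg.n_chroms * per_chrom
    gene_slots = [s for s in range(n_slots) if s % 2 == 0][: cfg.n_genes]
    novel_slots = [s for s in range(n_slots) if s % 2 == 1]

    genes = [
        _make_gene(cfg, slot, f"GENE_{i:04d}", rng)
        for i, slot in enumerate(gene_slots)
    ]
    reference = GeneAnnotation(genes)

    assembled: list[TranscriptModel] = []
    cursor = 0
    for i in range(cfg.n_candidates):
        assembled.append(
            _make_novel(cfg, novel_slots[cursor], f"CAND_{i:02d}", "candidate", rng)
        )
        cursor += 1
    host_idx = 0
    for cls in DECOY_CLASSES:
        for j in range(cfg.n_decoys_per_class):
            tid = f"DECOY_{cls}_{j:02d}"
            host = None
            if cls == "genic":
                host = genes[host_idx]
                host_idx += 1
            assembled.append(_make_novel(cfg, novel_slots[cursor], tid, cls, rng,
                                         host=host))
            cursor += 1
    return reference, GeneAnnotation(assembled)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB draws with var = mu + mu^2 * dispersion (Poisson at mu ~ 0)."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    p = n / (n + np.maximum(mean, 1e-12))
    out = rng.negative_binomial(n, p)
    return np.where(mean <= 0, 0, out)


def generate_counts(
    cfg: SimConfig, reference: GeneAnnotation, assembled: GeneAnnotation
) -> tuple[ExpressionMatrix, ExpressionMatrix, TruthManifest]:
    """Simulate transcript- and exon-level count matrices.

    The transcript matrix covers reference transcripts plus assembled
    transcripts (so library sizes are dominated by the annotated
    transcriptome, as in real quantification); exon-level counts are a
    length-proportional multinomial split of each assembled transcript's
    count, so exon counts sum exactly to the transcript count.
    """
    rng = cfg.rngs()["counts"]
    samples = [f"{cfg.group_a}_{i:02d}" for i in range(cfg.n_samples_a)] + [
        f"{cfg.group_b}_{i:02d}" for i in range(cfg.n_samples_b)
    ]
    groups = {s: (cfg.group_a if s.startswith(cfg.group_a) else cfg.group_b)
              for s in samples}
    is_a = np.array([groups[s] == cfg.group_a for s in samples])

    feature_ids, mean_a, mean_b = [], [], []
    planted: dict[str, float] = {}
    decoys: dict[str, str] = {}

    for t in reference:
        base = float(np.exp(rng.uniform(*np.log(cfg.gene_mean_range))))
        feature_ids.append(t.transcript_id)
        mean_a.append(base)
        mean_b.append(base)

    for t in assembled:
        tid = t.transcript_id
        base = float(np.exp(rng.uniform(*np.log(cfg.novel_mean_range))))
        if tid.startswith("CAND_"):
            # planted |log2FC| with random direction, as in a cohort with
            # both over- and under-expressed transcripts
            fc = float(rng.uniform(*cfg.log2fc_range) * rng.choice([-1.0, 1.0]))
            planted[tid] = fc
            a, b = base * 2.0**fc, base
        else:
            cls = tid.split("_", 1)[1].rsplit("_", 1)[0]
            decoys[tid] = cls
            if cls == "low_expression":
                a = b = cfg.low_expr_mean
            elif cls == "not_DE":
                a = b = base
            else:
                fc = float(rng.uniform(*cfg.log2fc_range) * rng.choice([-1.0, 1.0]))
                a, b = base * 2.0**fc, base
        feature_ids.append(tid)
        mean_a.append(a)
        mean_b.append(b)

    mean_a, mean_b = np.array(mean_a), np.array(mean_b)
    mu = np.where(is_a[None, :], mean_a[:, None], mean_b[:, None])
    counts = _nb_draw(rng, mu, cfg.dispersion)
    tx = ExpressionMatrix(
        pd.DataFrame(counts, index=feature_ids, columns=samples), groups
    )

    # exon-level split for assembled transcripts
    exon_ids, exon_rows = [], []
    for t in assembled:
        lens = np.array([e.length for e in t.exons], dtype=float)
        probs = lens / lens.sum()
        tx_counts = tx.counts.loc[t.transcript_id].to_numpy()
        split = np.stack([rng.multinomial(c, probs) for c in tx_counts], axis=1)
        for i in range(t.n_exons):
            exon_ids.append(f"{t.transcript_id}:exon{i + 1}")
            exon_rows.append(split[i])
    exon_m = ExpressionMatrix(
        pd.DataFrame(np.array(exon_rows), index=exon_ids, columns=samples), groups
    )

    truth = TruthManifest(
        seed=cfg.seed,
        planted_candidates=planted,
        decoys=decoys,
        chirp_consensus=[],
        chirp_target_genes=[],
        survival_beta=cfg.survival_beta,
        drug_dss={},
    )
    return tx, exon_m, truth


def generate_isoform_counts(
    shares: dict[str, float],
    exon_lengths: dict[str, int],
    n_samples: int = 72,
    depth: float = 2000.0,
    dispersion: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> ExpressionMatrix:
    """Exon-level counts with a planted molar usage mixture.

    ``shares`` gives the fraction of transcript molecules initiating (or
    terminating) at each alternative exon; reads per exon scale with
    molarity x exon length, so the length-normalized CPM shares recover the
    planted molar mixture. A high-expressed filler feature stands in for
    the rest of the library.
    """
    if not math.isclose(sum(shares.values()), 1.0, abs_tol=1e-9):
        raise ValueError("shares must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    rows, ids = [], []
    for exon, share in shares.items():
        mu = depth * share * exon_lengths[exon] / 1e3
        rows.append(_nb_draw(rng, np.full(n_samples, mu), dispersion))
        ids.append(exon)
    rows.append(rng.poisson(50 * depth, size=n_samples))
    ids.append("library_filler")
    return ExpressionMatrix(
        pd.DataFrame(np.array(rows), index=ids, columns=samples),
        {s: "AML" for s in samples},
    )


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

def generate_tracks(
    cfg: SimConfig,
    reference: GeneAnnotation,
    assembled: GeneAnnotation,
    truth: TruthManifest,
) -> dict[str, PeakSet]:
    """DNase/H3K4me3 support tracks, two ChIRP replicates and a
    chromatin-state partition (returned under key ``states`` as a
    DataFrame-backed PeakSet substitute; see :func:`generate_states`)."""
    rng = cfg.rngs()["tracks"]
    no_marks_tss = [
        (assembled.transcripts[tid].chrom, assembled.transcripts[tid].tss)
        for tid in truth.decoys
        if truth.decoys[tid] == "no_marks"
    ]

    def forbidden(chrom: str, start: int, end: int) -> bool:
        margin = cfg.tss_window + cfg.peak_halfwidth + 200
        return any(
            c == chrom and start < t + margin and end > t - margin
            for c, t in no_marks_tss
        )

    tracks: dict[str, PeakSet] = {}
    for track in ("dnase", "h3k4me3"):
        peaks = []
        for t in list(reference) + list(assembled):
            tid = t.transcript_id
            if tid in truth.decoys and truth.decoys[tid] == "no_marks":
                continue
            jitter = int(rng.integers(-100, 101))
            center = t.tss + jitter
            peaks.append(
                GenomicInterval(
                    t.chrom,
                    max(0, center - cfg.peak_halfwidth),
                    center + cfg.peak_halfwidth,
                )
            )
        placed = 0
        while placed < cfg.n_background_peaks:
            chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
            start = int(rng.integers(0, cfg.chrom_length - 600))
            if forbidden(chrom, start, start + 600):
                continue
            peaks.append(GenomicInterval(chrom, start, start + 600))
            placed += 1
        tracks[track] = PeakSet(name=track, peaks=peaks)
    return tracks


def generate_chirp(
    cfg: SimConfig, reference: GeneAnnotation, truth: TruthManifest
) -> tuple[PeakSet, PeakSet]:
    """Two ChIRP replicates around a planted consensus.

    Consensus peaks sit in the promoter or first intron of randomly chosen
    reference genes (recorded in the manifest as the planted peak-to-gene
    map); each replicate holds every consensus peak jittered by at most
    ``chirp_jitter`` bp plus replicate-private noise peaks placed in
    disjoint unannotated blocks, so the recovered consensus matches the
    planted set one-to-one.
    """
    rng = cfg.rngs()["chirp"]
    genes = sorted(reference.gene_spans)
    target_gids = sorted(
        rng.choice(genes, size=min(cfg.n_chirp_targets, len(genes)), replace=False)
    )
    consensus: list[GenomicInterval] = []
    target_genes: list[str] = []
    for gid in target_gids:
        t = next(tr for tr in reference if tr.gene_id == gid)
        if rng.random() < 0.5 or len(t.introns()) == 0:
            center = t.tss + int(rng.integers(-200, 201))
        else:
            intron = t.introns()[0]
            center = (intron.start + intron.end) // 2
        half = cfg.chirp_width // 2
        consensus.append(
            GenomicInterval(t.chrom, max(0, center - half), center + half)
        )
        target_genes.append(gid)
    truth.chirp_consensus = [(p.chrom, int(p.start), int(p.end)) for p in consensus]
    truth.chirp_target_genes = [str(g) for g in target_genes]

    # replicate-private noise: disjoint 1 kb blocks in unused gene slots
    per_chrom = cfg.chrom_length // cfg.slot_bp
    n_slots = cfg.n_chroms * per_chrom
    free_slots = [s for s in range(n_slots) if s % 2 == 0][cfg.n_genes:]
    blocks = []
    for s in free_slots:
        chrom, s0 = _slot_coords(cfg, s)
        for off in range(1000, cfg.slot_bp - 2000, 1500):
            blocks.append((chrom, s0 + off))
    rng.shuffle(blocks)

    reps = []
    n_noise = min(cfg.n_chirp_noise, len(blocks) // 2)
    for r in range(2):
        peaks = []
        for p in consensus:
            shift = int(rng.integers(-cfg.chirp_jitter, cfg.chirp_jitter + 1))
            peaks.append(
                GenomicInterval(p.chrom, max(0, p.start + shift), p.end + shift)
            )
        for chrom, start in blocks[r * n_noise:(r + 1) * n_noise]:
            width = int(rng.integers(200, 500))
            peaks.append(GenomicInterval(chrom, start, start + width))
        reps.append(
            PeakSet(name="chirp", peaks=peaks, replicate_id=f"rep{r + 1}",
                    scores=[float(s) for s in rng.uniform(5, 50, len(peaks))])
        )
    return reps[0], reps[1]


def generate_states(cfg: SimConfig) -> pd.DataFrame:
    """Chromatin-state partition: fixed-width tiles labelled by state, tiling
    each chromosome exactly once."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(7)[-1])
    rows = []
    for c in range(1, cfg.n_chroms + 1):
        pos = 0
        while pos < cfg.chrom_length:
            end = min(pos + cfg.state_tile_bp, cfg.chrom_length)
            state = rng.choice(STATE_NAMES, p=STATE_PROBS)
            rows.append({"chrom": f"chr{c}", "start": pos, "end": end,
                         "state": str(state)})
            pos = end
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clinical cohort
# ---------------------------------------------------------------------------

def generate_survival(
    n: int,
    beta: float,
    rng: np.random.Generator,
    baseline_hazard: float = 1.0 / 1000.0,
    covariate: np.ndarray | None = None,
    transplant_fraction: float = 0.0,
) -> list[SurvivalRecord]:
    """Exponential event times with hazard ``baseline * exp(beta * x)`` for a
    binary covariate x, independent uniform administrative censoring and an
    optional transplant-censoring fraction."""
    if covariate is None:
        covariate = (rng.random(n) < 0.5).astype(float)
    hazard = baseline_hazard * np.exp(beta * covariate)
    event_t = rng.exponential(1.0 / hazard)
    censor_t = rng.uniform(300.0, 2500.0, size=n)
    time = np.minimum(event_t, censor_t)
    event = event_t <= censor_t
    has_tx = rng.random(n) < transplant_fraction
    tx_time = rng.uniform(50.0, 600.0, size=n)
    records = []
    for i in range(n):
        records.append(
            SurvivalRecord(
                sample_id=f"P{i:04d}",
                time=float(max(time[i], 1e-3)),
                event=bool(event[i]),
                transplant_time=float(tx_time[i]) if has_tx[i] else None,
                covariates={"x": float(covariate[i])},
            )
        )
    return records


def generate_cohort_metadata(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, list[SurvivalRecord], list[DoseResponsePlate], TruthManifest]:
    """Patient table (expression + mutation flags + subgroup labels),
    survival records, drug plates, and a manifest fragment with the planted
    hazard ratio and drug DSS values."""
    rng = cfg.rngs()["cohort"]
    n = cfg.n_patients

    pml = rng.random(n) < 0.08
    npm1 = rng.random(n) < 0.25
    idh2_r140 = np.where(npm1, rng.random(n) < 0.20, rng.random(n) < 0.06)
    idh2_r172 = (~idh2_r140) & (rng.random(n) < 0.04)
    flt3 = rng.random(n) < 0.25

    # expression mixture on the log2(CPM+1) scale; APL-like and
    # NPM1/IDH2-R140 co-mutant patients are planted as high expressors
    u = rng.random(n)
    expr = np.select(
        [u < 0.35, u < 0.55, u < 0.85],
        [0.0, rng.uniform(1e-3, 0.5, n), rng.uniform(0.5, 2.0, n)],
        default=rng.uniform(2.0, 5.0, n),
    )
    expr = np.where(pml, rng.uniform(2.0, 5.0, n), expr)
    expr = np.where(npm1 & idh2_r140, rng.uniform(1.5, 4.5, n), expr)

    fab = rng.choice(["M0", "M1", "M2", "M3", "M4", "M5"], size=n)
    fab = np.where(pml, "M3", fab)
    risk = rng.choice(["favorable", "intermediate", "adverse"], size=n,
                      p=[0.3, 0.5, 0.2])

    meta = pd.DataFrame(
        {
            "sample_id": [f"P{i:04d}" for i in range(n)],
            "expression": expr,
            "NPM1": npm1,
            "IDH2_R140": idh2_r140,
            "IDH2_R172": idh2_r172,
            "FLT3_ITD": flt3,
            "PML_RARA": pml,
            "FAB": fab,
            "risk_group": risk,
        }
    ).set_index("sample_id")

    high = (expr >= np.median(expr)).astype(float)
    records = generate_survival(
        n,
        cfg.survival_beta,
        rng,
        baseline_hazard=cfg.baseline_hazard,
        covariate=high,
        transplant_fraction=cfg.transplant_fraction,
    )
    for r, (_, row) in zip(records, meta.iterrows()):
        r.covariates.update(
            {
                "high_expressor": r.covariates.pop("x"),
                "NPM1": float(row["NPM1"]),
                "FLT3_ITD": float(row["FLT3_ITD"]),
                "age_scaled": float(rng.normal(0, 1)),
            }
        )

    plates, drug_dss, diff_drug = generate_drug_plates(cfg)
    truth = TruthManifest(
        seed=cfg.seed,
        planted_candidates={},
        decoys={},
        chirp_consensus=[],
        chirp_target_genes=[],
        survival_beta=cfg.survival_beta,
        drug_dss=drug_dss,
        differential_drug=diff_drug,
    )
    return meta, records, plates, truth


# ---------------------------------------------------------------------------
# Drug plates
# ---------------------------------------------------------------------------

def _noiseless_dss(params: tuple[float, float, float, float],
                   conc: np.ndarray) -> float:
    plate = DoseResponsePlate("tmp", "tmp", conc, four_pl(conc, *params))
    return dss(plate)


def generate_drug_plates(
    cfg: SimConfig,
) -> tuple[list[DoseResponsePlate], dict[str, dict[str, float]], str]:
    """4PL viability plates for a KO-vs-WT screen.

    One drug ("ATO-like") is planted with a DSS difference of
    ``cfg.target_sdss`` between KO and WT (the KO IC50 is solved by
    bisection on the noiseless curves); the remaining drugs share identical
    parameters in both groups. Three replicates per (drug, group), Gaussian
    response noise.
    """
    rng = cfg.rngs()["drugs"]
    conc = cfg.top_concentration_um / cfg.dilution ** np.arange(cfg.n_doses)
    wt_params = (0.0, 85.0, 2.0, -1.2)  # bottom, top, ic50, hill (rising)
    base = _noiseless_dss(wt_params, conc)

    def ko_dss(ic50: float) -> float:
        return _noiseless_dss((wt_params[0], wt_params[1], ic50, wt_params[3]), conc)

    lo, hi = 1e-3, wt_params[2]
    for _ in range(80):  # bisection: DSS decreases in IC50
        mid = math.sqrt(lo * hi)
        if ko_dss(mid) - base > cfg.target_sdss:
            lo = mid
        else:
            hi = mid
    ko_ic50 = math.sqrt(lo * hi)
    ko_params = (wt_params[0], wt_params[1], ko_ic50, wt_params[3])

    drug_specs: dict[str, dict[str, tuple]] = {
        "ATO_like": {"KO": ko_params, "WT": wt_params}
    }
    for i in range(cfg.n_null_drugs):
        top = float(rng.uniform(40, 95))
        ic50 = float(rng.uniform(0.1, 8.0))
        hill = float(-rng.uniform(0.8, 2.0))
        drug_specs[f"drug_{i:02d}"] = {"KO": (0.0, top, ic50, hill),
                                       "WT": (0.0, top, ic50, hill)}

    plates, drug_dss = [], {}
    for drug, by_group in drug_specs.items():
        drug_dss[drug] = {}
        for group, params in by_group.items():
            clean = four_pl(conc, *params)
            drug_dss[drug][group] = _noiseless_dss(params, conc)
            for rep in range(1, 4):
                noisy = clean + rng.normal(0, cfg.drug_noise_sd, size=len(conc))
                plates.append(
                    DoseResponsePlate(drug, group, conc, noisy, replicate=rep)
                )
    return plates, drug_dss, "ATO_like"


# ---------------------------------------------------------------------------
# Full bundle + writers
# ---------------------------------------------------------------------------

def generate_all(cfg: SimConfig) -> dict:
    """Generate every synthetic input; returns a dict bundle."""
    reference, assembled = generate_reference(cfg)
    tx, exon_m, truth = generate_counts(cfg, reference, assembled)
    tracks = generate_tracks(cfg, reference, assembled, truth)
    rep1, rep2 = generate_chirp(cfg, reference, truth)
    states = generate_states(cfg)
    meta, records, plates, cohort_truth = generate_cohort_metadata(cfg)
    truth.drug_dss = cohort_truth.drug_dss
    truth.differential_drug = cohort_truth.differential_drug
    return {
        "config": cfg,
        "reference": reference,
        "assembled": assembled,
        "transcript_counts": tx,
        "exon_counts": exon_m,
        "tracks": tracks,
        "chirp_rep1": rep1,
        "chirp_rep2": rep2,
        "states": states,
        "patient_metadata": meta,
        "survival": records,
        "drug_plates": plates,
        "truth": truth,
    }


def write_bundle(bundle: dict, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic input as plain-text files under *outdir*."""
    from .genome import write_bed, write_gtf

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def p(name: str) -> Path:
        paths[name] = out / name
        return paths[name]

    write_gtf(bundle["reference"], p("reference.gtf"))
    write_gtf(bundle["assembled"], p("assembled.gtf"))
    bundle["transcript_counts"].to_tsv(p("transcript_counts.tsv"), p("sample_groups.tsv"))
    bundle["exon_counts"].to_tsv(p("exon_counts.tsv"), p("exon_sample_groups.tsv"))
    write_bed(bundle["tracks"]["dnase"], p("dnase.bed"))
    write_bed(bundle["tracks"]["h3k4me3"], p("h3k4me3.bed"))
    write_bed(bundle["chirp_rep1"], p("chirp_rep1.narrowPeak"), narrowpeak=True)
    write_bed(bundle["chirp_rep2"], p("chirp_rep2.narrowPeak"), narrowpeak=True)
    bundle["states"].to_csv(p("chromatin_states.bed"), sep="\t", header=False,
                            index=False)
    bundle["patient_metadata"].to_csv(p("patient_metadata.tsv"), sep="\t")
    surv_rows = []
    for r in bundle["survival"]:
        surv_rows.append({"sample_id": r.sample_id, "time": r.time,
                          "event": int(r.event),
                          "transplant_time": r.transplant_time
                          if r.transplant_time is not None else "",
                          **r.covariates})
    pd.DataFrame(surv_rows).to_csv(p("survival.tsv"), sep="\t", index=False)
    plate_rows = []
    for pl in bundle["drug_plates"]:
        for c, y in zip(pl.concentrations, pl.response):
            plate_rows.append({"drug": pl.drug, "group": pl.group,
                               "conc_uM": c, "response": y,
                               "replicate": pl.replicate})
    pd.DataFrame(plate_rows).to_csv(p("drug_plates.tsv"), sep="\t", index=False)
    bundle["truth"].to_json(p("truth_manifest.json"))
    return paths
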