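"""Synthetic annotations, ChIP read libraries and expression tables with
planted ground truth.

The generator emulates the statistical structure the analysis assumes: reads
fall uniformly over a mappable genome (Poisson background), marked genes
receive extra Poisson reads concentrated in the mark's promoter/body window,
fragment ends are offset by the DNA fragment size between strands, RPKM
values are consistent with planted silent/expressed status, and microarray
detection calls flip Present to Absent at a configurable false-absent rate.

Planted per-window counts are therefore exactly Poisson, which makes the
enrichment calibration's null model correct by construction — type-I tests
against the generator are sharp.  Chromatin classes are drawn independently
of expression (real marks correlate with transcription; tests that need the
correlation plant it explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .gene_models import TranscriptModel, derive_windows
from .reads import ReadLibrary

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_annotation",
    "generate_chip_library",
    "generate_expression",
    "generate_dataset",
    "MARKS",
]

MARKS = ("polII", "k4", "k27", "k36", "h3")
_MARK_STREAM = {m: i + 1 for i, m in enumerate(MARKS)}
VALENCY_LABELS = ("k4_only", "k27_only", "bivalent", "neither")
POLII_LABELS = ("active", "stalled", "none")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    ``background_rate`` of 0.0064 reads/bp gives lambda = 3.2 expected reads
    per 500-bp window, a depth at which each library's discrete Poisson
    threshold sits mid-plateau (realized per-mark false-positive rates near
    1-2%); ``enrichment_fold`` multiplies that rate inside marked windows.  Planted stalled genes carry a promoter read rate of
    ``promoter_body_ratio`` times the background body rate, so their
    expected stalling index equals the ratio; active genes get equal
    promoter and body enrichment (expected SI of 1).
    """

    seed: int = 0
    n_genes: int = 2000
    genome_bp: int = 20_000_000
    chrom: str = "chrS"
    valency_mix: dict = field(default_factory=lambda: {
        "k4_only": 0.30, "k27_only": 0.15, "bivalent": 0.05, "neither": 0.50})
    polII_mix: dict = field(default_factory=lambda: {
        "active": 0.35, "stalled": 0.15, "none": 0.50})
    expressed_fraction: float = 0.6
    background_rate: float = 0.0064        # reads per bp
    enrichment_fold: float = 5.0
    fragment_size: int = 160
    read_length: int = 25
    promoter_body_ratio: float = 14.0
    false_absent_rate: float = 0.05
    differentiation_fraction: float = 0.5  # of silent genes turned on in wt
    inconsistent_probe_fraction: float = 0.02
    n_replicates: int = 3
    n_short_transcripts: int = 20
    n_overlapping_pairs: int = 20
    n_close_tss_pairs: int = 20
    n_multi_isoform: int = 50

    def __post_init__(self):
        for mix in (self.valency_mix, self.polII_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("class mix proportions must sum to 1")
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must exceed 1")
        if self.n_multi_isoform > self.n_genes:
            raise ValueError("more multi-isoform genes than genes")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Planted per-gene labels (frame indexed by gene_id).

    Columns: valency, polII_class, expressed, special (empty for regular
    genes), and — after :func:`generate_expression` — rpkm_bam, rpkm_wt,
    differentiation, upregulated.
    """

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def generate_annotation(cfg: SimulationConfig
                        ) -> tuple[list[TranscriptModel], GroundTruth]:
    """Place genes on one synthetic chromosome and plant the special cases.

    Regular genes (2–6 kb, gaps 1.5–3 kb, random strand) never conflict;
    appended special cases plant exactly ``n_short_transcripts`` too-short
    exclusions, one overlap_conflict exclusion per overlapping pair (the
    nested transcript) and two tss_too_close exclusions per head-to-head
    close-TSS pair.
    """
    rng = cfg.rng(0)
    transcripts: list[TranscriptModel] = []
    rows = []
    cursor = 1000

    def place(length: int, min_gap=1500, max_gap=3000) -> tuple[int, int]:
        nonlocal cursor
        cursor += int(rng.integers(min_gap, max_gap + 1))
        start = cursor
        cursor += length
        return start, cursor

    val_labels = list(cfg.valency_mix)
    val_p = np.array([cfg.valency_mix[k] for k in val_labels])
    pol_labels = list(cfg.polII_mix)
    pol_p = np.array([cfg.polII_mix[k] for k in pol_labels])

    for i in range(cfg.n_genes):
        gid = f"g{i:05d}"
        L = int(rng.integers(2000, 6001))
        start, end = place(L)
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(TranscriptModel(
            f"{gid}.1", gid, cfg.chrom, strand, start, end))
        if i < cfg.n_multi_isoform:
            L2 = int(rng.integers(1600, max(1601, L)))
            if strand == "+":
                iso = (start, start + L2)
            else:
                iso = (end - L2, end)    # TSS (tx_end) shared with isoform 1
            transcripts.append(TranscriptModel(
                f"{gid}.2", gid, cfg.chrom, strand, iso[0], iso[1]))
        rows.append({
            "gene_id": gid,
            "valency": rng.choice(val_labels, p=val_p),
            "polII_class": rng.choice(pol_labels, p=pol_p),
            "expressed": bool(rng.random() < cfg.expressed_fraction),
            "special": "",
        })

    k = cfg.n_genes
    for _ in range(cfg.n_short_transcripts):
        gid = f"g{k:05d}"
        start, end = place(400)
        transcripts.append(TranscriptModel(
            f"{gid}.1", gid, cfg.chrom, "+", start, end))
        rows.append({"gene_id": gid, "valency": "neither",
                     "polII_class": "none", "expressed": False,
                     "special": "short"})
        k += 1

    for _ in range(cfg.n_overlapping_pairs):
        ga, gb = f"g{k:05d}", f"g{k + 1:05d}"
        start, end = place(4000)
        transcripts.append(TranscriptModel(
            f"{ga}.1", ga, cfg.chrom, "+", start, end))
        transcripts.append(TranscriptModel(          # nested in ga's span
            f"{gb}.1", gb, cfg.chrom, "+", start + 1500, start + 2500))
        rows.append({"gene_id": ga, "valency": "neither",
                     "polII_class": "none", "expressed": False,
                     "special": "overlap_host"})
        rows.append({"gene_id": gb, "valency": "neither",
                     "polII_class": "none", "expressed": False,
                     "special": "overlap_nested"})
        k += 2

    for _ in range(cfg.n_close_tss_pairs):
        ga, gb = f"g{k:05d}", f"g{k + 1:05d}"
        start, end = place(2000)
        transcripts.append(TranscriptModel(         # TSS at its tx_end
            f"{ga}.1", ga, cfg.chrom, "-", start, end))
        transcripts.append(TranscriptModel(         # head-to-head, 300 bp gap
            f"{gb}.1", gb, cfg.chrom, "+", end + 300, end + 2300))
        cursor = end + 2300
        rows.append({"gene_id": ga, "valency": "neither",
                     "polII_class": "none", "expressed": False,
                     "special": "close_tss"})
        rows.append({"gene_id": gb, "valency": "neither",
                     "polII_class": "none", "expressed": False,
                     "special": "close_tss"})
        k += 2

    if cursor + 1000 > cfg.genome_bp:
        raise ValueError(
            f"genes span {cursor} bp; increase genome_bp beyond {cfg.genome_bp}")
    truth = GroundTruth(pd.DataFrame(rows).set_index("gene_id"))
    return transcripts, truth


def _planted_windows(cfg, transcripts, truth, mark):
    """(window, mean extra reads) per marked gene; window of the longest
    (first) isoform."""
    primary: dict[str, TranscriptModel] = {}
    for t in transcripts:
        cur = primary.get(t.gene_id)
        if cur is None or t.length > cur.length:
            primary[t.gene_id] = t
    bg = cfg.background_rate
    out = []
    for gid, row in truth.table.iterrows():
        t = primary[gid]
        w = derive_windows(t)
        if mark == "k4" and row.valency in ("k4_only", "bivalent"):
            lo, hi = w.promoter_k4k27
            out.append((lo, hi, cfg.enrichment_fold * bg * (hi - lo)))
        elif mark == "k27" and row.valency in ("k27_only", "bivalent"):
            lo, hi = w.promoter_k4k27
            out.append((lo, hi, cfg.enrichment_fold * bg * (hi - lo)))
        elif mark == "k36" and row.expressed and w.k36_window:
            lo, hi = w.k36_window
            out.append((lo, hi, cfg.enrichment_fold * bg * (hi - lo)))
        elif mark == "polII" and row.polII_class == "active":
            lo, hi = w.promoter_polII
            out.append((lo, hi, cfg.enrichment_fold * bg * (hi - lo)))
            if w.gene_body:
                lo, hi = w.gene_body
                out.append((lo, hi, cfg.enrichment_fold * bg * (hi - lo)))
        elif mark == "polII" and row.polII_class == "stalled":
            lo, hi = w.promoter_polII
            out.append((lo, hi,
                        (cfg.promoter_body_ratio - 1) * bg * (hi - lo)))
    return out


def generate_chip_library(cfg: SimulationConfig,
                          transcripts: list[TranscriptModel],
                          truth: GroundTruth, mark: str) -> ReadLibrary:
    """Simulate one ChIP library (``h3`` is the no-enrichment control).

    Each sequenced fragment is centred on a genomic position (uniform for
    background, uniform inside the marked window for enrichment); the read
    comes off either fragment end with equal probability, so plus- and
    minus-strand 5' densities sit ``fragment_size`` apart.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}")
    rng = cfg.rng(_MARK_STREAM[mark])
    half = cfg.fragment_size // 2

    n_bg = rng.poisson(cfg.background_rate * cfg.genome_bp)
    centers = [rng.integers(half, cfg.genome_bp - half, size=n_bg)]
    if mark != "h3":
        for lo, hi, mean in _planted_windows(cfg, transcripts, truth, mark):
            n = rng.poisson(mean)
            if n:
                centers.append(rng.integers(lo, hi, size=n))
    c = np.concatenate(centers)
    plus = rng.random(c.size) < 0.5
    five = np.where(plus, c - half, c + half)
    start = np.where(plus, five, five - cfg.read_length + 1)
    end = start + cfg.read_length
    df = pd.DataFrame({
        "chrom": cfg.chrom,
        "start": np.clip(start, 0, cfg.genome_bp),
        "end": np.clip(end, 0, cfg.genome_bp),
        "strand": np.where(plus, "+", "-"),
    })
    return ReadLibrary(mark, df, fragment_size=cfg.fragment_size)


def generate_expression(cfg: SimulationConfig, truth: GroundTruth
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RPKM tables for the two conditions plus microarray P/A calls.

    Planted-expressed genes draw RPKM >= 1 (log-normal), silent genes < 0.5
    (zero-inflated); a ``differentiation_fraction`` of silent genes is
    turned on in the differentiated condition.  The truth table's
    differentiation/upregulated flags are recomputed from the drawn values,
    so they hold by construction.  Expressed genes are Present in every
    replicate except a ``false_absent_rate`` fraction flipped to all-Absent;
    an ``inconsistent_probe_fraction`` gets conflicting multi-probe calls
    and ``consistent=False``.
    """
    rng = cfg.rng(90)
    genes = truth.table.index
    n = len(genes)
    expressed = truth.table.expressed.to_numpy()

    def expr_draw(size):
        return np.maximum(1.0, rng.lognormal(np.log(8.0), 1.0, size))

    def silent_draw(size):
        v = 0.5 * rng.beta(1.2, 5.0, size)
        v[rng.random(size) < 0.3] = 0.0
        return v

    bam = np.where(expressed, expr_draw(n), silent_draw(n))
    diff = (~expressed) & (rng.random(n) < cfg.differentiation_fraction)
    wt = np.where(expressed, bam * 2.0 ** rng.normal(0, 1, n), silent_draw(n))
    wt = np.where(diff, expr_draw(n), wt)

    rpkm = pd.DataFrame({"rpkm_bam": bam, "rpkm_wt": wt}, index=genes)
    truth.table["rpkm_bam"] = bam
    truth.table["rpkm_wt"] = wt
    truth.table["differentiation"] = (bam < 0.5) & (wt >= 1.0)
    truth.table["upregulated"] = wt / np.maximum(bam, 0.5) >= 2.0

    detected = bam >= 1.0
    flip = detected & (rng.random(n) < cfg.false_absent_rate)
    inconsistent = rng.random(n) < cfg.inconsistent_probe_fraction
    calls = pd.DataFrame(index=genes)
    for r in range(cfg.n_replicates):
        col = np.where(detected & ~flip, "P", "A")
        if r == 0:
            col = np.where(inconsistent, "M", col)  # conflicting probe
        calls[f"call_{r + 1}"] = col
    calls["consistent"] = ~inconsistent
    return rpkm, calls


def generate_dataset(cfg: SimulationConfig,
                     marks: tuple = MARKS) -> dict:
    """One-call bundle: annotation, truth, all read libraries and tables."""
    transcripts, truth = generate_annotation(cfg)
    libraries = {m: generate_chip_library(cfg, transcripts, truth, m)
                 for m in marks}
    rpkm, calls = generate_expression(cfg, truth)
    return {"config": cfg, "transcripts": transcripts, "truth": truth,
            "libraries": libraries, "rpkm": rpkm, "calls": calls}
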