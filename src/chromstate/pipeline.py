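"""End-to-end orchestration: eligibility filtering, calibration, dominant
transcript selection, window counting, classification and reporting.

The pipeline consumes an annotation, per-mark read libraries and RPKM
tables, and produces the per-gene classification table plus the summary
artifacts (calibration TSV, quadrant summary, island BEDs, saturation and
metaprofile tables).  Every stage is also usable on in-memory objects via
:func:`analyze_bundle`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import classify, enrichment, expression, gene_models, islands, reads
from .gene_models import (EligibilitySet, TranscriptModel, windows_table,
                          select_dominant_transcript, K36_MIN_LEN)
from .reads import ReadLibrary

__all__ = ["RunConfig", "AnalysisResult", "analyze_bundle", "run_pipeline"]

PROMOTER_WINDOW_BP = 500
K36_WINDOW_BP = 1000


@dataclass
class RunConfig:
    """File-level run description; defaults are the analysis constants
    (alpha 0.05, SI cutoffs 3/5, RPKM cutoffs 0.5/1, fold 2)."""

    annotation: str = ""
    annotation_format: str = "genepred"
    libraries: dict = field(default_factory=dict)   # mark -> BED path
    rpkm_table: Optional[str] = None
    microarray_calls: Optional[str] = None
    genome_mappable_bp: int = enrichment.DEFAULT_MAPPABLE_GENOME_BP
    alpha: float = 0.05
    count_mode: str = "five_prime"
    max_duplicates: int = 3
    fragment_size: int = 160
    seed: int = 0
    outdir: str = "chromstate_out"
    run_islands: bool = False
    run_saturation: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class AnalysisResult:
    eligibility: EligibilitySet
    windows: pd.DataFrame
    calibrations: dict
    transcript_counts: pd.DataFrame
    gene_records: pd.DataFrame
    quadrants: pd.DataFrame


def _gene_seed(base: int, gene_id: str) -> int:
    return (base ^ zlib.crc32(gene_id.encode())) & 0x7FFFFFFF


def _count_matrix(libs: dict, windows: pd.DataFrame,
                  mode: str) -> pd.DataFrame:
    """Per-transcript read counts for every (library, window) pairing the
    selection chains and classifications need; missing windows are NaN."""
    spec = [
        ("polII_promoter", "polII", "promoter_polII"),
        ("polII_body", "polII", "gene_body"),
        ("k4_promoter", "k4", "promoter_k4k27"),
        ("k27_promoter", "k27", "promoter_k4k27"),
        ("k36_body", "k36", "k36_window"),
    ]
    out = pd.DataFrame(index=windows.index)
    for col, mark, kind in spec:
        if mark not in libs:
            out[col] = np.nan
            continue
        cnt = reads.count_windows(
            libs[mark], windows, mode,
            cols=("chrom", f"{kind}_start", f"{kind}_end")).astype(float)
        cnt[cnt < 0] = np.nan
        out[col] = cnt
    return out


def analyze_bundle(transcripts: list[TranscriptModel],
                   libraries: dict,
                   rpkm: Optional[pd.DataFrame] = None,
                   *,
                   genome_bp: int,
                   alpha: float = 0.05,
                   seed: int = 0,
                   count_mode: str = "five_prime",
                   max_duplicates: int = 3,
                   deduplicated: bool = False) -> AnalysisResult:
    """Run the gene-level analysis on in-memory objects.

    ``libraries`` maps mark names (polII/k4/k27/k36/h3) to
    :class:`ReadLibrary`; absent marks degrade gracefully (valency needs k4
    and k27, stalling needs polII).
    """
    elig = gene_models.filter_transcripts(transcripts)
    wtab = windows_table(transcripts)

    libs = {}
    calibs = {}
    for mark, lib in libraries.items():
        lib = lib if deduplicated else reads.deduplicate(lib, max_duplicates)
        libs[mark] = lib
        if mark == "h3":
            continue
        wbp = K36_WINDOW_BP if mark == "k36" else PROMOTER_WINDOW_BP
        calibs[mark] = enrichment.calibrate_threshold(
            lib.total_unique, wbp, genome_bp, alpha)

    tc = _count_matrix(libs, wtab, count_mode)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    tflags = elig.transcripts

    rows = {}
    for gid, grow in elig.genes.iterrows():
        if not grow.promoter_eligible:
            continue
        row = {}
        gseed = _gene_seed(seed, gid)
        gts = by_gene[gid]

        if "k4" in libs and "k27" in libs:
            ok = [t for t in gts if tflags.at[t.transcript_id, "k4k27_ok"]]
            if ok:
                t4 = select_dominant_transcript(ok, "k4_vs_k27", tc,
                                                seed=gseed)
                row["k4"] = tc.at[t4, "k4_promoter"]
                row["k27"] = tc.at[t4, "k27_promoter"]
                row["valency_transcript"] = t4

        if "polII" in libs:
            ok = [t for t in gts if tflags.at[t.transcript_id, "polII_ok"]]
            if ok:
                tp = select_dominant_transcript(ok, "polII_vs_rpkm", tc,
                                                seed=gseed)
                row["polII"] = tc.at[tp, "polII_promoter"]
                row["polII_body"] = (tc.at[tp, "polII_body"]
                                     if grow.stalling_eligible else np.nan)
                row["polII_transcript"] = tp

        if "k36" in libs and grow.k36_eligible:
            ok = [t for t in gts
                  if (tflags.at[t.transcript_id, "k4k27_ok"]
                      or tflags.at[t.transcript_id, "polII_ok"])
                  and t.length > K36_MIN_LEN]
            if ok:
                t36 = select_dominant_transcript(ok, "k36_vs_rpkm", tc,
                                                 seed=gseed)
                row["k36"] = tc.at[t36, "k36_body"]
        if row:
            rows[gid] = row

    counts = pd.DataFrame.from_dict(rows, orient="index")
    counts.index.name = "gene_id"
    for col in ("k4", "k27", "polII", "k36"):
        if col in counts.columns:
            counts[col] = counts[col].fillna(-1).astype(int)
    if "polII_body" not in counts.columns:
        counts["polII_body"] = np.nan

    records = classify.build_gene_records(counts, calibs, rpkm)
    for extra in ("valency_transcript", "polII_transcript"):
        if extra in counts.columns:
            records[extra] = counts[extra]
    if "valency" in records.columns:
        flags = [f for f in ("differentiation", "upregulated")
                 if f in records.columns]
        quad = classify.quadrant_report(records, flags)
    else:
        quad = pd.DataFrame(
            columns=["subset", "class", "count", "total", "percent"])
    return AnalysisResult(elig, wtab, calibs, tc, records, quad)


class PipelineError(RuntimeError):
    def __init__(self, stage, detail):
        super().__init__(f"stage {stage!r}: {detail}")


def run_pipeline(cfg: RunConfig) -> Path:
    """File-driven run; writes the report bundle and returns the outdir.

    Output TSVs are deterministic for a fixed config and seed.  The quadrant
    summary is recounted from the per-gene table before writing (built-in
    reconciliation check).
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    notes = []

    try:
        transcripts = gene_models.load_annotation(
            cfg.annotation, cfg.annotation_format)
    except Exception as exc:
        raise PipelineError("annotation", exc) from exc

    libraries = {}
    for mark, path in cfg.libraries.items():
        try:
            libraries[mark] = reads.load_reads(
                path, name=mark, fragment_size=cfg.fragment_size)
        except Exception as exc:
            raise PipelineError(f"reads:{mark}", exc) from exc
    for needed, analysis in (("k4", "valency"), ("k27", "valency"),
                             ("polII", "stalling")):
        if needed not in libraries:
            notes.append(f"{analysis} analysis skipped: no {needed} library")

    rpkm = None
    if cfg.rpkm_table:
        rpkm = pd.read_csv(cfg.rpkm_table, sep="\t", index_col="gene_id")

    res = analyze_bundle(
        transcripts, libraries, rpkm,
        genome_bp=cfg.genome_mappable_bp, alpha=cfg.alpha,
        seed=cfg.seed, count_mode=cfg.count_mode,
        max_duplicates=cfg.max_duplicates)

    # reconciliation: the written summary must recount from the gene table
    if "valency" in res.gene_records.columns:
        vc = res.gene_records.valency.value_counts()
        for _, qrow in res.quadrants[res.quadrants.subset == "all"].iterrows():
            if int(vc.get(qrow["class"], 0)) != qrow["count"]:
                raise PipelineError(
                    "report", f"quadrant recount mismatch for {qrow['class']}")

    res.eligibility.to_tsv(out / "eligibility.tsv")
    res.gene_records.to_csv(out / "gene_records.tsv", sep="\t",
                            index_label="gene_id")
    res.quadrants.to_csv(out / "quadrant_summary.tsv", sep="\t", index=False)
    calib_rows = [{
        "library": mark, "total_unique_reads": c.total_unique_reads,
        "window_bp": c.window_bp, "lambda": c.lam, "alpha": c.alpha,
        "threshold_count": c.threshold_count,
        "windows_tested": int((res.gene_records.get(
            f"{mark}_count", pd.Series(dtype=float)) >= 0).sum()),
    } for mark, c in res.calibrations.items()]
    pd.DataFrame(calib_rows).to_csv(out / "calibration.tsv", sep="\t",
                                    index=False)

    if cfg.microarray_calls and rpkm is not None:
        calls = pd.read_csv(cfg.microarray_calls, sep="\t",
                            index_col="gene_id")
        conc = expression.concordance(calls, rpkm)
        conc["present_log_rpkm_hist"].to_csv(
            out / "present_rpkm_histogram.tsv", sep="\t", index=False)
        pd.Series({k: v for k, v in conc.items()
                   if np.isscalar(v)}).to_csv(
            out / "microarray_concordance.tsv", sep="\t", header=False)

    chrom_lengths = {
        c: int(g.end.max())
        for lib in libraries.values()
        for c, g in lib.reads.groupby("chrom")}
    if cfg.run_islands:
        for mark, lib in libraries.items():
            wbp = 400 if mark in ("k27", "k36") else 200
            isl = islands.call_islands(
                reads.deduplicate(lib, cfg.max_duplicates),
                islands.IslandParams(window_bp=wbp),
                cfg.genome_mappable_bp, chrom_lengths, seed=cfg.seed)
            isl.to_csv(out / f"islands_{mark}.bed", sep="\t",
                       header=False, index=False)
    if cfg.run_saturation:
        for mark, lib in libraries.items():
            wbp = 400 if mark in ("k27", "k36") else 200
            sat = islands.saturation_curve(
                reads.deduplicate(lib, cfg.max_duplicates),
                islands.IslandParams(window_bp=wbp),
                cfg.genome_mappable_bp, chrom_lengths, seed=cfg.seed)
            sat.to_csv(out / f"saturation_{mark}.tsv", sep="\t", index=False)

    with open(out / "run_report.txt", "w") as fh:
        fh.write("chromstate run report\n")
        for key, val in asdict(cfg).items():
            fh.write(f"{key}: {val}\n")
        fh.write(f"promoter_eligible_genes: "
                 f"{int(res.eligibility.genes.promoter_eligible.sum())}\n")
        for row in calib_rows:
            fh.write(f"calibration {row['library']}: lambda={row['lambda']:.4f} "
                     f"threshold={row['threshold_count']}\n")
        for note in notes:
            fh.write(f"note: {note}\n")
    return out
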