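"""Headline gene classifications: valency quadrants, Pol II stalling
classes, differentiation/up-regulation flags and poised candidates.

A promoter is *bivalent* when both H3K4me3 and H3K27me3 are significantly
enriched in its 0..+500 window, *monovalent* with exactly one, *neither*
otherwise.  The stalling index (SI) is the ratio of Pol II reads in the
promoter (-250..+250) to reads in the gene body (+500..+1000); genes with
significant promoter Pol II are *active* at SI <= 3 and *stalled* at
SI >= 5, with an explicit *intermediate* bucket for 3 < SI < 5 (the gap the
three-class rule leaves open) rather than silently dropping them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .enrichment import EnrichmentCall

__all__ = [
    "VALENCY_CLASSES",
    "POLII_CLASSES",
    "classify_valency",
    "flag_differentiation",
    "flag_upregulated",
    "stalling_index",
    "classify_polII",
    "flag_poised",
    "percent",
    "quadrant_report",
    "region_overlap",
    "build_gene_records",
]

VALENCY_CLASSES = ("bivalent", "k4_only", "k27_only", "neither")
POLII_CLASSES = ("active", "stalled", "intermediate", "none")

ACTIVE_SI_MAX = 3.0
STALLED_SI_MIN = 5.0
FOLD_CUTOFF = 2.0
RPKM_FLOOR = 0.5


def classify_valency(k4: EnrichmentCall, k27: EnrichmentCall) -> str:
    if k4.significant and k27.significant:
        return "bivalent"
    if k4.significant:
        return "k4_only"
    if k27.significant:
        return "k27_only"
    return "neither"


def flag_differentiation(rpkm_bam: float, rpkm_wt: float) -> bool:
    """Silent in the undifferentiated sample, expressed in the
    differentiated one."""
    if rpkm_bam is None or rpkm_wt is None or \
            math.isnan(rpkm_bam) or math.isnan(rpkm_wt):
        raise ValueError("both RPKM values are required")
    return rpkm_bam < 0.5 and rpkm_wt >= 1.0


def flag_upregulated(rpkm_bam: float, rpkm_wt: float,
                     fold: float = FOLD_CUTOFF,
                     floor: float = RPKM_FLOOR) -> bool:
    """At least ``fold``-fold up in the differentiated sample; the
    denominator is floored at ``floor`` so silent genes do not explode the
    ratio."""
    return rpkm_wt / max(rpkm_bam, floor) >= fold


def stalling_index(promoter_count: int, body_count: int) -> float:
    """Promoter / gene-body Pol II read ratio; +inf when the body is empty
    and NaN (undefined, reported) when both windows are empty."""
    if promoter_count < 0 or body_count < 0:
        raise ValueError("read counts must be non-negative")
    if body_count == 0:
        return float("inf") if promoter_count > 0 else float("nan")
    return promoter_count / body_count


def classify_polII(si: float, call: EnrichmentCall) -> str:
    """Three-way Pol II class plus the explicit intermediate bucket.

    An infinite SI with significant promoter enrichment is stalled (the
    limit of the rule); an undefined SI (NaN) with significant enrichment
    falls in the intermediate/unresolved bucket.
    """
    if not call.significant:
        return "none"
    if math.isnan(si):
        return "intermediate"
    if si <= ACTIVE_SI_MAX:
        return "active"
    if si >= STALLED_SI_MIN:
        return "stalled"
    return "intermediate"


def flag_poised(polII_call: EnrichmentCall, rpkm: float) -> bool:
    """Significant promoter Pol II on a gene expressed below the detection
    cutoff — recruited but not productively transcribing."""
    return polII_call.significant and rpkm < 1.0


def percent(n: int, d: int, decimals: Optional[int] = 1) -> float:
    """Percentage with round-half-up formatting.

    ``decimals=0`` rounds to the nearest integer (how approximate headline
    percentages are printed); NaN for an empty denominator.
    """
    if d == 0:
        return float("nan")
    q = Decimal(n) / Decimal(d) * 100
    places = Decimal(1).scaleb(-decimals) if decimals else Decimal(1)
    return float(q.quantize(places, rounding=ROUND_HALF_UP))


def quadrant_report(records: pd.DataFrame,
                    flags: Sequence[str] = ("differentiation", "upregulated"),
                    class_column: str = "valency",
                    classes: Sequence[str] = VALENCY_CLASSES) -> pd.DataFrame:
    """Count class membership overall and within flagged subsets.

    ``records`` is a per-gene frame carrying ``class_column`` and boolean
    flag columns.  Returns one row per (subset, class) with count and
    percentage of the subset (one decimal, round-half-up).
    """
    rows = []
    subsets = [("all", pd.Series(True, index=records.index))]
    subsets += [(f, records[f].astype(bool)) for f in flags
                if f in records.columns]
    for name, mask in subsets:
        sub = records[mask]
        total = len(sub)
        for cls in classes:
            n = int((sub[class_column] == cls).sum())
            rows.append({"subset": name, "class": cls, "count": n,
                         "total": total, "percent": percent(n, total)})
    return pd.DataFrame(rows)


def region_overlap(regions: Sequence[tuple], windows: pd.DataFrame,
                   window: str = "promoter_k4k27") -> list[str]:
    """Genes whose promoter window intersects at least one region.

    ``regions`` holds (chrom, start, end) half-open intervals; ``windows``
    is a windows table (see gene_models.windows_table) indexed by
    transcript_id with a gene_id column.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in regions:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    hits = set()
    scol, ecol = f"{window}_start", f"{window}_end"
    for _, row in windows.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None or pd.isna(row[scol]):
            continue
        if tree.overlap(int(row[scol]), int(row[ecol])):
            hits.add(row["gene_id"])
    return sorted(hits)


def build_gene_records(window_counts: pd.DataFrame,
                       calibrations: dict,
                       expression: Optional[pd.DataFrame] = None
                       ) -> pd.DataFrame:
    """Assemble the per-gene classification table.

    ``window_counts`` is indexed by gene_id with integer columns among
    ``k4``, ``k27``, ``polII``, ``k36`` (promoter-window counts of the
    gene's dominant transcript), ``polII_body`` (gene-body Pol II count;
    -1/NaN when the gene is not stalling-eligible).  ``calibrations`` maps
    mark name to its :class:`LibraryCalibration`.  ``expression``, when
    given, is indexed by gene_id with ``rpkm_bam``/``rpkm_wt`` columns and
    contributes the differentiation / up-regulation / poised flags.
    """
    rec = pd.DataFrame(index=window_counts.index)
    calls = {}
    for mark in ("k4", "k27", "polII", "k36"):
        if mark not in window_counts.columns or mark not in calibrations:
            continue
        calib = calibrations[mark]
        cnts = window_counts[mark].to_numpy()
        sig = cnts >= calib.threshold_count
        pvals = np.array([calib.pvalue(int(c)) if c >= 0 else np.nan
                          for c in cnts])
        rec[f"{mark}_count"] = cnts
        rec[f"{mark}_pvalue"] = pvals
        rec[f"{mark}_significant"] = sig & (cnts >= 0)
        calls[mark] = rec[f"{mark}_significant"]

    if "k4" in calls and "k27" in calls:
        valency = np.where(
            calls["k4"] & calls["k27"], "bivalent",
            np.where(calls["k4"], "k4_only",
                     np.where(calls["k27"], "k27_only", "neither")))
        rec["valency"] = valency

    if "polII" in calls and "polII_body" in window_counts.columns:
        prom = window_counts["polII"].to_numpy(dtype=float)
        body = window_counts["polII_body"].to_numpy(dtype=float)
        eligible = ~np.isnan(body) & (body >= 0)
        si = np.full(len(rec), np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            si[eligible] = np.where(
                body[eligible] > 0, prom[eligible] / body[eligible],
                np.where(prom[eligible] > 0, np.inf, np.nan))
        rec["stalling_index"] = si
        cls = np.full(len(rec), "none", dtype=object)
        sig = calls["polII"].to_numpy()
        cls[sig & eligible & (si <= ACTIVE_SI_MAX)] = "active"
        cls[sig & eligible & (si >= STALLED_SI_MIN)] = "stalled"
        cls[sig & eligible & (si > ACTIVE_SI_MAX)
            & (si < STALLED_SI_MIN)] = "intermediate"
        cls[sig & eligible & np.isnan(si)] = "intermediate"
        cls[sig & ~eligible] = "ineligible"
        rec["polII_class"] = cls

    if expression is not None:
        joined = rec.join(expression[["rpkm_bam", "rpkm_wt"]], how="left")
        bam = joined["rpkm_bam"].to_numpy(dtype=float)
        wt = joined["rpkm_wt"].to_numpy(dtype=float)
        rec["rpkm_bam"] = bam
        rec["rpkm_wt"] = wt
        rec["differentiation"] = (bam < 0.5) & (wt >= 1.0)
        rec["upregulated"] = wt / np.maximum(bam, RPKM_FLOOR) >= FOLD_CUTOFF
        if "polII" in calls:
            rec["poised_candidate"] = calls["polII"] & (bam < 1.0)
    return rec
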