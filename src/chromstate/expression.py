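"""RPKM computation, expression classes and microarray concordance.

Expression is measured in RPKM (reads per kilobase of exon per million
mapped reads).  The working cutoffs are RPKM >= 1 for expressed genes and
RPKM < 0.5 for silent genes, validated by comparing RNA-seq values with
microarray Present/Absent detection calls: nearly all genes unambiguously
Present on the array should sit above the expressed cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SILENT_RPKM",
    "EXPRESSED_RPKM",
    "compute_rpkm",
    "log_rpkm",
    "classify_expression",
    "classify_table",
    "tertile_bounds",
    "concordance",
]

SILENT_RPKM = 0.5
EXPRESSED_RPKM = 1.0


def compute_rpkm(exon_reads: float, exonic_kb: float,
                 mapped_millions: float) -> float:
    """reads / (kb of exon x millions of mapped reads)."""
    if exonic_kb <= 0:
        raise ValueError("exonic length must be positive")
    if mapped_millions <= 0:
        raise ValueError("mapped read count must be positive")
    return exon_reads / (exonic_kb * mapped_millions)


def log_rpkm(rpkm):
    """log2(RPKM + 1); the pseudo-count keeps zeros finite."""
    arr = np.asarray(rpkm, dtype=float)
    if (arr < 0).any():
        raise ValueError("RPKM must be non-negative")
    out = np.log2(arr + 1.0)
    return float(out) if np.isscalar(rpkm) else out


def classify_expression(rpkm: float,
                        group_bounds: Optional[tuple] = None,
                        scheme: str = "cutoff") -> tuple[str, Optional[str]]:
    """Assign (class, subgroup) for one RPKM value.

    ``scheme='cutoff'``: silent < 0.5 <= intermediate < 1 <= expressed — the
    working cutoffs used for differentiation/up-regulation logic.
    ``scheme='strict'``: silent iff RPKM == 0, intermediate in (0, 1) — the
    grouping used when silent means literally undetected.

    Expressed genes are split low/moderate/high at ``group_bounds``
    (b1 <= rpkm < b2 is moderate); subgroup is None otherwise.
    """
    if rpkm < 0:
        raise ValueError("RPKM must be non-negative")
    if scheme == "cutoff":
        if rpkm < SILENT_RPKM:
            return "silent", None
        if rpkm < EXPRESSED_RPKM:
            return "intermediate", None
    elif scheme == "strict":
        if rpkm == 0:
            return "silent", None
        if rpkm < EXPRESSED_RPKM:
            return "intermediate", None
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    sub = None
    if group_bounds is not None:
        b1, b2 = group_bounds
        if not (EXPRESSED_RPKM <= b1 < b2):
            raise ValueError("need 1 <= b1 < b2")
        sub = "low" if rpkm < b1 else ("moderate" if rpkm < b2 else "high")
    return "expressed", sub


def tertile_bounds(rpkm: pd.Series) -> tuple[float, float]:
    """Tertile boundaries of the expressed (RPKM >= 1) genes, for the
    low/moderate/high split."""
    expr = rpkm[rpkm >= EXPRESSED_RPKM]
    if expr.empty:
        raise ValueError("no expressed genes to derive bounds from")
    b1, b2 = np.quantile(expr, [1 / 3, 2 / 3])
    return float(max(b1, EXPRESSED_RPKM)), float(max(b2, b1 + 1e-9))


def classify_table(rpkm: pd.DataFrame, column: str = "rpkm_bam",
                   group_bounds: Optional[tuple] = None,
                   scheme: str = "cutoff") -> pd.DataFrame:
    """Classify every gene of an RPKM table (indexed by gene_id)."""
    if group_bounds is None:
        try:
            group_bounds = tertile_bounds(rpkm[column])
        except ValueError:
            group_bounds = None
    cls, sub = [], []
    for v in rpkm[column]:
        c, s = classify_expression(float(v), group_bounds, scheme)
        cls.append(c)
        sub.append(s)
    return rpkm.assign(expression_class=cls, subgroup=sub)


def concordance(calls: pd.DataFrame, rpkm: pd.DataFrame,
                column: str = "rpkm_bam") -> dict:
    """Compare microarray Present/Absent calls with RNA-seq RPKM.

    ``calls`` is indexed by gene_id with replicate columns ``call_*`` holding
    P/A/M codes and an optional boolean ``consistent`` column (genes with
    conflicting multi-probe calls carry False and are dropped).  Returns the
    all-Absent-yet-expressed and all-Present concordance counts/fractions,
    the log2(RPKM+1) histogram of all-Present genes, and the ids that failed
    to join.
    """
    call_cols = [c for c in calls.columns if c.startswith("call_")]
    if not call_cols:
        raise ValueError("no call_* replicate columns found")
    use = calls
    if "consistent" in calls.columns:
        use = calls[calls.consistent.astype(bool)]
    joined = use.join(rpkm[[column]], how="inner")
    unjoined = sorted(set(use.index) - set(joined.index))

    cm = joined[call_cols]
    all_absent = (cm == "A").all(axis=1)
    all_present = (cm == "P").all(axis=1)
    r = joined[column]

    n_aa = int(all_absent.sum())
    n_aa_expr = int((all_absent & (r >= EXPRESSED_RPKM)).sum())
    n_pp = int(all_present.sum())
    n_pp_expr = int((all_present & (r >= EXPRESSED_RPKM)).sum())
    n_pp_silent = int((all_present & (r < SILENT_RPKM)).sum())

    logs = log_rpkm(r[all_present].to_numpy())
    edges = np.arange(0, max(10.0, logs.max() if logs.size else 1) + 0.5, 0.5)
    hist, edges = np.histogram(logs, bins=edges)

    return {
        "n_genes": len(joined),
        "n_all_absent": n_aa,
        "n_all_absent_expressed": n_aa_expr,
        "frac_all_absent_expressed": n_aa_expr / n_aa if n_aa else float("nan"),
        "n_all_present": n_pp,
        "frac_all_present_expressed":
            n_pp_expr / n_pp if n_pp else float("nan"),
        "frac_all_present_silent":
            n_pp_silent / n_pp if n_pp else float("nan"),
        "present_log_rpkm_hist": pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist}),
        "unjoined_gene_ids": unjoined,
    }
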