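"""Per-library Poisson calibration of fixed-width window enrichment.

The null model distributes a library's unique reads uniformly over the
mappable genome, so the read count of any fixed window of ``window_bp`` is
Poisson with rate ``lambda = total_reads * window_bp / genome_bp``.  The
significance threshold is the minimal count whose exact upper-tail
probability drops to ``alpha``; counts are then called per gene window
against that single per-library threshold (no multiple-testing correction —
the number of windows tested is reported alongside for transparency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

__all__ = [
    "DEFAULT_MAPPABLE_GENOME_BP",
    "LibraryCalibration",
    "EnrichmentCall",
    "CalibrationError",
    "window_pvalue",
    "calibrate_threshold",
    "call_enrichment",
    "normalized_signal",
]

# sum of the dm3 major euchromatic chromosome arms (2L+2R+3L+3R+X+4); the
# default denominator for the uniform-background rate
DEFAULT_MAPPABLE_GENOME_BP = 120_381_546


class CalibrationError(ValueError):
    """No count in the searched range reaches significance."""


@dataclass
class LibraryCalibration:
    total_unique_reads: int
    genome_mappable_bp: int
    window_bp: int
    alpha: float
    lam: float
    threshold_count: int
    pvalue_table: np.ndarray  # pvalue_table[n] = P(X >= n), n = 0..range max

    def pvalue(self, n: int) -> float:
        if n < len(self.pvalue_table):
            return float(self.pvalue_table[n])
        return float(poisson.sf(n - 1, self.lam))


@dataclass
class EnrichmentCall:
    count: int
    p_value: float
    significant: bool
    normalized_signal: float = float("nan")


def window_pvalue(n: int, calib: LibraryCalibration) -> float:
    """Exact Poisson upper tail P(X >= n) under the calibration's rate."""
    if n < 0:
        raise ValueError("count must be non-negative")
    if n == 0:
        return 1.0
    return calib.pvalue(n)


def calibrate_threshold(total: int, window_bp: int, genome_bp: int,
                        alpha: float = 0.05,
                        count_range: range = range(1, 100)
                        ) -> LibraryCalibration:
    """Find the minimal read count significant at ``alpha``.

    The tail probability P(X >= n) is tabulated over ``count_range`` (1..99
    by default) and the threshold is the smallest n whose tail drops to
    ``alpha``.  Deep libraries whose threshold lies beyond the range raise
    :class:`CalibrationError` (extend the range).
    """
    if total <= 0:
        raise ValueError("total reads must be positive")
    if genome_bp <= window_bp:
        raise ValueError("genome must be larger than the window")
    lam = total * window_bp / genome_bp
    nmax = count_range.stop - 1
    ns = np.arange(0, nmax + 1)
    table = poisson.sf(ns - 1, lam)      # P(X >= n); n=0 -> 1.0
    sig = [n for n in count_range if table[n] <= alpha]
    if not sig:
        raise CalibrationError(
            f"no count in {count_range} reaches alpha={alpha} "
            f"(lambda={lam:.3g}); extend the range")
    return LibraryCalibration(
        total_unique_reads=total, genome_mappable_bp=genome_bp,
        window_bp=window_bp, alpha=alpha, lam=lam,
        threshold_count=min(sig), pvalue_table=table)


def call_enrichment(count: int, calib: LibraryCalibration) -> EnrichmentCall:
    """Call one window's enrichment against the library calibration."""
    p = window_pvalue(count, calib)
    return EnrichmentCall(
        count=count, p_value=p,
        significant=count >= calib.threshold_count,
        normalized_signal=normalized_signal(
            count, calib.total_unique_reads, calib.window_bp))


def normalized_signal(count: int, total: int, window_bp: int) -> float:
    """Reads per 1-kb window per 1 million total reads."""
    if total <= 0:
        raise ValueError("total reads must be positive")
    return count * (1000 / window_bp) * (1_000_000 / total)
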