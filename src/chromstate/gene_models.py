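"""Transcript models, eligibility filtering and strand-aware analysis windows.

Coordinates are 0-based half-open throughout (BED/genePred native).  The TSS
of a plus-strand transcript is ``tx_start``; for a minus-strand transcript it
is ``tx_end``, and every "+x" window offset runs leftward from there.

The eligibility filter mirrors the three-step transcript selection used for
promoter-window ChIP-seq analysis in gene-dense genomes:

1. drop transcripts shorter than ``min_len`` (promoter windows of such genes
   are dominated by neighbouring features);
2. drop transcripts whose promoter window for a given analysis intersects the
   span of a transcript from a *different* gene, and — for the Pol II
   (-250..+250) analysis only — drop non-overlapping opposite-strand pairs
   whose TSSs lie closer than ``tss_gap``;
3. report the survivors with per-gene eligibility flags.

Because every exclusion is either intrinsic (length) or symmetric with respect
to the full input set, the filter is idempotent: re-filtering its own
survivors changes nothing.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "TranscriptModel",
    "AnalysisWindows",
    "EligibilitySet",
    "AnnotationError",
    "load_annotation",
    "write_refflat",
    "filter_transcripts",
    "derive_windows",
    "select_dominant_transcript",
]

# offsets of each analysis window relative to the TSS, in transcript
# orientation (start inclusive, end exclusive)
WINDOW_OFFSETS = {
    "promoter_polII": (-250, 250),
    "promoter_k4k27": (0, 500),
    "k36_window": (500, 1500),
    "gene_body": (500, 1000),
}
GENE_BODY_MIN_LEN = 1000      # gene body window requires transcript > 1 kb
K36_MIN_LEN = 1500            # K36 window requires transcript > 1.5 kb


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class TranscriptModel:
    """One annotated isoform with exon structure.

    ``exons`` are half-open intervals, sorted, non-overlapping and contained
    in ``[tx_start, tx_end)``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.transcript_id}: unknown strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise AnnotationError(
                f"{self.transcript_id}: tx_start must be < tx_end")
        prev = self.tx_start
        for s, e in self.exons:
            if s < prev or e <= s or e > self.tx_end:
                raise AnnotationError(
                    f"{self.transcript_id}: bad exon structure")
            prev = e

    @property
    def length(self) -> int:
        """Transcript span, annotated start to end."""
        return self.tx_end - self.tx_start

    @property
    def exonic_length(self) -> int:
        if not self.exons:
            return self.length
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    def window(self, lo_offset: int, hi_offset: int) -> tuple[int, int]:
        """Genomic half-open interval for a TSS-relative offset pair.

        Offsets are in transcript orientation; they are mirrored for minus
        strand so that "+x" runs into the gene body on both strands.
        """
        if self.strand == "+":
            return (self.tss + lo_offset, self.tss + hi_offset)
        return (self.tss - hi_offset, self.tss - lo_offset)


@dataclass
class AnalysisWindows:
    """Strand-aware genomic windows for one transcript.

    ``gene_body`` and ``k36_window`` are ``None`` for transcripts too short
    to contain them.
    """

    transcript_id: str
    chrom: str
    strand: str
    promoter_polII: tuple[int, int]
    promoter_k4k27: tuple[int, int]
    k36_window: Optional[tuple[int, int]] = None
    gene_body: Optional[tuple[int, int]] = None


@dataclass
class EligibilitySet:
    """Per-transcript survival flags and per-gene eligibility.

    ``transcripts`` columns: gene_id, chrom, strand, tx_start, tx_end,
    length, polII_ok, k4k27_ok, reason_polII, reason_k4k27 (empty string when
    the transcript survives that analysis).
    ``genes`` columns: promoter_eligible, stalling_eligible, k36_eligible.
    """

    transcripts: pd.DataFrame
    genes: pd.DataFrame

    def surviving(self, analysis: str = "k4k27") -> pd.DataFrame:
        col = {"k4k27": "k4k27_ok", "polII": "polII_ok"}[analysis]
        return self.transcripts[self.transcripts[col]]

    def reason_counts(self) -> pd.Series:
        """Count exclusion reasons over both analyses (a transcript excluded
        for the same reason in both is counted once)."""
        reasons = []
        for _, row in self.transcripts.iterrows():
            rs = {row.reason_polII, row.reason_k4k27} - {""}
            reasons.extend(sorted(rs))
        return pd.Series(reasons, dtype=object).value_counts()

    def to_tsv(self, path) -> None:
        self.transcripts.to_csv(path, sep="\t", index_label="transcript_id")


# ---------------------------------------------------------------------------
# annotation IO
# ---------------------------------------------------------------------------

def _parse_refflat_line(fields: Sequence[str], lineno: int) -> TranscriptModel:
    # refFlat: geneName name chrom strand txStart txEnd cdsStart cdsEnd
    #          exonCount exonStarts exonEnds
    # genePred: same without the leading geneName
    if len(fields) >= 11:
        gene, name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
        tx_start, tx_end = int(fields[4]), int(fields[5])
        n_exons = int(fields[8])
        starts = [int(x) for x in fields[9].rstrip(",").split(",") if x]
        ends = [int(x) for x in fields[10].rstrip(",").split(",") if x]
    elif len(fields) >= 10:
        name, chrom, strand = fields[0], fields[1], fields[2]
        gene = name
        tx_start, tx_end = int(fields[3]), int(fields[4])
        n_exons = int(fields[7])
        starts = [int(x) for x in fields[8].rstrip(",").split(",") if x]
        ends = [int(x) for x in fields[9].rstrip(",").split(",") if x]
    else:
        raise AnnotationError(f"line {lineno}: expected >= 10 fields")
    if len(starts) != n_exons or len(ends) != n_exons:
        raise AnnotationError(f"line {lineno}: exon count mismatch")
    return TranscriptModel(name, gene, chrom, strand, tx_start, tx_end,
                           tuple(zip(starts, ends)))


def _parse_bed12_line(fields: Sequence[str], lineno: int) -> TranscriptModel:
    if len(fields) < 12:
        raise AnnotationError(f"line {lineno}: expected 12 BED fields")
    chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
    strand = fields[5]
    sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",") if x]
    exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
    return TranscriptModel(name, name, chrom, strand, start, end, exons)


def load_annotation(path, format: str = "genepred") -> list[TranscriptModel]:
    """Read transcripts from genePred/refFlat, BED12 or GTF.

    Records with an unknown strand symbol are dropped with a warning;
    structurally malformed lines raise :class:`AnnotationError` naming the
    line number.
    """
    fmt = format.lower()
    if fmt == "gtf":
        return _load_gtf(path)
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if fmt in ("genepred", "refflat"):
                    t = _parse_refflat_line(fields, lineno)
                elif fmt == "bed12":
                    t = _parse_bed12_line(fields, lineno)
                else:
                    raise AnnotationError(f"unknown format {format!r}")
            except AnnotationError as exc:
                if "strand" in str(exc):
                    warnings.warn(f"line {lineno}: {exc}; record skipped")
                    continue
                raise
            except (ValueError, IndexError) as exc:
                raise AnnotationError(f"line {lineno}: {exc}") from exc
            out.append(t)
    return out


def _load_gtf(path) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True,
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    out = []
    for tr in db.features_of_type("transcript"):
        exons = tuple(sorted((e.start - 1, e.end)
                             for e in db.children(tr, featuretype="exon")))
        if tr.strand not in ("+", "-"):
            warnings.warn(f"{tr.id}: unknown strand; record skipped")
            continue
        out.append(TranscriptModel(
            tr.attributes["transcript_id"][0],
            tr.attributes["gene_id"][0],
            tr.seqid, tr.strand, tr.start - 1, tr.end, exons))
    return out


def write_refflat(transcripts: Iterable[TranscriptModel], path) -> None:
    """Write transcripts as refFlat (geneName-first genePred dialect)."""
    with open(path, "w") as fh:
        for t in transcripts:
            exons = t.exons or ((t.tx_start, t.tx_end),)
            starts = ",".join(str(s) for s, _ in exons) + ","
            ends = ",".join(str(e) for _, e in exons) + ","
            fh.write("\t".join([
                t.gene_id, t.transcript_id, t.chrom, t.strand,
                str(t.tx_start), str(t.tx_end),
                str(t.tx_start), str(t.tx_end),
                str(len(exons)), starts, ends]) + "\n")


# ---------------------------------------------------------------------------
# eligibility filtering
# ---------------------------------------------------------------------------

def filter_transcripts(
    transcripts: Sequence[TranscriptModel],
    min_len: int = 500,
    tss_gap: int = 400,
    known_chroms: Optional[set] = None,
) -> EligibilitySet:
    """Apply the three-step eligibility filter.

    Per-analysis semantics: a transcript is excluded from a promoter analysis
    iff its promoter window for that analysis intersects the transcript span
    of a different gene (``overlap_conflict``).  The TSS-distance rule
    (``tss_too_close``, opposite-strand non-overlapping pairs with TSSs closer
    than ``tss_gap``) applies only to the Pol II analysis.  Transcripts below
    ``min_len`` (``too_short``) and on unknown chromosomes
    (``unknown_chrom``) are excluded from both.
    """
    n = len(transcripts)
    reason_pol = [""] * n
    reason_k4 = [""] * n

    for i, t in enumerate(transcripts):
        if known_chroms is not None and t.chrom not in known_chroms:
            reason_pol[i] = reason_k4[i] = "unknown_chrom"
        elif t.length < min_len:
            reason_pol[i] = reason_k4[i] = "too_short"

    # span tree per chromosome for the overlap rule (step 2a)
    trees: dict[str, IntervalTree] = {}
    for i, t in enumerate(transcripts):
        trees.setdefault(t.chrom, IntervalTree()).addi(
            t.tx_start, t.tx_end, (i, t.gene_id))

    for i, t in enumerate(transcripts):
        if reason_pol[i] and reason_k4[i]:
            continue
        for kind, reasons in (("promoter_polII", reason_pol),
                              ("promoter_k4k27", reason_k4)):
            if reasons[i]:
                continue
            lo, hi = t.window(*WINDOW_OFFSETS[kind])
            lo = max(lo, 0)
            if hi <= lo:
                reasons[i] = "too_short"
                continue
            for hit in trees[t.chrom].overlap(lo, hi):
                if hit.data[1] != t.gene_id:
                    reasons[i] = "overlap_conflict"
                    break

    # step 2b: opposite-strand non-overlapping TSS proximity (Pol II only)
    by_chrom: dict[str, list[int]] = {}
    for i, t in enumerate(transcripts):
        by_chrom.setdefault(t.chrom, []).append(i)
    for idxs in by_chrom.values():
        tss = np.array([transcripts[i].tss for i in idxs])
        order = np.argsort(tss, kind="stable")
        sorted_tss = tss[order]
        for k, oi in enumerate(order):
            i = idxs[oi]
            ti = transcripts[i]
            if reason_pol[i]:
                continue
            lo = np.searchsorted(sorted_tss, ti.tss - tss_gap + 1, "left")
            hi = np.searchsorted(sorted_tss, ti.tss + tss_gap - 1, "right")
            for m in range(lo, hi):
                j = idxs[order[m]]
                if j == i:
                    continue
                tj = transcripts[j]
                if (tj.gene_id != ti.gene_id and tj.strand != ti.strand
                        and (tj.tx_end <= ti.tx_start
                             or ti.tx_end <= tj.tx_start)
                        and abs(tj.tss - ti.tss) < tss_gap):
                    reason_pol[i] = "tss_too_close"
                    break

    tdf = pd.DataFrame({
        "gene_id": [t.gene_id for t in transcripts],
        "chrom": [t.chrom for t in transcripts],
        "strand": [t.strand for t in transcripts],
        "tx_start": [t.tx_start for t in transcripts],
        "tx_end": [t.tx_end for t in transcripts],
        "length": [t.length for t in transcripts],
        "polII_ok": [r == "" for r in reason_pol],
        "k4k27_ok": [r == "" for r in reason_k4],
        "reason_polII": reason_pol,
        "reason_k4k27": reason_k4,
    }, index=pd.Index([t.transcript_id for t in transcripts],
                      name="transcript_id"))

    surv_any = tdf.polII_ok | tdf.k4k27_ok
    gene_grp = tdf.assign(surv_any=surv_any).groupby("gene_id", sort=True)
    genes = pd.DataFrame({
        "promoter_eligible": gene_grp.surv_any.any(),
        "stalling_eligible": gene_grp.apply(
            lambda g: bool((g.polII_ok & (g.length > GENE_BODY_MIN_LEN)).any()),
            include_groups=False),
        "k36_eligible": gene_grp.apply(
            lambda g: bool((((g.polII_ok | g.k4k27_ok)
                             & (g.length > K36_MIN_LEN))).any()),
            include_groups=False),
    })
    return EligibilitySet(transcripts=tdf, genes=genes)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def derive_windows(t: TranscriptModel) -> AnalysisWindows:
    """Derive the strand-aware analysis windows for one transcript.

    Windows extending past the chromosome start are truncated at 0 with a
    warning.  ``gene_body`` is present only for transcripts longer than 1 kb;
    ``k36_window`` only beyond 1.5 kb.
    """

    def mk(kind):
        lo, hi = t.window(*WINDOW_OFFSETS[kind])
        if lo < 0:
            warnings.warn(
                f"{t.transcript_id}: {kind} truncated at chromosome start")
            lo = max(lo, 0)
        return (lo, hi)

    return AnalysisWindows(
        transcript_id=t.transcript_id,
        chrom=t.chrom,
        strand=t.strand,
        promoter_polII=mk("promoter_polII"),
        promoter_k4k27=mk("promoter_k4k27"),
        k36_window=mk("k36_window") if t.length > K36_MIN_LEN else None,
        gene_body=mk("gene_body") if t.length > GENE_BODY_MIN_LEN else None,
    )


def windows_table(transcripts: Iterable[TranscriptModel]) -> pd.DataFrame:
    """Tabulate analysis windows (one row per transcript).

    Absent windows appear as NaN start/end pairs.
    """
    rows = []
    for t in transcripts:
        w = derive_windows(t)
        row = {"transcript_id": t.transcript_id, "gene_id": t.gene_id,
               "chrom": t.chrom, "strand": t.strand, "tss": t.tss,
               "length": t.length}
        for kind in WINDOW_OFFSETS:
            iv = getattr(w, kind)
            row[f"{kind}_start"] = iv[0] if iv else np.nan
            row[f"{kind}_end"] = iv[1] if iv else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("transcript_id")


# ---------------------------------------------------------------------------
# dominant transcript selection
# ---------------------------------------------------------------------------

RULE_CHAINS = ("polII_vs_rpkm", "k4_vs_k27", "k36_vs_rpkm")


class NoSelectionError(ValueError):
    """Raised when a gene has no eligible transcript for the chain."""


def select_dominant_transcript(
    transcripts: Sequence[TranscriptModel],
    rule_chain: str,
    counts: pd.DataFrame,
    seed: int = 0,
) -> str:
    """Pick the single representative isoform of a gene.

    ``counts`` is indexed by transcript_id with columns ``polII_promoter``,
    ``k4_promoter``, ``k36_body`` and ``polII_body`` (read counts in the
    corresponding windows; NaN/missing treated as 0).

    Each chain applies its ordered criteria, keeping at every stage only the
    transcripts that maximize the current key; remaining ties fall through to
    the longest transcript and finally to a seeded random choice.  The
    secondary criterion is length-conditional per transcript: e.g. for the
    Pol II chain, gene-body Pol II reads for transcripts longer than 1 kb and
    H3K4me3 promoter reads otherwise.
    """
    if rule_chain not in RULE_CHAINS:
        raise ValueError(f"unknown rule chain {rule_chain!r}")
    cand = list(transcripts)
    if rule_chain == "k36_vs_rpkm":
        cand = [t for t in cand if t.length > K36_MIN_LEN]
    if not cand:
        raise NoSelectionError("gene has no eligible transcript")
    if len(cand) == 1:
        return cand[0].transcript_id

    def cnt(t, col):
        try:
            v = counts.at[t.transcript_id, col]
        except KeyError:
            return 0.0
        return 0.0 if pd.isna(v) else float(v)

    if rule_chain == "polII_vs_rpkm":
        keys = [
            lambda t: cnt(t, "polII_promoter"),
            lambda t: (cnt(t, "polII_body") if t.length > GENE_BODY_MIN_LEN
                       else cnt(t, "k4_promoter")),
        ]
    elif rule_chain == "k4_vs_k27":
        keys = [
            lambda t: cnt(t, "k4_promoter"),
            lambda t: (cnt(t, "k36_body") if t.length > K36_MIN_LEN
                       else cnt(t, "polII_promoter")),
        ]
    else:  # k36_vs_rpkm
        keys = [
            lambda t: cnt(t, "k36_body"),
            lambda t: cnt(t, "k4_promoter"),
        ]
    keys.append(lambda t: t.length)

    for key in keys:
        vals = [key(t) for t in cand]
        best = max(vals)
        cand = [t for t, v in zip(cand, vals) if v == best]
        if len(cand) == 1:
            return cand[0].transcript_id

    ids = sorted(t.transcript_id for t in cand)
    return random.Random(seed).choice(ids)
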