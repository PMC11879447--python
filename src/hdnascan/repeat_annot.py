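"""Short tandem repeat and G-quadruplex annotation.

The STR scanner reports every maximal exact tandem run with a primitive
repeat unit of 1..max_unit bp and at least ``min_copies`` full copies; the
final copy may be partial.  "Maximal" means the run cannot be extended on
either side with the same period; each run is reported once, under its
primitive (smallest-period) unit.  No mismatches are tolerated.

The G-quadruplex scanner scores each base by the canonical G/C-run rule:
every base inside a run of L consecutive Gs scores +min(L, 4), every base in
a C-run scores -min(L, 4), all other bases 0.  Regions are called where a
sliding-window mean reaches a threshold on the G-rich (+) or C-rich (-)
side; qualifying windows are merged and trimmed to the longest sub-span
whose mean still meets the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome_io import AnnotationTrack, SequenceRecord, intersect_bp, merge_intervals, total_bp

__all__ = [
    "TandemRepeat",
    "G4Region",
    "scan_strs",
    "oracle_strs",
    "bp_overlap_fraction",
    "g4hunter_scores",
    "detect_g4",
    "strs_to_track",
    "g4_to_track",
]


@dataclass(frozen=True)
class TandemRepeat:
    chrom: str
    start: int
    end: int
    unit: str
    copies: float

    def __post_init__(self) -> None:
        if self.end - self.start < 2 * len(self.unit):
            raise ValueError("tandem run must cover at least two unit copies")


@dataclass(frozen=True)
class G4Region:
    chrom: str
    start: int
    end: int
    mean_score: float

    @property
    def strand(self) -> str:
        return "+" if self.mean_score > 0 else "-"


# ---------------------------------------------------------------------------
# STRs
# ---------------------------------------------------------------------------


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) spans of consecutive True values."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def scan_strs(
    record: SequenceRecord, max_unit: int = 9, min_copies: int = 2
) -> list[TandemRepeat]:
    """Maximal exact tandem runs with primitive unit length 1..max_unit.

    A run found under period u is reported only when u is the smallest period
    of its span, so e.g. "AAAA" is one unit-"A" run, never a unit-"AA" run.
    Non-ACGT characters never match, splitting runs.
    """
    seq = record.seq.upper()
    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    n = arr.size
    valid = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))

    # match_u[i] == True iff seq[i] == seq[i+u] with both positions ACGT
    matches: dict[int, np.ndarray] = {}
    prefix: dict[int, np.ndarray] = {}
    for u in range(1, max_unit + 1):
        if n <= u:
            matches[u] = np.zeros(0, dtype=bool)
        else:
            matches[u] = (arr[:-u] == arr[u:]) & valid[:-u] & valid[u:]
        prefix[u] = np.concatenate([[0], np.cumsum(matches[u], dtype=np.int64)])

    def has_period(span_start: int, span_end: int, q: int) -> bool:
        m_len = (span_end - q) - span_start
        if m_len <= 0:
            return False
        return (prefix[q][span_end - q] - prefix[q][span_start]) == m_len

    out: list[TandemRepeat] = []
    for u in range(1, max_unit + 1):
        for i, j in _runs_of_true(matches[u]):
            span_start, span_end = i, j + u
            if span_end - span_start < min_copies * u:
                continue
            # report under the smallest period only
            if any(has_period(span_start, span_end, q) for q in range(1, u)):
                continue
            out.append(
                TandemRepeat(
                    chrom=record.id,
                    start=span_start,
                    end=span_end,
                    unit=seq[span_start : span_start + u],
                    copies=(span_end - span_start) / u,
                )
            )
    out.sort(key=lambda r: (r.start, r.end, len(r.unit)))
    return out


def oracle_strs(
    record: SequenceRecord, max_unit: int = 9, min_copies: int = 2, max_len: int = 2000
) -> list[TandemRepeat]:
    """Brute-force periodicity check; reference for :func:`scan_strs`."""
    n = len(record.seq)
    if n > max_len:
        raise ValueError(f"oracle_strs limited to {max_len} bp (got {n})")
    seq = record.seq.upper()
    acgt = set("ACGT")

    def matches_at(i: int, u: int) -> bool:
        return (
            i + u < n
            and seq[i] in acgt
            and seq[i + u] in acgt
            and seq[i] == seq[i + u]
        )

    out = []
    for u in range(1, max_unit + 1):
        i = 0
        while i < n:
            if not matches_at(i, u):
                i += 1
                continue
            j = i
            while matches_at(j, u):
                j += 1
            span_start, span_end = i, j + u
            i = j + 1
            if span_end - span_start < min_copies * u:
                continue
            # smallest period of the span
            smaller = False
            for q in range(1, u):
                if all(
                    matches_at(t, q) for t in range(span_start, span_end - q)
                ):
                    smaller = True
                    break
            if smaller:
                continue
            out.append(
                TandemRepeat(
                    chrom=record.id,
                    start=span_start,
                    end=span_end,
                    unit=seq[span_start : span_start + u],
                    copies=(span_end - span_start) / u,
                )
            )
    out.sort(key=lambda r: (r.start, r.end, len(r.unit)))
    return out


def bp_overlap_fraction(a: AnnotationTrack, b: AnnotationTrack) -> float:
    """Fraction of a's covered bp that are also covered by b.

    bp(merge(a) & merge(b)) / bp(merge(a)); NaN when a covers no bp.
    """
    am = merge_intervals(a)
    denom = total_bp(am)
    if denom == 0:
        return math.nan
    _, num = intersect_bp(am, merge_intervals(b))
    return num / denom


# ---------------------------------------------------------------------------
# G-quadruplexes
# ---------------------------------------------------------------------------


def g4hunter_scores(record: SequenceRecord) -> np.ndarray:
    """Per-base signed G4 propensity scores.

    Bases in a G-run of length L score +min(L, 4); C-runs score -min(L, 4);
    everything else scores 0.  Case-insensitive.
    """
    arr = np.frombuffer(record.seq.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    scores = np.zeros(arr.size, dtype=np.float64)
    for base, sign in ((ord("G"), 1.0), (ord("C"), -1.0)):
        mask = arr == base
        for i, j in _runs_of_true(mask):
            scores[i:j] = sign * min(j - i, 4)
    return scores


def _trim_to_threshold(scores: np.ndarray, start: int, end: int, threshold: float) -> tuple[int, int] | None:
    """Longest (leftmost on ties) sub-span of [start, end) with mean >= threshold."""
    seg = scores[start:end]
    csum = np.concatenate([[0.0], np.cumsum(seg)])
    m = seg.size
    for length in range(m, 0, -1):
        sums = csum[length:] - csum[: m - length + 1]
        idx = np.flatnonzero(sums >= threshold * length)
        if idx.size:
            i = int(idx[0])
            return start + i, start + i + length
    return None


def detect_g4(
    record: SequenceRecord, window: int = 25, threshold: float = 1.5
) -> list[G4Region]:
    """G-quadruplex-prone regions from windowed mean scores.

    A window qualifies when its mean score is >= threshold (G-rich, +) or
    <= -threshold (C-rich, -).  Overlapping qualifying windows of the same
    sign are merged, then the merged span is trimmed to the longest sub-span
    whose mean still meets the threshold.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    scores = g4hunter_scores(record)
    n = scores.size
    if n < window:
        return []
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    means = (csum[window:] - csum[:-window]) / window

    out: list[G4Region] = []
    for sign in (1.0, -1.0):
        qual = sign * means >= threshold
        for i, j in _runs_of_true(qual):
            # union of windows starting in [i, j)
            span = _trim_to_threshold(sign * scores, i, j - 1 + window, threshold)
            if span is None:
                continue
            s, e = span
            out.append(
                G4Region(
                    chrom=record.id,
                    start=s,
                    end=e,
                    mean_score=float(scores[s:e].mean()),
                )
            )
    out.sort(key=lambda r: (r.start, r.end))
    return out


# ---------------------------------------------------------------------------
# track conversion
# ---------------------------------------------------------------------------


def strs_to_track(strs: list[TandemRepeat], name: str = "str") -> AnnotationTrack:
    from .genome_io import GenomicInterval

    return AnnotationTrack(
        name=name,
        intervals=[GenomicInterval(r.chrom, r.start, r.end) for r in strs],
        metadata=[(r.unit, f"{r.copies:.2f}", ".") for r in strs],
    )


def g4_to_track(regions: list[G4Region], name: str = "g4") -> AnnotationTrack:
    from .genome_io import GenomicInterval

    return AnnotationTrack(
        name=name,
        intervals=[GenomicInterval(r.chrom, r.start, r.end) for r in regions],
        metadata=[("G4", f"{r.mean_score:.3f}", r.strand) for r in regions],
    )
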