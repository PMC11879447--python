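"""Position-anchored motif density profiles.

A positional profile counts motif base pairs at each signed offset from a
set of anchor positions (TSSs, TESs, peak centers), sums over anchors, and
normalizes by the window mean so that a flat background has enrichment 1.
Minus-strand anchors flip the offset sign, putting "downstream" at positive
offsets for every gene.  The counting unit is motif bp per offset (motifs
are merged first so overlapping motifs count once per base).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import BinProfile, assign_bins, bootstrap_quantiles
from .genome_io import AnnotationTrack, GenomicInterval, merge_intervals
from .motif_scan import MirrorRepeat

__all__ = [
    "PositionalProfile",
    "PeakSet",
    "RdnaArrayProfile",
    "site_profile",
    "rdna_bin_profile",
    "filter_and_merge_peaks",
    "arm_pwm",
    "max_enrichment_class",
]


@dataclass
class PositionalProfile:
    """Counts and window-mean-normalized enrichment per signed offset."""

    offsets: np.ndarray  # -W .. +W
    counts: np.ndarray
    units: np.ndarray | None = None  # per-anchor count matrix (n_anchors, 2W+1)
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None

    @property
    def enrichment(self) -> np.ndarray:
        mean = self.counts.mean()
        if mean == 0:
            return np.full(self.counts.size, math.nan)
        return self.counts / mean

    def add_bootstrap_ci(
        self, N: int = 1000, q_lo: float = 0.025, q_hi: float = 0.975, seed: int | None = None
    ) -> "PositionalProfile":
        """Bootstrap band on the enrichment by resampling anchors."""
        if self.units is None:
            raise ValueError("profile was built without per-anchor units")

        def stat(mat: np.ndarray) -> np.ndarray:
            col = mat.sum(axis=0).astype(np.float64)
            m = col.mean()
            return col / m if m > 0 else np.full(col.size, math.nan)

        self.ci_lo, self.ci_hi = bootstrap_quantiles(
            self.units, statistic=stat, N=N, q_lo=q_lo, q_hi=q_hi, seed=seed
        )
        return self


@dataclass
class PeakSet:
    """Peak intervals with optional q-value metadata (FDR)."""

    intervals: list[GenomicInterval]
    qvalues: list[float] | None = None
    name: str = "peaks"

    def __post_init__(self) -> None:
        if self.qvalues is not None:
            if len(self.qvalues) != len(self.intervals):
                raise ValueError("qvalues must parallel intervals")
            for q in self.qvalues:
                if not (0.0 <= q <= 1.0):
                    raise ValueError(f"q-value {q} outside [0, 1]")

    def anchors(self) -> list[tuple[str, int, str]]:
        """(chrom, center, strand) anchors; center = floor of the midpoint."""
        return [(iv.chrom, (iv.start + iv.end) // 2, "+") for iv in self.intervals]


@dataclass
class RdnaArrayProfile:
    """Bin profile of one tandem array plus genic-overlay bin spans."""

    array: GenomicInterval
    profile: BinProfile
    overlays: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


def _motif_arrays(motifs) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    if isinstance(motifs, AnnotationTrack):
        track = motifs
    else:
        track = AnnotationTrack("motifs", [m.interval() for m in motifs])
    merged = merge_intervals(track)
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in merged.intervals:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        c: (np.asarray([p[0] for p in v]), np.asarray([p[1] for p in v]))
        for c, v in by.items()
    }


def site_profile(
    anchors: list[tuple[str, int, str]],
    motifs,
    half_window: int = 3000,
    chrom_sizes: dict[str, int] | None = None,
    keep_units: bool = False,
) -> PositionalProfile:
    """Motif-bp counts per signed offset around a set of anchors.

    ``anchors`` are (chrom, position, strand) triples; minus-strand anchors
    flip the offset sign.  Anchors near a chromosome edge contribute only
    their in-bounds offsets (``chrom_sizes`` bounds the right edge; the left
    edge is bounded at 0 always).  ``keep_units`` retains the per-anchor
    count matrix so a bootstrap band can be added.
    """
    if not anchors:
        raise ValueError("need at least one anchor")
    W = half_window
    width = 2 * W + 1
    arrays = _motif_arrays(motifs)
    counts = np.zeros(width, dtype=np.int64)
    units = np.zeros((len(anchors), width), dtype=np.int32) if keep_units else None

    for ai, (chrom, pos, strand) in enumerate(anchors):
        if chrom not in arrays:
            continue
        starts, ends = arrays[chrom]
        lo_g = max(pos - W, 0)
        hi_g = pos + W + 1
        if chrom_sizes is not None and chrom in chrom_sizes:
            hi_g = min(hi_g, chrom_sizes[chrom])
        # motif intervals overlapping [lo_g, hi_g)
        first = int(np.searchsorted(ends, lo_g, side="right"))
        row = np.zeros(width, dtype=np.int64)
        for k in range(first, starts.size):
            if starts[k] >= hi_g:
                break
            s = max(int(starts[k]), lo_g)
            e = min(int(ends[k]), hi_g)
            if strand == "-":
                o_lo, o_hi = pos - e + 1, pos - s + 1  # flipped offsets
            else:
                o_lo, o_hi = s - pos, e - pos
            row[o_lo + W : o_hi + W] += 1
        counts += row
        if units is not None:
            units[ai] = row
    return PositionalProfile(
        offsets=np.arange(-W, W + 1), counts=counts, units=units
    )


def rdna_bin_profile(
    array_track: AnnotationTrack,
    motifs,
    n_bins: int = 3500,
    genic_overlays: AnnotationTrack | None = None,
    overlay_names: list[str] | None = None,
) -> list[RdnaArrayProfile]:
    """Per-array bin profiles of motif occurrences within tandem arrays.

    Motifs are restricted to each array span and binned in array-relative
    coordinates; ``profile.fraction`` gives the count-over-total
    normalization.  Genic overlays (e.g. 18S/5.8S/28S spans) are reported as
    1-based bin ranges per array; names come from ``overlay_names`` or the
    overlay metadata column.
    """
    if not array_track.intervals:
        raise ValueError("array track is empty")
    if isinstance(motifs, AnnotationTrack):
        motif_ivs = motifs.intervals
    else:
        motif_ivs = [m.interval() for m in motifs]
    out = []
    for arr in array_track.intervals:
        local = [
            GenomicInterval(arr.chrom, iv.start - arr.start, iv.end - arr.start)
            for iv in motif_ivs
            if iv.chrom == arr.chrom and iv.start >= arr.start and iv.end <= arr.end
        ]
        profile = assign_bins(local, chrom_size=len(arr), n_bins=n_bins)
        overlays: dict[str, list[tuple[int, int]]] = {}
        if genic_overlays is not None:
            meta = genic_overlays.metadata or [()] * len(genic_overlays.intervals)
            for gi, (giv, gmeta) in enumerate(zip(genic_overlays.intervals, meta)):
                if giv.chrom != arr.chrom or giv.end <= arr.start or giv.start >= arr.end:
                    continue
                s = max(giv.start, arr.start) - arr.start
                e = min(giv.end, arr.end) - arr.start
                from .enrichment import bin_span

                b0 = bin_span(s, len(arr), n_bins)
                b1 = bin_span(e - 1, len(arr), n_bins)
                gname = (
                    overlay_names[gi]
                    if overlay_names is not None
                    else (gmeta[0] if gmeta else f"overlay{gi}")
                )
                overlays.setdefault(gname, []).append((b0, b1))
        out.append(RdnaArrayProfile(array=arr, profile=profile, overlays=overlays))
    return out


def filter_and_merge_peaks(peaks: PeakSet, q_max: float = 0.005) -> AnnotationTrack:
    """Keep peaks with q strictly below ``q_max``, then merge overlaps.

    A peak with q exactly equal to ``q_max`` is dropped.  Peak sets without
    q-values are rejected; merge without filtering via
    ``merge_intervals(AnnotationTrack(...))`` when no FDR column exists.
    """
    if peaks.qvalues is None:
        raise ValueError(
            "peak set carries no q-values; to skip FDR filtering, merge the "
            "raw intervals instead (merge_intervals)"
        )
    kept = [
        iv for iv, q in zip(peaks.intervals, peaks.qvalues) if q < q_max
    ]
    return merge_intervals(AnnotationTrack(name=peaks.name, intervals=kept))


def arm_pwm(
    motifs: list[MirrorRepeat],
    anchors: list[tuple[str, int, str]],
    half_window: int = 3000,
) -> pd.DataFrame:
    """Position-frequency matrix of first-arm sequences near anchors.

    Collects the first arm of every motif whose span intersects any anchor
    window, takes the modal arm length L, and reports per-position base
    frequencies (rows A/C/G/T, columns 1..L) over the arms of length >= L
    (aligned at the arm start, truncated to L).  Empty when no motif lies in
    any window.
    """
    windows: dict[str, list[tuple[int, int]]] = {}
    for chrom, pos, _ in anchors:
        windows.setdefault(chrom, []).append((pos - half_window, pos + half_window + 1))
    arms: list[str] = []
    for m in motifs:
        spans = windows.get(m.chrom, ())
        if any(m.start < hi and m.end > lo for lo, hi in spans):
            arms.append(m.arm1.upper())
    if not arms:
        return pd.DataFrame(index=list("ACGT"))
    lengths = pd.Series([len(a) for a in arms])
    modal = int(lengths.mode().iloc[0])
    usable = [a[:modal] for a in arms if len(a) >= modal]
    mat = np.zeros((4, modal), dtype=np.float64)
    index = {b: i for i, b in enumerate("ACGT")}
    for a in usable:
        for j, ch in enumerate(a):
            if ch in index:
                mat[index[ch], j] += 1
    mat /= mat.sum(axis=0, keepdims=True)
    return pd.DataFrame(mat, index=list("ACGT"), columns=range(1, modal + 1))


def max_enrichment_class(
    profile: PositionalProfile, radius: int = 250
) -> tuple[float, int, bool]:
    """Maximum enrichment, its offset, and whether it lies within ``radius``.

    Ties resolve toward the smallest |offset| (negative side first on exact
    |offset| ties).
    """
    enr = profile.enrichment
    if np.isnan(enr).all():
        raise ValueError("enrichment undefined (window mean is zero)")
    order = sorted(
        range(enr.size),
        key=lambda i: (-enr[i], abs(int(profile.offsets[i])), int(profile.offsets[i])),
    )
    best = order[0]
    off = int(profile.offsets[best])
    return float(enr[best]), off, abs(off) <= radius
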