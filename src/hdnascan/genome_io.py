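"""Genomic I/O and interval algebra.

All coordinates inside the package are 0-based half-open (BED-native);
GFF3's 1-based inclusive convention is converted at the parsing boundary.
Chromosome names are matched by exact string equality -- no "chr" aliasing.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("hdnascan")

__all__ = [
    "GenomicInterval",
    "SequenceRecord",
    "AnnotationTrack",
    "GeneAnchor",
    "BedParseError",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_gff_genes",
    "merge_intervals",
    "intersect_bp",
    "reciprocal_overlap_filter",
    "total_bp",
    "complement_track",
]


class FastaParseError(ValueError):
    """Raised on a malformed FASTA file."""


class BedParseError(ValueError):
    """Raised on a malformed BED line; message carries the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SequenceRecord:
    """A named nucleotide sequence; letters are kept verbatim (case preserved)."""

    id: str
    seq: str


@dataclass
class AnnotationTrack:
    """A named set of intervals (one subcompartment, repeat class, motif set ...).

    ``metadata`` carries the extra BED columns (beyond chrom/start/end) of each
    interval, as opaque string tuples, parallel to ``intervals``.
    ``consolidated`` is True once intervals are sorted and per-chromosome
    non-overlapping (the state :func:`merge_intervals` guarantees).
    """

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    consolidated: bool = False
    metadata: list[tuple[str, ...]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)


@dataclass(frozen=True)
class GeneAnchor:
    """A gene with strand-resolved TSS/TES positions (0-based)."""

    gene_id: str
    chrom: str
    tss: int
    tes: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be +/- (gene {self.gene_id})")
        if self.tss == self.tes:
            raise ValueError(f"tss == tes for gene {self.gene_id}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a plain or gzipped FASTA into records, preserving letter case.

    Raises :class:`FastaParseError` (naming the offending line) when the first
    non-blank line is not a ``>`` header.
    """
    with _open_text(path) as fh:
        text_start = fh.tell()
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header "
                        f"starting with '>', got {line.strip()[:30]!r}"
                    )
                break
        fh.seek(text_start)
        return [
            SequenceRecord(id=rec.id, seq=str(rec.seq))
            for rec in SeqIO.parse(fh, "fasta")
        ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, name: str | None = None) -> AnnotationTrack:
    """Read a BED file (0-based half-open) into an unconsolidated track.

    Columns past the third are retained verbatim in ``track.metadata`` so that
    score / q-value columns survive for downstream filters.
    """
    intervals: list[GenomicInterval] = []
    metadata: list[tuple[str, ...]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates {s!r}/{e!r}"
                ) from exc
            if start >= end:
                raise BedParseError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})"
                )
            intervals.append(GenomicInterval(chrom, start, end))
            metadata.append(tuple(fields[3:]))
    return AnnotationTrack(
        name=name or Path(path).stem,
        intervals=intervals,
        consolidated=False,
        metadata=metadata,
    )


def write_bed(track: AnnotationTrack, path: str | Path) -> None:
    """Write a track as BED; metadata columns (if any) follow the coordinates."""
    meta = track.metadata or [()] * len(track.intervals)
    with open(path, "wt") as fh:
        for iv, extra in zip(track.intervals, meta):
            cols = [iv.chrom, str(iv.start), str(iv.end), *extra]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff_genes(
    path: str | Path,
    feature_types: Sequence[str] = ("gene",),
    biotypes: Sequence[str] | None = None,
) -> list[GeneAnchor]:
    """Extract strand-resolved gene anchors from a GFF3 file.

    GFF3 is 1-based inclusive; positions are converted to 0-based here.
    TSS is the 5' end by strand and TES the 3' end, so for a ``-`` strand gene
    the TSS is the larger coordinate.  Records without a defined strand are
    skipped with a warning; feature types outside ``feature_types`` are
    ignored.  ``biotypes`` optionally restricts by the ``gene_biotype`` (or
    ``biotype``) attribute, e.g. ``("protein_coding",)`` or ``("rRNA",)``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    anchors: list[GeneAnchor] = []
    for ftype in feature_types:
        try:
            feats = list(db.features_of_type(ftype))
        except Exception:
            continue
        for feat in feats:
            if biotypes is not None:
                bt = feat.attributes.get("gene_biotype", feat.attributes.get("biotype", [None]))[0]
                if bt not in biotypes:
                    continue
            if feat.strand not in {"+", "-"}:
                logger.warning("skipping %s %s: undefined strand", ftype, feat.id)
                continue
            start0 = feat.start - 1  # 1-based inclusive -> 0-based
            end0 = feat.end - 1
            tss, tes = (start0, end0) if feat.strand == "+" else (end0, start0)
            gid = feat.attributes.get("ID", [feat.id])[0]
            anchors.append(
                GeneAnchor(gene_id=gid, chrom=feat.seqid, tss=tss, tes=tes, strand=feat.strand)
            )
    return anchors


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def _per_chrom_arrays(track: AnnotationTrack) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in track.intervals:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by.items():
        arr = np.asarray(sorted(pairs), dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted intervals; bookended spans ([1,5),[5,9)) coalesce."""
    if starts.size == 0:
        return starts, ends
    keep_s = [starts[0]]
    keep_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= keep_e[-1]:  # overlap OR bookended
            if e > keep_e[-1]:
                keep_e[-1] = e
        else:
            keep_s.append(s)
            keep_e.append(e)
    return np.asarray(keep_s, dtype=np.int64), np.asarray(keep_e, dtype=np.int64)


def merge_intervals(track: AnnotationTrack) -> AnnotationTrack:
    """Consolidate a track: sort and union overlapping/bookended intervals.

    Base-pair coverage is preserved; metadata does not survive merging.
    Idempotent.
    """
    merged: list[GenomicInterval] = []
    for chrom in sorted({iv.chrom for iv in track.intervals}):
        starts, ends = _per_chrom_arrays(track)[chrom]
        ms, me = _merge_arrays(starts, ends)
        merged.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(ms, me))
    return AnnotationTrack(name=track.name, intervals=merged, consolidated=True)


def total_bp(track: AnnotationTrack) -> int:
    """Base pairs covered by the track (consolidating first)."""
    t = track if track.consolidated else merge_intervals(track)
    return sum(len(iv) for iv in t.intervals)


def intersect_bp(a: AnnotationTrack, b: AnnotationTrack) -> tuple[list[GenomicInterval], int]:
    """Overlap intervals and total overlapping bp between two tracks.

    Both inputs are consolidated first, so shared bp are counted once.
    """
    am = a if a.consolidated else merge_intervals(a)
    bm = b if b.consolidated else merge_intervals(b)
    a_arr = _per_chrom_arrays(am)
    b_arr = _per_chrom_arrays(bm)
    out: list[GenomicInterval] = []
    bp = 0
    for chrom in sorted(set(a_arr) & set(b_arr)):
        as_, ae = a_arr[chrom]
        bs, be = b_arr[chrom]
        i = j = 0
        while i < as_.size and j < bs.size:
            s = max(as_[i], bs[j])
            e = min(ae[i], be[j])
            if s < e:
                out.append(GenomicInterval(chrom, int(s), int(e)))
                bp += int(e - s)
            if ae[i] <= be[j]:
                i += 1
            else:
                j += 1
    return out, bp


def reciprocal_overlap_filter(
    a: AnnotationTrack, b: AnnotationTrack, frac: float
) -> AnnotationTrack:
    """Keep intervals of ``a`` that reciprocally overlap some interval of ``b``.

    An a-interval is kept when some b-interval shares at least
    ``frac * len(a_iv)`` AND ``frac * len(b_iv)`` base pairs with it.
    """
    if not (0.0 < frac <= 1.0):
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    b_arr = _per_chrom_arrays(b)
    kept: list[GenomicInterval] = []
    for iv in a.intervals:
        if iv.chrom not in b_arr:
            continue
        bs, be = b_arr[iv.chrom]
        # candidates: b.start < iv.end and b.end > iv.start
        lo = int(np.searchsorted(bs, iv.end, side="left"))
        for k in range(lo):
            if be[k] <= iv.start:
                continue
            ov = min(iv.end, int(be[k])) - max(iv.start, int(bs[k]))
            if ov >= frac * len(iv) and ov >= frac * (be[k] - bs[k]):
                kept.append(iv)
                break
    return AnnotationTrack(name=a.name, intervals=kept, consolidated=False)


def complement_track(track: AnnotationTrack, chrom_sizes: dict[str, int], name: str = "complement") -> AnnotationTrack:
    """Intervals of each chromosome NOT covered by ``track``."""
    t = track if track.consolidated else merge_intervals(track)
    arr = _per_chrom_arrays(t)
    out: list[GenomicInterval] = []
    for chrom, size in chrom_sizes.items():
        if chrom not in arr:
            out.append(GenomicInterval(chrom, 0, size))
            continue
        starts, ends = arr[chrom]
        prev = 0
        for s, e in zip(starts, ends):
            if s > prev:
                out.append(GenomicInterval(chrom, int(prev), int(s)))
            prev = max(prev, int(e))
        if prev < size:
            out.append(GenomicInterval(chrom, prev, size))
    return AnnotationTrack(name=name, intervals=out, consolidated=True)
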