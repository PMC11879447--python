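"""Synthetic genomes with planted mirror repeats and a truth ledger.

The generator emulates the genomic structure the analysis assumes: an
i.i.d. background of a stated GC content, tandem rDNA-like arrays whose
units carry rRNA-gene placeholders (18S/5.8S/28S) and CT-rich H-DNA motifs
planted at fixed intergenic-spacer offsets (giving the periodic enrichment
signal), protein-coding-like gene annotations with strand, and synthetic
peak sets overlapping a stated fraction of the planted motifs.  Every
planted element is recorded in a :class:`SyntheticTruth` ledger so scanner
recovery, density recovery and profile shape can be checked exactly.

Every planted locus is validated at generation time against the scanner
definitions: planted H-DNAs must be recoverable at their exact coordinates,
mirror-only plants must pass the mirror definition but fail the
compositional filter, and decoys must not overlap any detectable mirror
repeat.  Flanks that accidentally extend or spawn repeats are locally
redrawn (rejection sampling), so the ledger is exhaustive at the planted
loci; elsewhere in a large background, unplanned chance motifs are allowed
and recovery is judged on planted loci only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import (
    AnnotationTrack,
    GeneAnchor,
    GenomicInterval,
    SequenceRecord,
    write_fasta,
)
from .metaprofile import PeakSet
from .motif_scan import MirrorRepeat, ScanParams, scan_hdna, scan_mirror_repeats

__all__ = [
    "SyntheticSpec",
    "PlantedMotif",
    "SyntheticTruth",
    "SyntheticGenome",
    "generate_genome",
    "generate_peaks",
    "evaluate_recovery",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed planted templates (arm, spacer); the H-DNA arm/spacer reconstructs the
# modal CT-rich rDNA motif ctctctctgtctgtctctctc (arm 10, spacer 1)
_HDNA_ARM, _HDNA_SPACER = "CTCTCTCTGT", "C"
_MIRROR_ARM, _MIRROR_SPACER = "ACGTACGTAC", "G"  # mirror-symmetric, mixed composition
_DECOY = "CTCTCTCTGT" + "C" + "TGACTCGCTC"  # arm2 broken at two inner positions


def _mirror_motif(arm: str, spacer: str) -> str:
    return arm + spacer + arm[::-1]


@dataclass(frozen=True)
class SyntheticSpec:
    """Layout and rates of a synthetic genome; ``seed`` is mandatory.

    The defaults give a 10 Mb single-chromosome genome at human-like 41% GC
    with five 50 kb rDNA-like arrays (5 kb unit x 10 copies).  Each unit
    carries 18S/5.8S/28S placeholders and three H-DNA motifs planted in the
    intergenic spacer, and the background carries enough additional planted
    motifs that the array-vs-background motif density ratio equals
    ``array_fold`` (40x by default, the enrichment scale reported for human
    rDNA arrays).
    """

    seed: int
    genome_len: int = 10_000_000
    gc: float = 0.41
    chrom_name: str = "chr1"
    n_arrays: int = 5
    unit_len: int = 5000
    units_per_array: int = 10
    genic_layout: tuple[tuple[str, int, int], ...] = (
        ("18S", 200, 800),
        ("5.8S", 900, 960),
        ("28S", 1100, 2600),
    )
    igs_offsets: tuple[int, ...] = (3000, 3800, 4500)
    array_fold: float = 40.0
    n_mirror_only: int = 20
    n_decoys: int = 20
    gene_count: int = 40
    gene_len_range: tuple[int, int] = (2000, 8000)
    tes_motif_offset: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")
        if self.array_fold <= 0:
            raise ValueError("array_fold must be positive")
        motif_len = len(_mirror_motif(_HDNA_ARM, _HDNA_SPACER))
        for name, s, e in self.genic_layout:
            if not (0 <= s < e <= self.unit_len):
                raise ValueError(f"genic span {name} does not fit in the unit")
        genic_hi = max((e for _, _, e in self.genic_layout), default=0)
        for off in self.igs_offsets:
            if off < genic_hi or off + motif_len + 20 > self.unit_len:
                raise ValueError(
                    f"IGS motif offset {off} collides with genic layout or unit end"
                )
        if self.n_arrays * self.unit_len * self.units_per_array >= self.genome_len:
            raise ValueError("arrays do not fit in the genome")

    @property
    def array_len(self) -> int:
        return self.unit_len * self.units_per_array

    @property
    def n_array_motifs(self) -> int:
        return self.n_arrays * self.units_per_array * len(self.igs_offsets)


@dataclass(frozen=True)
class PlantedMotif:
    chrom: str
    start: int
    end: int
    arm_len: int
    spacer_len: int
    cls: str  # hdna | mirror | decoy
    in_array: bool


@dataclass
class SyntheticTruth:
    """Ledger of everything the generator planted."""

    chrom_name: str
    genome_len: int
    motifs: list[PlantedMotif] = field(default_factory=list)
    arrays: list[GenomicInterval] = field(default_factory=list)
    genic: list[tuple[str, GenomicInterval]] = field(default_factory=list)
    genes: list[GeneAnchor] = field(default_factory=list)
    peaks: PeakSet | None = None

    def planted(self, cls: str, in_array: bool | None = None) -> list[PlantedMotif]:
        return [
            m
            for m in self.motifs
            if m.cls == cls and (in_array is None or m.in_array == in_array)
        ]

    def array_track(self) -> AnnotationTrack:
        return AnnotationTrack("rdna_array", list(self.arrays), consolidated=True)


@dataclass
class SyntheticGenome:
    record: SequenceRecord
    truth: SyntheticTruth
    spec: SyntheticSpec

    def write_outputs(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome.fa, truth.tsv, arrays.bed, genic.bed, genes.gff3[, peaks.bed]."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        paths["fasta"] = outdir / "genome.fa"
        write_fasta([self.record], paths["fasta"])

        paths["truth"] = outdir / "truth.tsv"
        with open(paths["truth"], "wt") as fh:
            fh.write("chrom\tstart\tend\tarm_len\tspacer_len\tclass\tin_array\n")
            for m in self.truth.motifs:
                fh.write(
                    f"{m.chrom}\t{m.start}\t{m.end}\t{m.arm_len}\t{m.spacer_len}"
                    f"\t{m.cls}\t{int(m.in_array)}\n"
                )

        paths["arrays"] = outdir / "arrays.bed"
        with open(paths["arrays"], "wt") as fh:
            for iv in self.truth.arrays:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\trdna_array\n")

        paths["genic"] = outdir / "genic.bed"
        with open(paths["genic"], "wt") as fh:
            for name, iv in self.truth.genic:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")

        paths["gff"] = outdir / "genes.gff3"
        with open(paths["gff"], "wt") as fh:
            fh.write("##gff-version 3\n")
            for g in self.truth.genes:
                s0 = min(g.tss, g.tes)
                e0 = max(g.tss, g.tes)
                fh.write(
                    f"{g.chrom}\thdnascan_sim\tgene\t{s0 + 1}\t{e0 + 1}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id};gene_biotype=protein_coding\n"
                )
            for i, (name, iv) in enumerate(self.truth.genic):
                fh.write(
                    f"{iv.chrom}\thdnascan_sim\trRNA\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"+\t.\tID=rrna{i};Name={name};gene_biotype=rRNA\n"
                )

        if self.truth.peaks is not None:
            paths["peaks"] = outdir / "peaks.bed"
            pk = self.truth.peaks
            qvals = pk.qvalues or [0.0] * len(pk.intervals)
            with open(paths["peaks"], "wt") as fh:
                for iv, q in zip(pk.intervals, qvals):
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak\t0\t.\t{q:.6g}\n")
        return paths


# ---------------------------------------------------------------------------
# planting machinery
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _window_scan(
    genome: np.ndarray, lo: int, hi: int, params: ScanParams, hdna_only: bool
) -> list[MirrorRepeat]:
    lo, hi = max(lo, 0), min(hi, genome.size)
    rec = SequenceRecord(id="w", seq=genome[lo:hi].tobytes().decode("ascii"))
    reps = scan_hdna(rec, params) if hdna_only else scan_mirror_repeats(rec, params)
    return [
        MirrorRepeat(
            chrom=rec.id,
            start=r.start + lo,
            end=r.end + lo,
            arm_len=r.arm_len,
            spacer_len=r.spacer_len,
            seq=r.seq,
            frac_ag=r.frac_ag,
            frac_ct=r.frac_ct,
            frac_at=r.frac_at,
            is_hdna=r.is_hdna,
        )
        for r in reps
    ]


def _plant_validated(
    genome: np.ndarray,
    start: int,
    motif: str,
    cls: str,
    params: ScanParams,
    rng: np.random.Generator,
    gc: float,
    max_tries: int = 100,
) -> None:
    """Write a motif into the genome and locally rejection-sample its flanks.

    Validation per class: 'hdna' and 'mirror' plants must be reported by the
    scanner at exactly the planted span (with/without the H-DNA flag);
    'decoy' plants must not overlap any reported mirror repeat.  Flanking
    bases (12 bp each side) are redrawn until validation passes.
    """
    end = start + len(motif)
    margin = 2 * params.min_arm + params.max_spacer + 10
    genome[start:end] = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    for attempt in range(max_tries):
        if cls == "decoy":
            reps = _window_scan(genome, start - margin, end + margin, params, False)
            bad = [r for r in reps if r.start < end and r.end > start]
            if not bad:
                return
        else:
            reps = _window_scan(genome, start - margin, end + margin, params, cls == "hdna")
            if any(r.start == start and r.end == end for r in reps):
                return
        flank = 12
        lo = max(start - flank, 0)
        genome[lo:start] = _random_bases(rng, start - lo, gc)
        hi = min(end + flank, genome.size)
        genome[end:hi] = _random_bases(rng, hi - end, gc)
    raise RuntimeError(
        f"could not validate planted {cls} motif at {start} after {max_tries} tries"
    )


def generate_genome(
    spec: SyntheticSpec, params: ScanParams = ScanParams()
) -> SyntheticGenome:
    """Build a synthetic genome, its annotations, and the truth ledger.

    Deterministic given ``spec.seed``.  Arrays are exact tandem copies of a
    per-array unit sequence, so planted IGS motifs recur at a fixed phase in
    every copy; the background receives enough extra planted motifs that the
    array-vs-background planted-motif density ratio equals
    ``spec.array_fold``.
    """
    rng = np.random.default_rng(spec.seed)
    chrom = spec.chrom_name
    genome = _random_bases(rng, spec.genome_len, spec.gc)
    truth = SyntheticTruth(chrom_name=chrom, genome_len=spec.genome_len)
    hdna_motif = _mirror_motif(_HDNA_ARM, _HDNA_SPACER)
    mirror_motif = _mirror_motif(_MIRROR_ARM, _MIRROR_SPACER)

    # --- tandem arrays ---
    array_len = spec.array_len
    gap = (spec.genome_len - spec.n_arrays * array_len) / (spec.n_arrays + 1)
    array_starts = [
        int(round(gap * (i + 1) + array_len * i)) for i in range(spec.n_arrays)
    ]
    for a_start in array_starts:
        unit = _random_bases(rng, spec.unit_len, spec.gc)
        for off in spec.igs_offsets:
            unit[off : off + len(hdna_motif)] = np.frombuffer(
                hdna_motif.encode("ascii"), dtype=np.uint8
            )
        tiled = np.tile(unit, spec.units_per_array)
        genome[a_start : a_start + array_len] = tiled
        truth.arrays.append(GenomicInterval(chrom, a_start, a_start + array_len))
        for copy in range(spec.units_per_array):
            u0 = a_start + copy * spec.unit_len
            for name, gs, ge in spec.genic_layout:
                truth.genic.append((name, GenomicInterval(chrom, u0 + gs, u0 + ge)))
            for off in spec.igs_offsets:
                _plant_validated(
                    genome, u0 + off, hdna_motif, "hdna", params, rng, spec.gc
                )
                truth.motifs.append(
                    PlantedMotif(
                        chrom,
                        u0 + off,
                        u0 + off + len(hdna_motif),
                        len(_HDNA_ARM),
                        len(_HDNA_SPACER),
                        "hdna",
                        True,
                    )
                )

    # NB: flank redraws inside one unit copy are not propagated to the other
    # copies, which is fine -- each copy is validated in its own context.

    occupied = [(s, s + array_len) for s in array_starts]

    def _free_position(length: int, margin: int = 100, tries: int = 1000) -> int:
        for _ in range(tries):
            pos = int(rng.integers(margin, spec.genome_len - length - margin))
            if all(
                pos + length + margin <= s or pos >= e + margin for s, e in occupied
            ):
                return pos
        raise RuntimeError("could not place an element in the background")

    # --- background planted H-DNA, sized to hit the target fold ratio ---
    bg_bp = spec.genome_len - spec.n_arrays * array_len
    array_bp = spec.n_arrays * array_len
    n_bg = int(round(spec.n_array_motifs * bg_bp / (spec.array_fold * array_bp)))
    for cls, template, n in (
        ("hdna", hdna_motif, n_bg),
        ("mirror", mirror_motif, spec.n_mirror_only),
        ("decoy", _DECOY, spec.n_decoys),
    ):
        for _ in range(n):
            pos = _free_position(len(template))
            _plant_validated(genome, pos, template, cls, params, rng, spec.gc)
            truth.motifs.append(
                PlantedMotif(
                    chrom,
                    pos,
                    pos + len(template),
                    len(_HDNA_ARM),
                    len(_HDNA_SPACER),
                    cls,
                    False,
                )
            )
            occupied.append((pos, pos + len(template)))

    # --- protein-coding-like genes ---
    lo_len, hi_len = spec.gene_len_range
    tes_margin = (spec.tes_motif_offset or 0) + len(hdna_motif) + 100
    for i in range(spec.gene_count):
        glen = int(rng.integers(lo_len, hi_len + 1))
        pos = _free_position(glen + 2 * tes_margin) + tes_margin
        strand = "+" if rng.random() < 0.5 else "-"
        s0, e0 = pos, pos + glen
        tss, tes = (s0, e0 - 1) if strand == "+" else (e0 - 1, s0)
        truth.genes.append(
            GeneAnchor(
                gene_id=f"gene{i}", chrom=chrom, tss=tss, tes=tes, strand=strand
            )
        )
        occupied.append((pos - tes_margin, pos + glen + tes_margin))
        if spec.tes_motif_offset is not None:
            off = spec.tes_motif_offset
            if strand == "+":
                m_start = tes + off
            else:
                m_start = tes - off - len(hdna_motif) + 1
            _plant_validated(genome, m_start, hdna_motif, "hdna", params, rng, spec.gc)
            truth.motifs.append(
                PlantedMotif(
                    chrom,
                    m_start,
                    m_start + len(hdna_motif),
                    len(_HDNA_ARM),
                    len(_HDNA_SPACER),
                    "hdna",
                    False,
                )
            )

    record = SequenceRecord(id=chrom, seq=genome.tobytes().decode("ascii"))
    return SyntheticGenome(record=record, truth=truth, spec=spec)


def generate_peaks(
    truth: SyntheticTruth,
    frac_on_motif: float,
    n_peaks: int,
    peak_len: int,
    seed: int,
    q_pass_frac: float = 0.9,
    jitter: int = 10,
) -> PeakSet:
    """Synthetic peak set: a stated fraction centered on planted H-DNA motifs.

    ``frac_on_motif`` of the peaks are centered (with +/- ``jitter`` bp of
    noise) on randomly chosen planted H-DNA motifs; the rest are uniform on
    the genome.  q-values are drawn so that round(q_pass_frac * n_peaks) of
    them pass the strict q < 0.005 filter; pass/fail labels are assigned to
    peaks at random.  The peak set is also attached to ``truth.peaks``.
    """
    if not (0.0 <= frac_on_motif <= 1.0):
        raise ValueError("frac_on_motif must be in [0, 1]")
    if n_peaks > truth.genome_len // max(peak_len, 1):
        raise ValueError("n_peaks exceeds genome capacity")
    rng = np.random.default_rng(seed)
    planted = truth.planted("hdna")
    n_on = int(round(frac_on_motif * n_peaks))
    if n_on > 0 and not planted:
        raise ValueError("no planted H-DNA motifs to center peaks on")

    intervals: list[GenomicInterval] = []
    half = peak_len // 2
    for _ in range(n_on):
        m = planted[int(rng.integers(0, len(planted)))]
        center = (m.start + m.end) // 2 + int(rng.integers(-jitter, jitter + 1))
        s = max(center - half, 0)
        s = min(s, truth.genome_len - peak_len)
        intervals.append(GenomicInterval(truth.chrom_name, s, s + peak_len))
    for _ in range(n_peaks - n_on):
        s = int(rng.integers(0, truth.genome_len - peak_len))
        intervals.append(GenomicInterval(truth.chrom_name, s, s + peak_len))

    n_pass = int(round(q_pass_frac * n_peaks))
    qvals = np.empty(n_peaks)
    qvals[:n_pass] = rng.uniform(1e-8, 0.0049, size=n_pass)
    qvals[n_pass:] = rng.uniform(0.006, 0.5, size=n_peaks - n_pass)
    rng.shuffle(qvals)
    peaks = PeakSet(intervals=intervals, qvalues=qvals.tolist(), name="synthetic_peaks")
    truth.peaks = peaks
    return peaks


def evaluate_recovery(
    truth: SyntheticTruth, scanned: list[MirrorRepeat]
) -> dict[str, float]:
    """Compare scanner output with the planted ledger.

    Returns counts of planted canonical H-DNAs recovered at their exact
    coordinates and of decoys overlapped by any reported motif (false
    positives).
    """
    spans = {(m.start, m.end) for m in scanned}
    by_start = sorted(scanned, key=lambda m: m.start)
    starts = np.asarray([m.start for m in by_start])
    ends = np.asarray([m.end for m in by_start])

    planted = truth.planted("hdna")
    recovered = sum((p.start, p.end) in spans for p in planted)
    decoy_hits = 0
    for d in truth.planted("decoy"):
        k = int(np.searchsorted(starts, d.end, side="left"))
        if np.any(ends[:k] > d.start):
            decoy_hits += 1
    return {
        "n_planted": len(planted),
        "n_recovered": recovered,
        "recovery_rate": recovered / len(planted) if planted else float("nan"),
        "n_decoys": len(truth.planted("decoy")),
        "decoy_false_positives": decoy_hits,
    }
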