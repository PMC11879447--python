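import numpy as np
import pytest

from hdnascan.genome_io import AnnotationTrack, GenomicInterval
from hdnascan.metaprofile import (
    PeakSet,
    PositionalProfile,
    arm_pwm,
    filter_and_merge_peaks,
    max_enrichment_class,
    rdna_bin_profile,
    site_profile,
)
from hdnascan.motif_scan import MirrorRepeat


def _track(pairs, chrom="chr1", name="m"):
    return AnnotationTrack(name, [GenomicInterval(chrom, s, e) for s, e in pairs])


class TestSiteProfile:
    def test_single_motif_spike(self):
        prof = site_profile([("chr1", 500, "+")], _track([(600, 601)]), half_window=300)
        assert prof.counts.sum() == 1
        assert prof.counts[np.flatnonzero(prof.counts)[0]] == 1
        assert int(prof.offsets[np.argmax(prof.counts)]) == 100

    def test_minus_strand_flips_offsets(self):
        # motif physically left of a minus-strand anchor appears downstream (+)
        prof = site_profile([("chr1", 500, "-")], _track([(400, 401)]), half_window=300)
        assert int(prof.offsets[np.argmax(prof.counts)]) == 100

    def test_counts_conserved_with_window_coverage(self):
        from hdnascan.genome_io import intersect_bp

        motifs = _track([(100, 130), (480, 520), (900, 905)])
        anchors = [("chr1", 500, "+")]
        W = 200
        prof = site_profile(anchors, motifs, half_window=W)
        windows = _track([(300, 701)])
        _, bp = intersect_bp(motifs, windows)
        assert int(prof.counts.sum()) == bp

    def test_enrichment_mean_is_one(self):
        prof = site_profile([("chr1", 500, "+")], _track([(400, 650)]), half_window=300)
        assert prof.enrichment.mean() == pytest.approx(1.0)

    def test_strand_negation_reverses_profile(self):
        motifs = _track([(550, 580), (350, 360)])
        plus = site_profile([("chr1", 500, "+")], motifs, half_window=300)
        minus = site_profile([("chr1", 500, "-")], motifs, half_window=300)
        np.testing.assert_array_equal(plus.counts, minus.counts[::-1])

    def test_empty_anchors_rejected(self):
        with pytest.raises(ValueError):
            site_profile([], _track([(0, 5)]))

    def test_zero_counts_returns_nan_enrichment(self):
        prof = site_profile([("chr1", 500, "+")], _track([(5000, 5010)]), half_window=100)
        assert np.isnan(prof.enrichment).all()
        assert prof.counts.sum() == 0


class TestPeakFiltering:
    def _peaks(self, qs):
        ivs = [GenomicInterval("chr1", 100 * i, 100 * i + 50) for i in range(len(qs))]
        return PeakSet(intervals=ivs, qvalues=qs)

    def test_boundary_q_dropped_strictly(self):
        kept = filter_and_merge_peaks(self._peaks([0.005]))
        assert kept.intervals == []

    def test_below_threshold_kept(self):
        kept = filter_and_merge_peaks(self._peaks([0.004]))
        assert len(kept.intervals) == 1

    def test_overlapping_kept_peaks_merge(self):
        ivs = [
            GenomicInterval("chr1", 0, 60),
            GenomicInterval("chr1", 50, 120),
            GenomicInterval("chr1", 110, 200),
        ]
        kept = filter_and_merge_peaks(PeakSet(intervals=ivs, qvalues=[1e-4] * 3))
        assert [(iv.start, iv.end) for iv in kept.intervals] == [(0, 200)]

    def test_missing_q_column_directs_user(self):
        with pytest.raises(ValueError, match="no q-values"):
            filter_and_merge_peaks(PeakSet(intervals=[GenomicInterval("chr1", 0, 5)]))

    def test_q_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            PeakSet(intervals=[GenomicInterval("chr1", 0, 5)], qvalues=[1.5])


class TestArmPwm:
    def _motif(self, start, arm, spacer="C"):
        seq = arm + spacer + arm[::-1]
        return MirrorRepeat("chr1", start, start + len(seq), len(arm), len(spacer), seq)

    def test_identical_arms_indicator_columns(self):
        motifs = [self._motif(100 * i, "CTCTCTCTGT") for i in range(5)]
        pwm = arm_pwm(motifs, [("chr1", 250, "+")], half_window=3000)
        assert pwm.shape == (4, 10)
        np.testing.assert_allclose(pwm.max(axis=0).to_numpy(), np.ones(10))
        assert "".join(pwm.idxmax(axis=0)) == "CTCTCTCTGT"

    def test_even_mixture_gives_half_columns(self):
        motifs = [self._motif(0, "AAAAAAAAAA"), self._motif(100, "GGGGGGGGGG")]
        pwm = arm_pwm(motifs, [("chr1", 50, "+")], half_window=200)
        np.testing.assert_allclose(pwm.loc["A"].to_numpy(), 0.5)
        np.testing.assert_allclose(pwm.loc["G"].to_numpy(), 0.5)

    def test_no_motifs_in_vicinity_empty(self):
        motifs = [self._motif(100_000, "CTCTCTCTGT")]
        pwm = arm_pwm(motifs, [("chr1", 0, "+")], half_window=100)
        assert pwm.empty


class TestMaxEnrichmentClass:
    def _profile(self, counts):
        counts = np.asarray(counts)
        W = counts.size // 2
        return PositionalProfile(offsets=np.arange(-W, W + 1), counts=counts)

    def test_spike_at_zero_within_radius(self):
        counts = np.ones(501)
        counts[250] = 10
        _, off, within = max_enrichment_class(self._profile(counts), radius=250)
        assert off == 0 and within

    def test_spike_beyond_radius(self):
        counts = np.ones(1201)
        counts[600 + 500] = 9
        max_e, off, within = max_enrichment_class(self._profile(counts), radius=250)
        assert off == 500 and not within

    def test_tie_breaks_toward_center(self):
        counts = np.ones(201)
        counts[100 + 80] = 5
        counts[100 - 30] = 5
        _, off, _ = max_enrichment_class(self._profile(counts), radius=250)
        assert off == -30

    def test_undefined_enrichment_rejected(self):
        with pytest.raises(ValueError):
            max_enrichment_class(self._profile(np.zeros(11)))


class TestRdnaBinProfile:
    def test_uniform_planting_flat_fraction(self):
        array = AnnotationTrack("arr", [GenomicInterval("chr1", 0, 35_000)], consolidated=True)
        motifs = _track([(i * 10, i * 10 + 1) for i in range(3500)])
        out = rdna_bin_profile(array, motifs, n_bins=3500)
        assert len(out) == 1
        frac = out[0].profile.fraction
        np.testing.assert_allclose(frac, 1 / 3500, rtol=1e-9)

    def test_periodic_planting_phase(self):
        # 10 units of 1000 bp, motif at offset 300 in each unit -> peaks every
        # 350 bins of a 3500-bin profile, at a fixed phase
        array = AnnotationTrack("arr", [GenomicInterval("chr1", 0, 10_000)], consolidated=True)
        motifs = _track([(u * 1000 + 300, u * 1000 + 321) for u in range(10)])
        out = rdna_bin_profile(array, motifs, n_bins=3500)
        hot = np.flatnonzero(out[0].profile.counts)
        gaps = np.diff([hot[i] for i in range(0, len(hot), len(hot) // 10)])
        assert all(g == 350 for g in gaps)

    def test_genic_overlays_reported_in_bins(self):
        array = AnnotationTrack("arr", [GenomicInterval("chr1", 0, 35_000)], consolidated=True)
        genic = AnnotationTrack(
            "genic",
            [GenomicInterval("chr1", 0, 3500)],
            metadata=[("18S",)],
        )
        out = rdna_bin_profile(array, _track([(5, 6)]), n_bins=3500, genic_overlays=genic)
        assert out[0].overlays["18S"] == [(1, 350)]

    def test_empty_array_rejected(self):
        with pytest.raises(ValueError):
            rdna_bin_profile(AnnotationTrack("arr", []), _track([(0, 5)]))

    def test_motifs_outside_array_ignored(self):
        array = AnnotationTrack("arr", [GenomicInterval("chr1", 1000, 2000)], consolidated=True)
        out = rdna_bin_profile(array, _track([(10, 20), (1500, 1510)]), n_bins=10)
        assert out[0].profile.counts.sum() >= 1
        assert out[0].profile.counts.sum() <= 2  # outside motif not binned
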