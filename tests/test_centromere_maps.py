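"""End-count tracks, composites, peak calling, end bias, ratio tracks."""

import numpy as np
import pandas as pd
import pytest

import hemimap as hm
from hemimap.centromere_maps import CompositeHistogram
from conftest import toy_annotation, toy_fragments


class TestEndCountTrack:
    def test_window_assignment(self):
        tracks = hm.end_count_track(toy_fragments([("c", 100, 250)]), window=10)
        tr = tracks["c"]
        assert tr.left[10] == 1  # left end 100 in window [100, 110)
        assert tr.right[24] == 1  # right end 249 in window [240, 250)
        assert tr.left.sum() == tr.right.sum() == 1

    def test_end_count_conservation_is_2n(self, hemisome_run):
        frags = hemisome_run["filtered"]
        tracks = hm.end_count_track(frags, window=1)
        total = sum(tr.total.sum() for tr in tracks.values())
        assert total == 2 * len(frags)

    def test_most_cleaved_position_is_a_particle_neighborhood(self, hemisome_run):
        placements = hemisome_run["placements"]
        tracks = hm.end_count_track(hemisome_run["filtered"], window=1)
        tr = tracks["chr2"]
        pos = tr.most_cleaved_position()
        anchors = placements[placements["chrom"] == "chr2"]["anchor"].to_numpy()
        assert np.min(np.abs(anchors - pos)) <= 10

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            hm.end_count_track(toy_fragments([("c", 0, 10)]), window=0)


class TestCompositeHistogram:
    def test_left_end_at_anchor_counts_at_offset_zero(self):
        ann = toy_annotation()
        mid = int(ann.df.iloc[0]["mid_cen"])
        hist = hm.composite_histogram(
            toy_fragments([("chr1", mid, mid + 200)]), ann, flank=50
        )
        assert hist.left[50] == 1  # offset 0
        assert hist.total.sum() == 1  # right end outside the flank

    def test_minus_strand_reflection(self):
        rows = [dict(chrom="chr1", cde3_start=100, cde3_end=126, cde2_start=126,
                     cde2_end=209, cde1_start=209, cde1_end=217, strand="-")]
        ann = toy_annotation(rows)
        mid = int(ann.df.iloc[0]["mid_cen"])
        # a fragment END at mid+7 appears at offset -7 after reflection
        hist = hm.composite_histogram(
            toy_fragments([("chr1", mid - 300, mid + 8)]), ann, flank=50
        )
        assert hist.left[50 - 7] == 1  # genomic right end plays the left role

    def test_empty_length_class_rejected(self, hemisome_run):
        with pytest.raises(ValueError):
            hm.composite_histogram(
                hemisome_run["filtered"], hemisome_run["annotation"], [999]
            )

    def test_translation_invariance_of_spacings(self, hemisome_run):
        """Shifting all annotations and fragments together leaves spacings fixed."""
        frags = hemisome_run["filtered"]
        ann = hemisome_run["annotation"]
        shift = 37
        moved = hm.FragmentSet.from_arrays(
            frags.chrom, frags.start + shift, frags.end + shift
        )
        cols = ["cde1_start", "cde1_end", "cde2_start", "cde2_end",
                "cde3_start", "cde3_end"]
        df = ann.df.copy()
        df[cols] = df[cols] + shift
        ann2 = hm.CentromereAnnotation(
            df[["chrom"] + cols + ["strand"]]
        )
        h1 = hm.composite_histogram(frags, ann, [117, 118, 119, 120])
        h2 = hm.composite_histogram(moved, ann2, [117, 118, 119, 120])
        np.testing.assert_array_equal(h1.total, h2.total)


class TestPeakCalling:
    def _spike_hist(self, spikes, flank=60):
        offsets = np.arange(-flank, flank + 1)
        total = np.zeros(offsets.size, dtype=np.int64)
        for off, h in spikes.items():
            total[off + flank] = h
        return CompositeHistogram(offsets, total, np.zeros_like(total))

    def test_constructed_spikes_give_printed_spacings(self):
        hist = self._spike_hist({-26: 90, -16: 100, 17: 95, 27: 85})
        peaks = hm.call_peak_maxima(hist, 4, smooth_window=1)
        assert peaks.intra_cluster == (10, 10)
        assert peaks.inner == 33
        assert peaks.outer == 53

    def test_flat_histogram_has_no_maxima(self):
        hist = self._spike_hist({})
        with pytest.raises(ValueError):
            hm.call_peak_maxima(hist, 4)

    def test_too_few_maxima_reports_count(self):
        hist = self._spike_hist({0: 10, 30: 8})
        with pytest.raises(ValueError, match="only 2"):
            hm.call_peak_maxima(hist, 4, smooth_window=1)

    def test_min_separation_enforced(self):
        hist = self._spike_hist({0: 10, 2: 9, 30: 8, 40: 7})
        peaks = hm.call_peak_maxima(hist, 3, smooth_window=1, min_separation=5)
        assert list(peaks.offsets) == [0, 30, 40]  # offset 2 suppressed

    def test_hemisome_class_composite_has_four_peaks(self, hemisome_run):
        hist = hm.composite_histogram(
            hemisome_run["filtered"], hemisome_run["annotation"], [117, 118, 119, 120]
        )
        peaks = hm.call_peak_maxima(hist, 4, smooth_window=1)
        assert len(peaks.offsets) == 4
        # symmetric paired clusters around mid-Cen
        assert peaks.offsets[0] < -15 and peaks.offsets[3] > 15

    def test_octasome_composite_is_single_central_cluster(self, octasome_run):
        """The discriminating contrast: a two-H4 particle over mid-Cen gives one
        central cleavage cluster, not symmetric paired clusters."""
        hist = hm.composite_histogram(
            octasome_run["filtered"], octasome_run["annotation"], [117, 118, 119, 120]
        )
        peaks = hm.call_peak_maxima(hist, 2, smooth_window=1)
        assert np.all(np.abs(peaks.offsets) <= 12)


class TestEndBias:
    def test_unbiased_data_has_symmetric_ends(self, hemisome_run):
        """Without AT loss the bias statistic at the cleavage clusters
        (high-count windows) stays within 3 standard errors of zero."""
        unbiased = hemisome_run["sim"].fragments
        eb = hm.end_bias_histogram(
            unbiased, hemisome_run["annotation"].anchors(), flank=500, window=100
        )
        counts = eb["left"] + eb["right"]
        clusters = eb[counts > 1000]
        assert len(clusters) >= 4
        # 3 standard errors of (L-R)/(L+R) under symmetric ends ~ 3/sqrt(n)
        assert (clusters["bias"].abs() <= 3.0 / np.sqrt(counts[clusters.index])).all()

    def test_at_bias_depletes_spanning_fragment_ends(self, hemisome_run):
        """Fragments crossing CDEII are lost: the CDEI-side cluster loses left
        ends and the CDEIII-side cluster loses right ends."""
        eb = hm.end_bias_histogram(
            hemisome_run["filtered"], hemisome_run["annotation"].anchors(),
            flank=40, window=20,
        )
        left_cluster = eb[eb["offset"] == -40].iloc[0]  # window [-40, -20)
        right_cluster = eb[eb["offset"] == 0].iloc[0]  # window [0, 20)
        assert left_cluster["bias"] < -0.2
        assert right_cluster["bias"] > 0.2

    def test_fragment_left_of_anchor_contributes_negative_offsets(self):
        anchors = pd.DataFrame({"chrom": ["c"], "pos": [1000], "strand": ["+"]})
        eb = hm.end_bias_histogram(
            toy_fragments([("c", 500, 900)]), anchors, flank=600, window=10
        )
        hit = eb[(eb["left"] + eb["right"]) > 0]
        assert (hit["offset"] < 0).all()


class TestRatioTrack:
    def test_equal_tracks_are_zero(self):
        x = np.array([0.0, 3.0, 10.0])
        np.testing.assert_allclose(hm.ratio_track(x, x), 0.0)

    def test_doubling_gives_ones_in_the_limit(self):
        x = np.full(5, 1e6)
        np.testing.assert_allclose(hm.ratio_track(2 * x, x), 1.0, atol=1e-5)

    def test_double_zero_is_zero_and_mismatch_rejected(self):
        assert hm.ratio_track(np.zeros(3), np.zeros(3)).tolist() == [0.0] * 3
        with pytest.raises(ValueError):
            hm.ratio_track(np.zeros(3), np.zeros(4))
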