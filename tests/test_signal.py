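"""Insertion-site shifting, coverage tracks, footprint profiles, heatmaps."""

import numpy as np
import pytest

from greekislands.intervals import GenomicInterval, PeakSet
from greekislands.signal import (
    FragmentSet,
    InsertionSites,
    SignalTrack,
    coverage_track,
    end_density_profile,
    profile_heatmap,
    region_count_matrix,
    shift_to_insertions,
    subtract_tracks,
)

import oracles


def frags(intervals, lib=None):
    ivs = sorted(intervals, key=lambda v: v.sort_key())
    return FragmentSet("fs", ivs, lib if lib is not None else len(ivs))


class TestShiftToInsertions:
    def test_four_bp_interior_shift(self):
        out = shift_to_insertions(frags([GenomicInterval("chr1", 100, 200)]))
        assert out.sites == [("chr1", 104), ("chr1", 196)]
        assert out.n_clamped == 0

    def test_short_fragment_clamped_to_midpoint(self):
        out = shift_to_insertions(frags([GenomicInterval("chr1", 100, 108)]))
        assert out.sites == [("chr1", 104), ("chr1", 104)]
        assert out.n_clamped == 1

    def test_multiset_equals_per_fragment_oracle(self, rng):
        ivs = []
        for _ in range(100):
            s = int(rng.integers(0, 5000))
            ivs.append(GenomicInterval("chrT", s, s + int(rng.integers(1, 600))))
        got = sorted(shift_to_insertions(frags(ivs)).sites)
        exp = []
        for fr in ivs:
            if fr.end - fr.start < 9:
                m = (fr.start + fr.end) // 2
                exp += [("chrT", m), ("chrT", m)]
            else:
                exp += [("chrT", fr.start + 4), ("chrT", fr.end - 4)]
        assert got == sorted(exp)


class TestCoverageTrack:
    def test_identical_fragments_normalise_to_ten_million(self):
        ivs = [GenomicInterval("chr1", 10, 20)] * 5
        track = coverage_track(frags(ivs, lib=5), extend="full")
        assert np.allclose(track.values["chr1"][10:20], 1e7)
        assert np.allclose(track.values["chr1"][:10], 0)

    def test_empty_input_is_all_zero(self):
        track = coverage_track(frags([], lib=1), chrom_sizes={"chr1": 100})
        assert not track.values["chr1"].any()

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            coverage_track(InsertionSites([("chr1", 5)]), library_size=0, extend="1bp")

    def test_matches_per_bp_accumulation(self, rng):
        ivs = []
        for _ in range(60):
            s = int(rng.integers(0, 900))
            ivs.append(GenomicInterval("chrT", s, s + int(rng.integers(1, 80))))
        fs = frags(ivs, lib=60)
        track = coverage_track(fs, extend="full", chrom_sizes={"chrT": 1000})
        exp = oracles.coverage_bruteforce(ivs, {"chrT": 1000})
        assert np.allclose(track.values["chrT"], exp["chrT"] * (1e7 / 60))

    def test_track_sum_invariant(self, rng):
        ivs = [GenomicInterval("chrT", int(s), int(s) + 50)
               for s in rng.integers(0, 500, size=20)]
        fs = frags(ivs, lib=20)
        full = coverage_track(fs, extend="full")
        total = sum(a.sum() for a in full.values.values())
        assert total * 20 / 1e7 == pytest.approx(sum(v.length for v in ivs))
        ones = coverage_track(fs, extend="1bp")
        total1 = sum(a.sum() for a in ones.values.values())
        assert total1 * 20 / 1e7 == pytest.approx(2 * len(ivs))


class TestEndDensityProfile:
    def test_sites_at_center_fill_central_bin_only(self):
        centers = [("chr1", 100), ("chr1", 300)]
        sites = InsertionSites([("chr1", 100)] * 3 + [("chr1", 300)] * 3)
        prof = end_density_profile(sites, centers, flank_bp=25, bin_bp=5)
        central = prof[prof.bin_start == 0]
        assert central["mean"].iloc[0] == pytest.approx(3.0)
        assert central["sem"].iloc[0] == pytest.approx(0.0)
        assert prof[prof.bin_start != 0]["mean"].sum() == 0

    def test_single_center_has_zero_sem(self, rng):
        sites = InsertionSites([("chr1", int(p)) for p in rng.integers(0, 200, 50)])
        prof = end_density_profile(sites, [("chr1", 100)], flank_bp=50, bin_bp=5)
        assert (prof["sem"] == 0).all()

    def test_no_centers_rejected(self):
        with pytest.raises(ValueError):
            end_density_profile(InsertionSites([]), [], flank_bp=50)

    def test_pooled_mean_equals_pooled_histogram(self, rng):
        centers = [("chr1", 500), ("chr1", 1500), ("chr1", 2500)]
        sites = InsertionSites([("chr1", int(p)) for p in rng.integers(0, 3000, 400)])
        prof = end_density_profile(sites, centers, flank_bp=100, bin_bp=5)
        pooled = np.zeros(40)
        pos = np.array([p for _, p in sites.sites])
        for _, c in centers:
            sel = pos[(pos >= c - 100) & (pos < c + 100)]
            pooled += np.bincount((sel - (c - 100)) // 5, minlength=40)[:40]
        assert np.allclose(prof["mean"], pooled / len(centers))


class TestRegionCountMatrix:
    def test_single_overlap_counts_once(self):
        peaks = PeakSet("p", [GenomicInterval("chr1", 100, 200, id="p0")])
        fs = {"s1": frags([GenomicInterval("chr1", 150, 160)])}
        counts, norm = region_count_matrix(fs, peaks)
        assert counts.loc["p0", "s1"] == 1
        assert norm.loc["p0", "s1"] == pytest.approx(1e7)

    def test_fragment_spanning_two_peaks_counted_in_both(self):
        peaks = PeakSet("p", [
            GenomicInterval("chr1", 100, 200, id="p0"),
            GenomicInterval("chr1", 200, 300, id="p1"),
        ])
        fs = {"s1": frags([GenomicInterval("chr1", 190, 210)])}
        counts, _ = region_count_matrix(fs, peaks)
        assert counts["s1"].tolist() == [1, 1]

    def test_matches_bruteforce_tally(self, rng):
        peaks = oracles.random_peakset(rng, "p", 15, chrom_span=5000)
        ivs = [GenomicInterval("chrT", int(s), int(s) + int(rng.integers(1, 300)))
               for s in rng.integers(0, 4500, 80)]
        fs = {"s1": frags(ivs)}
        counts, _ = region_count_matrix(fs, peaks)
        assert counts["s1"].tolist() == oracles.region_counts_bruteforce(ivs, peaks)


class TestProfileHeatmap:
    def track(self, values):
        return SignalTrack({"chr1": np.asarray(values, dtype=float)}, 1.0)

    def test_uniform_track_constant_rows_stable_order(self):
        track = self.track(np.ones(1000))
        regions = [GenomicInterval("chr1", 300, 400, id=f"r{i}") for i in range(3)]
        pm = profile_heatmap(track, regions, flank_bp=50)
        assert np.allclose(pm.values, 1.0)
        assert pm.row_ids == ["r0", "r1", "r2"]  # ties keep input order

    def test_rows_sorted_by_mean_descending(self):
        arr = np.zeros(1000)
        arr[100:200] = 1.0
        arr[600:700] = 5.0
        track = self.track(arr)
        regions = [GenomicInterval("chr1", 100, 200, id="lo"),
                   GenomicInterval("chr1", 600, 700, id="hi")]
        pm = profile_heatmap(track, regions, flank_bp=20)
        assert pm.row_ids == ["hi", "lo"]

    def test_minus_strand_row_is_reversed(self):
        arr = np.arange(1000, dtype=float)
        track = self.track(arr)
        plus = GenomicInterval("chr1", 480, 520, strand="+")
        minus = GenomicInterval("chr1", 480, 520, strand="-")
        pm = profile_heatmap(track, [plus, minus], flank_bp=10)
        assert np.allclose(pm.values[0], pm.values[1][::-1])

    def test_identity_extraction(self):
        arr = np.arange(100, dtype=float)
        track = self.track(arr)
        reg = GenomicInterval("chr1", 20, 60)
        pm = profile_heatmap(track, [reg], flank_bp=0, scale_body=40)
        assert np.allclose(pm.values[0], arr[20:60])

    def test_region_outside_track_is_zeros(self):
        pm = profile_heatmap(self.track(np.ones(100)),
                             [GenomicInterval("chr2", 10, 30)], flank_bp=5)
        assert not pm.values.any()

    def test_body_scaling_window_mean_preserved(self, rng):
        arr = rng.random(2000)
        track = self.track(arr)
        reg = GenomicInterval("chr1", 500, 900)
        pm = profile_heatmap(track, [reg], flank_bp=0, scale_body=100)
        # linear interpolation keeps the coarse mean close to the direct mean
        assert pm.values[0].mean() == pytest.approx(arr[500:900].mean(), abs=0.05)


def test_subtract_tracks_clips_at_zero():
    a = SignalTrack({"chr1": np.array([3.0, 1.0, 0.0])}, 1.0)
    b = SignalTrack({"chr1": np.array([1.0, 5.0, 0.0])}, 1.0)
    out = subtract_tracks(a, b)
    assert out.values["chr1"].tolist() == [2.0, 0.0, 0.0]
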