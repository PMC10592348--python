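"""Decay scoring, TSS-window geometry, and peak-window association against
a brute-force all-pairs oracle."""

import numpy as np
import pandas as pd
import pytest

from tftarget.potential import (
    associate_peaks,
    decay,
    regulatory_potential,
    resize_regions,
)

from conftest import brute_force_pairs, make_peaks, make_windows, random_fixture


class TestDecay:
    @pytest.mark.parametrize("D", [50_000, 100_000])
    @pytest.mark.parametrize(
        "frac, expected",
        [(0.0, np.exp(-0.5)), (0.5, np.exp(-2.5)), (1.0, np.exp(-4.5))],
    )
    def test_known_points(self, D, frac, expected):
        assert decay(frac * D, D) == pytest.approx(expected, abs=1e-12)

    def test_strictly_decreasing_and_uncapped(self):
        d = np.arange(0, 300_001, 997)
        scores = decay(d, 100_000)
        assert np.all(np.diff(scores) < 0)
        assert decay(150_000, 100_000) > 0  # beyond-edge midpoints still score

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            decay(-1, 100_000)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            decay(10, 0)


def region(region_id, chrom, start, end, strand):
    return pd.DataFrame(
        [(chrom, start, end, region_id, 0, strand)],
        columns=["chrom", "start", "end", "region_id", "score", "strand"],
    )


class TestResizeRegions:
    def test_plus_strand_window(self):
        # a 100 kb half-width around a TSS at 51,376,688 spans
        # [51,276,688, 51,476,687]: width exactly 200,000
        win = resize_regions(region("NR_045762", "chr19", 51_376_688, 51_400_000, "+"), 100_000)
        assert (win.loc[0, "start"], win.loc[0, "end"]) == (51_276_688, 51_476_687)
        assert win.loc[0, "end"] - win.loc[0, "start"] + 1 == 200_000
        assert win.loc[0, "tss"] == 51_376_688

    def test_minus_strand_window(self):
        win = resize_regions(region("r1", "chr1", 400_000, 500_000, "-"), 100_000)
        assert (win.loc[0, "start"], win.loc[0, "end"]) == (400_001, 600_000)
        assert win.loc[0, "tss"] == 500_000

    def test_strandless_treated_as_plus(self):
        dot = resize_regions(region("r1", "chr1", 5_000, 9_000, "."), 1_000)
        plus = resize_regions(region("r1", "chr1", 5_000, 9_000, "+"), 1_000)
        pd.testing.assert_frame_equal(
            dot.drop(columns="strand"), plus.drop(columns="strand")
        )

    def test_left_clip_at_one(self, caplog):
        with caplog.at_level("INFO", logger="tftarget"):
            win = resize_regions(region("r1", "chr1", 50, 400, "+"), 100)
        assert win.loc[0, "start"] == 1
        assert "clipped" in caplog.text

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            resize_regions(region("r1", "chr1", 10, 20, "+"), 0)

    def test_width_invariant_unclipped(self, rng):
        _, windows = random_fixture(rng, 0, 100, D=1_000)
        widths = windows["end"] - windows["start"] + 1
        assert (widths == 2_000).all()


class TestAssociatePeaks:
    def test_peak_at_tss(self):
        windows = make_windows([("r1", "chr1", 900, 2899, "+", 1900)])
        peaks = make_peaks([("chr1", 1880, 1920, "p1")])
        assoc = associate_peaks(peaks, windows, 1_000)
        assert len(assoc) == 1
        assert assoc.loc[0, "distance"] == 0
        assert assoc.loc[0, "score"] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_chromosome_mismatch_empty(self):
        windows = make_windows([("r1", "chr1", 900, 2899, "+", 1900)])
        peaks = make_peaks([("chr2", 1880, 1920, "p1")])
        assert len(associate_peaks(peaks, windows, 1_000)) == 0

    def test_peak_in_two_overlapping_windows(self):
        windows = make_windows(
            [
                ("r1", "chr1", 1000, 2999, "+", 2000),
                ("r2", "chr1", 1500, 3499, "+", 2500),
            ]
        )
        peaks = make_peaks([("chr1", 1990, 2010, "p1")])
        assoc = associate_peaks(peaks, windows, 1_000)
        assert sorted(assoc["region_id"]) == ["r1", "r2"]

    def test_minus_strand_distance_sign(self):
        # midpoint 300 bp left of the TSS is downstream (+300) on "-"
        windows = make_windows([("r1", "chr1", 1001, 3000, "-", 2000)])
        peaks = make_peaks([("chr1", 1690, 1710, "p1")])
        assoc = associate_peaks(peaks, windows, 1_000)
        assert assoc.loc[0, "distance"] == 300

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        peaks, windows = random_fixture(rng, n_peaks=200, n_regions=50)
        got = associate_peaks(peaks, windows, 1_000)
        expected = brute_force_pairs(peaks, windows, 1_000)
        pd.testing.assert_frame_equal(got, expected)

    def test_pairs_unique(self, rng):
        peaks, windows = random_fixture(rng, n_peaks=300, n_regions=60)
        assoc = associate_peaks(peaks, windows, 1_000)
        assert not assoc.duplicated(["peak_id", "region_id"]).any()


class TestRegulatoryPotential:
    windows = make_windows(
        [
            ("r1", "chr1", 1000, 2999, "+", 2000),
            ("r2", "chr1", 5000, 6999, "+", 6000),
        ]
    )

    def test_zero_peak_window(self):
        assoc = pd.DataFrame(columns=["peak_id", "region_id", "distance", "score"])
        pot = regulatory_potential(assoc, self.windows)
        assert list(pot["potential"]) == [0.0, 0.0]
        assert list(pot["n_peaks"]) == [0, 0]

    def test_sum_of_decay_terms(self):
        D = 1_000
        assoc = pd.DataFrame(
            {
                "peak_id": ["p1", "p2"],
                "region_id": ["r1", "r1"],
                "distance": [0, D],
                "score": [np.exp(-0.5), np.exp(-4.5)],
            }
        )
        pot = regulatory_potential(assoc, self.windows)
        assert pot.loc[pot["region_id"] == "r1", "potential"].iloc[0] == pytest.approx(
            np.exp(-0.5) + np.exp(-4.5), abs=1e-12
        )
        assert pot.loc[pot["region_id"] == "r2", "potential"].iloc[0] == 0.0

    def test_orphan_region_rejected(self):
        assoc = pd.DataFrame(
            {"peak_id": ["p1"], "region_id": ["ghost"], "distance": [0], "score": [0.5]}
        )
        with pytest.raises(ValueError, match="ghost"):
            regulatory_potential(assoc, self.windows)


class TestPotentialProperties:
    def full_potentials(self, peaks, windows, D=1_000):
        return regulatory_potential(associate_peaks(peaks, windows, D), windows)

    def test_permuting_peaks_changes_nothing(self, rng):
        peaks, windows = random_fixture(rng, n_peaks=150, n_regions=40)
        base = self.full_potentials(peaks, windows)
        shuffled = peaks.sample(frac=1.0, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(self.full_potentials(shuffled, windows), base)

    def test_moving_peak_away_never_raises_score(self):
        windows = make_windows([("r1", "chr1", 1000, 2999, "+", 2000)])
        scores = []
        for offset in range(0, 900, 50):
            peaks = make_peaks([("chr1", 1995 + offset, 2005 + offset, "p1")])
            scores.append(associate_peaks(peaks, windows, 1_000).loc[0, "score"])
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_extra_overlapping_peak_strictly_increases_potential(self, rng):
        peaks, windows = random_fixture(rng, n_peaks=100, n_regions=30)
        base = self.full_potentials(peaks, windows)
        target = windows.iloc[0]
        extra = make_peaks([(target["chrom"], target["tss"], target["tss"], "extra")])
        more = self.full_potentials(
            pd.concat([peaks, extra], ignore_index=True), windows
        )
        assert (
            more.loc[more["region_id"] == target["region_id"], "potential"].iloc[0]
            > base.loc[base["region_id"] == target["region_id"], "potential"].iloc[0]
        )
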