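import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rtprofiler as rt
from rtprofiler.dynamics import (
    call_extrema,
    dynamics_summary,
    inter_peak_distances,
    peak_slopes,
)


def profile_frame(rt_values, centers=None, chrom="chr1", segment_id=0):
    rt_values = np.asarray(rt_values, dtype=float)
    if centers is None:
        centers = np.arange(rt_values.size) * 10_000 + 5_000
    return pd.DataFrame(
        {"chrom": chrom, "center": np.asarray(centers), "rt": rt_values,
         "segment_id": segment_id}
    )


def extrema_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "position", "rt", "kind", "prominence", "segment_id"]
    )


class TestCallExtrema:
    def test_simple_peak(self):
        ext = call_extrema(profile_frame([0, 1, 0]))
        assert len(ext) == 1
        assert ext.loc[0, "kind"] == "peak"
        assert ext.loc[0, "position"] == 15_000
        assert ext.loc[0, "prominence"] == pytest.approx(1.0)

    def test_monotone_has_no_extrema(self):
        assert len(call_extrema(profile_frame([0, 1, 2, 3, 4]))) == 0

    def test_plateau_collapses_to_midpoint(self):
        ext = call_extrema(profile_frame([0, 1, 1, 1, 0]))
        assert len(ext) == 1
        assert ext.loc[0, "position"] == 25_000  # middle bin of the plateau

    def test_alternation_after_prominence_filter(self):
        # two peaks with a shallow valley between them: filtering the
        # valley forces one peak to be discarded
        ext = call_extrema(
            profile_frame([0, 2, 1.9, 2.5, 0]), min_prominence=0.5
        )
        kinds = ext["kind"].tolist()
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        assert kinds.count("peak") == 1

    def test_segments_isolated(self):
        prof = pd.concat(
            [profile_frame([0, 1, 0], segment_id=0),
             profile_frame([0, -1, 0], centers=[500_000, 510_000, 520_000], segment_id=1)],
            ignore_index=True,
        )
        ext = call_extrema(prof)
        assert ext["kind"].tolist() == ["peak", "valley"]

    def test_empty_output_allowed(self):
        assert len(call_extrema(profile_frame([1.0, 1.0]))) == 0

    @given(
        st.lists(
            st.floats(min_value=-5, max_value=5, allow_nan=False),
            min_size=3, max_size=60,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_alternation_invariant(self, values):
        ext = call_extrema(profile_frame(values))
        kinds = ext["kind"].tolist()
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        assert (ext["prominence"] >= 0).all()

    def test_origin_recovery_on_simulation(self, recovery_runs):
        for run in recovery_runs[:3]:
            profile = run["profile"]
            ext = call_extrema(profile)
            peaks = ext.loc[ext["kind"] == "peak", "position"].to_numpy()
            origins = np.array([p for p, _ in run["landscape"].origins])
            gaps = np.diff(origins)
            clear = np.ones(origins.size, dtype=bool)
            clear[1:] &= gaps >= 1_000_000
            clear[:-1] &= gaps >= 1_000_000
            bin_width = np.median(np.diff(profile["center"]))
            hits = [
                np.min(np.abs(peaks - o)) <= 2 * bin_width for o in origins[clear]
            ]
            assert np.mean(hits) >= 0.90


class TestInterPeakDistances:
    def test_simple_subtraction(self):
        ext = extrema_frame([
            ("chr1", 1_000_000, 1.0, "peak", 1.0, 0),
            ("chr1", 1_300_000, -1.0, "valley", 1.0, 0),
            ("chr1", 1_650_000, 1.0, "peak", 1.0, 0),
        ])
        d = inter_peak_distances(ext)
        assert d["distance"].tolist() == [650_000]

    def test_single_peak_contributes_nothing(self):
        ext = extrema_frame([("chr1", 1_000_000, 1.0, "peak", 1.0, 0)])
        assert len(inter_peak_distances(ext)) == 0

    def test_region_attribution_both_inside(self):
        ext = extrema_frame([
            ("chr1", 1_000_000, 1.0, "peak", 1.0, 0),
            ("chr1", 2_000_000, 1.0, "peak", 1.0, 0),
            ("chr1", 3_500_000, 1.0, "peak", 1.0, 0),
        ])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [1_500_000], "end": [4_000_000]})
        d = inter_peak_distances(ext, regions=regions)
        assert d.loc[d["in_region"], "distance"].tolist() == [1_500_000]

    def test_segments_break_pairs(self):
        ext = extrema_frame([
            ("chr1", 1_000_000, 1.0, "peak", 1.0, 0),
            ("chr1", 9_000_000, 1.0, "peak", 1.0, 1),
        ])
        assert len(inter_peak_distances(ext)) == 0


class TestPeakSlopes:
    def test_asymmetric_triple(self):
        ext = extrema_frame([
            ("chr1", 1_000_000, -1.0, "valley", 1.0, 0),
            ("chr1", 1_500_000, 0.0, "peak", 1.0, 0),
            ("chr1", 2_500_000, -1.0, "valley", 1.0, 0),
        ])
        s = peak_slopes(profile_frame([0]), ext)
        # ascending 1/0.5 = 2.0 per Mb, descending 1/1.0 = 1.0 per Mb
        assert s["slope"].tolist() == [pytest.approx(1.5)]

    def test_symmetric_tent(self):
        ext = extrema_frame([
            ("chr1", 1_000_000, -1.0, "valley", 1.0, 0),
            ("chr1", 2_000_000, 1.0, "peak", 1.0, 0),
            ("chr1", 3_000_000, -1.0, "valley", 1.0, 0),
        ])
        s = peak_slopes(profile_frame([0]), ext)
        assert s["slope"].tolist() == [pytest.approx(2.0)]

    def test_edge_peak_uses_single_side(self):
        ext = extrema_frame([
            ("chr1", 1_000_000, 1.0, "peak", 1.0, 0),
            ("chr1", 2_000_000, -1.0, "valley", 1.0, 0),
        ])
        s = peak_slopes(profile_frame([0]), ext)
        assert s["slope"].tolist() == [pytest.approx(2.0)]

    def test_flat_profile_no_slopes(self):
        s = peak_slopes(profile_frame([0]), extrema_frame([]))
        assert len(s) == 0

    def test_slopes_nonnegative(self, recovery_runs):
        prof = recovery_runs[0]["profile"]
        ext = call_extrema(prof)
        s = peak_slopes(prof, ext)
        assert (s["slope"] >= 0).all()


class TestScalingCovariance:
    def test_doubling_positions(self):
        ext = extrema_frame([
            ("chr1", 1_000_000, -1.0, "valley", 1.0, 0),
            ("chr1", 1_500_000, 0.0, "peak", 1.0, 0),
            ("chr1", 2_500_000, -1.0, "valley", 1.0, 0),
            ("chr1", 3_000_000, 0.5, "peak", 1.0, 0),
        ])
        doubled = ext.copy()
        doubled["position"] = ext["position"] * 2
        d1 = inter_peak_distances(ext)["distance"].to_numpy()
        d2 = inter_peak_distances(doubled)["distance"].to_numpy()
        np.testing.assert_array_equal(d2, 2 * d1)
        s1 = peak_slopes(profile_frame([0]), ext)["slope"].to_numpy()
        s2 = peak_slopes(profile_frame([0]), doubled)["slope"].to_numpy()
        np.testing.assert_allclose(s2, s1 / 2)


def test_median_inter_peak_distance_tracks_origin_spacing(recovery_runs):
    for run in recovery_runs[:3]:
        ext = call_extrema(run["profile"])
        d = inter_peak_distances(ext)["distance"].to_numpy()
        origins = np.array([p for p, _ in run["landscape"].origins])
        true_median = np.median(np.diff(origins))
        assert abs(np.median(d) - true_median) / true_median < 0.15


def test_dynamics_summary_keys(recovery_runs):
    prof = recovery_runs[0]["profile"]
    regions = pd.DataFrame(
        {"chrom": ["chr1"], "start": [40_000_000], "end": [60_000_000]}
    )
    summary = dynamics_summary(prof, regions=regions)
    assert summary["n_peaks"] > 0
    assert summary["median_inter_peak_mb"] > 0
    assert summary["median_slope_per_mb"] > 0
    assert "median_inter_peak_mb_in_region" in summary
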