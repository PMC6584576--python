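"""Tests for the windowed differential-coverage scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uvlinker.coverage import (
    CoverageTrack,
    add_ratios,
    combine_windows,
    estimate_scale,
    flag_windows,
    log2_ratio,
    merge_regions,
    read_regions_bed,
    summarize_regions,
    window_coverage,
    write_regions_bed,
)
from uvlinker.errors import InputError, NormalizationError


def _track(**segs):
    return CoverageTrack.from_arrays(
        {k: np.asarray(v, dtype=float) for k, v in segs.items()})


def _windows(cov_a, cov_b, **extra):
    n = len(cov_a)
    df = pd.DataFrame({
        "seg": extra.get("seg", ["s"] * n),
        "start": np.arange(n) * 500,
        "end": (np.arange(n) + 1) * 500,
        "width": 500,
        "partial": extra.get("partial", [False] * n),
        "cov_a": cov_a,
        "cov_b": cov_b,
    })
    return df


class TestWindows:
    def test_uniform_depth_tiles_exactly(self):
        track = _track(s=[10.0] * 1500)
        w = window_coverage(track, width=500)
        assert len(w) == 3
        assert (w["cov"] == 10.0).all()
        assert not w["partial"].any()

    def test_partial_first_window_mean(self):
        depth = np.zeros(1000)
        depth[:250] = 10.0
        w = window_coverage(_track(s=depth), width=500)
        assert w.iloc[0]["cov"] == pytest.approx(5.0)

    def test_terminal_partial_window(self):
        w = window_coverage(_track(s=np.ones(1234)), width=500)
        assert list(w["start"]) == [0, 500, 1000]
        assert list(w["end"]) == [500, 1000, 1234]
        assert list(w["partial"]) == [False, False, True]

    def test_tiling_conserves_segment_length(self, small_reference,
                                             small_reads):
        male, _ = small_reads
        track = CoverageTrack.from_arrays(
            male.truth_coverage(small_reference.segment_lengths))
        w = window_coverage(track, width=500)
        for seg, length in small_reference.segment_lengths.items():
            assert w[w["seg"] == seg]["width"].sum() == length

    def test_width_validation(self):
        with pytest.raises(ValueError):
            window_coverage(_track(s=np.ones(10)), width=0)

    def test_bedgraph_round_trip(self, tmp_path):
        depth = np.concatenate([np.full(300, 7.0), np.full(200, 2.0)])
        track = _track(s=depth)
        track.write_bedgraph(tmp_path / "t.bg")
        back = CoverageTrack.from_bedgraph(tmp_path / "t.bg", {"s": 500})
        np.testing.assert_array_equal(back.depth["s"], depth)


class TestScale:
    def test_doubled_library(self):
        w = _windows([20, 40, 60], [10, 20, 30])
        assert estimate_scale(w) == pytest.approx(2.0)
        ratios = add_ratios(w)["log2_ratio"]
        assert np.allclose(ratios, 0.0, atol=0.01)

    def test_equal_libraries(self):
        w = _windows([10, 20], [10, 20])
        assert estimate_scale(w) == pytest.approx(1.0)

    def test_no_eligible_window_rejected(self):
        w = _windows([5, 0], [0, 5])
        with pytest.raises(NormalizationError):
            estimate_scale(w)

    def test_downsampled_library_recovered(self, small_reference):
        """Male library at half depth: scale near 0.5."""
        from uvlinker.simulate import simulate_reads
        male = simulate_reads(small_reference, "male", depth=10.0, seed=21)
        female = simulate_reads(small_reference, "female", depth=20.0, seed=22)
        lengths = small_reference.segment_lengths
        wa = window_coverage(
            CoverageTrack.from_arrays(male.truth_coverage(lengths)))
        wb = window_coverage(
            CoverageTrack.from_arrays(female.truth_coverage(lengths)))
        scale = estimate_scale(combine_windows(wa, wb), baseline={"chr1"})
        assert 0.45 <= scale <= 0.55


class TestLog2Ratio:
    def test_sixteen_fold(self):
        assert log2_ratio(32, 2, 1.0, 1e-9) == pytest.approx(4.0, abs=1e-6)

    def test_balanced_zero(self):
        assert log2_ratio(20, 20, 1.0) == 0.0

    def test_zero_coverage_pseudocount(self):
        assert log2_ratio(20, 0, 1.0, 0.1) == pytest.approx(
            np.log2(20.1 / 0.1))

    @given(st.floats(0, 1000), st.floats(0, 1000),
           st.floats(0.01, 100), st.floats(1e-3, 1))
    @settings(deadline=None)
    def test_antisymmetry_exact(self, a, b, scale, p):
        forward = log2_ratio(a, b, scale, p)
        backward = log2_ratio(b, a, 1.0 / scale, p)
        assert forward == pytest.approx(-backward, abs=1e-12)

    def test_pseudocount_validation(self):
        with pytest.raises(ValueError):
            log2_ratio(1, 1, 1.0, 0.0)


class TestFlags:
    def test_balanced_window_not_flagged(self):
        w = add_ratios(_windows([20], [20]), scale=1.0)
        out = flag_windows(w)
        assert out.iloc[0]["call"] == "balanced"
        assert not out.iloc[0]["flag"]

    def test_a_specific_call(self):
        w = add_ratios(_windows([20, 20], [0, 20]), scale=1.0)
        out = flag_windows(w)
        assert out.iloc[0]["call"] == "a_specific"

    def test_enriched_when_depleted_sample_still_covered(self):
        w = add_ratios(_windows([200, 10], [3, 10]), scale=1.0)
        out = flag_windows(w)
        assert out.iloc[0]["flag"]
        assert out.iloc[0]["call"] == "a_enriched"

    def test_partial_windows_never_flagged(self):
        w = add_ratios(_windows([200, 10], [0, 10],
                                partial=[True, False]), scale=1.0)
        out = flag_windows(w)
        assert not out.iloc[0]["flag"]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        cov_a = rng.poisson(20, 200).astype(float)
        cov_b = cov_a.copy()
        cov_b[:50] = rng.poisson(1, 50)
        w = add_ratios(_windows(cov_a, cov_b), scale=1.0)
        counts = [flag_windows(w, enrich_threshold=t)["flag"].sum()
                  for t in (1, 2, 4, 6)]
        assert counts == sorted(counts, reverse=True)


class TestRegions:
    def _flagged(self, calls, seg="s"):
        n = len(calls)
        df = _windows([1] * n, [1] * n, seg=[seg] * n)
        df["scale"] = 1.0
        df["log2_ratio"] = [5.0 if c != "balanced" else 0.0 for c in calls]
        df["flag"] = [c != "balanced" for c in calls]
        df["call"] = calls
        return df

    def test_adjacent_same_call_merge(self):
        regions = merge_regions(self._flagged(["a_specific"] * 3))
        assert len(regions) == 1
        assert regions.iloc[0]["n_windows"] == 3

    def test_gap_splits_regions(self):
        regions = merge_regions(
            self._flagged(["a_specific", "balanced", "a_specific"]))
        assert len(regions) == 2

    def test_gap_bridged_with_max_gap(self):
        regions = merge_regions(
            self._flagged(["a_specific", "balanced", "a_specific"]),
            max_gap=1)
        assert len(regions) == 1

    def test_different_calls_never_merge(self):
        regions = merge_regions(
            self._flagged(["a_specific", "b_specific"]))
        assert len(regions) == 2

    def test_unsorted_input_rejected(self):
        df = self._flagged(["a_specific", "a_specific"])
        df = df.iloc[::-1]
        with pytest.raises(InputError):
            merge_regions(df)

    def test_summary_arithmetic(self):
        regions = merge_regions(self._flagged(
            ["a_specific"] * 3 + ["balanced"] + ["b_specific"]))
        s = summarize_regions(regions)
        assert s.n_regions == 2
        assert s.total_bp == 2000

    def test_empty_summary(self):
        s = summarize_regions(merge_regions(self._flagged(["balanced"])))
        assert (s.n_regions, s.total_bp) == (0, 0)

    def test_bed_round_trip(self, tmp_path):
        regions = merge_regions(
            self._flagged(["a_specific", "a_specific", "b_specific"]))
        write_regions_bed(regions, tmp_path / "r.bed")
        back = read_regions_bed(tmp_path / "r.bed")
        assert list(back["call"]) == ["a_specific", "b_specific"]
        assert list(back["start"]) == [0, 1000]
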