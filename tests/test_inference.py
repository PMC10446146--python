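"""Masking, block averaging and derivative-based emission estimation."""

import numpy as np
import pytest

from nanorelease.inference import (
    ConcentrationSeries,
    DerivativeStats,
    EmptySeriesError,
    ExclusionIntervals,
    block_average,
    derivative_stats,
    emission_bound,
    mask_series,
)


def make_series(t, v, **kw):
    return ConcentrationSeries(timestamps_s=np.asarray(t, float), values=np.asarray(v, float), **kw)


class TestSeriesValidation:
    def test_rejects_non_monotone_time(self):
        with pytest.raises(ValueError):
            make_series([0.0, 2.0, 1.0], [1, 1, 1])

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError):
            make_series([0.0, 1.0], [1.0, -0.1])

    def test_rejects_empty(self):
        with pytest.raises(EmptySeriesError):
            make_series([], [])


class TestMaskSeries:
    def test_empty_exclusions_identity(self):
        s = make_series(np.arange(10.0), np.ones(10))
        masked = mask_series(s, ExclusionIntervals())
        assert masked is s

    def test_interval_removal_and_gap_recording(self):
        s = make_series(np.arange(100.0), np.ones(100))
        masked = mask_series(s, ExclusionIntervals(((40.0, 61.0),)))  # samples 40..60
        assert len(masked) == 79
        assert masked.segments.max() == 1  # exactly one recorded gap
        assert np.all(np.diff(masked.segments) >= 0)

    def test_overlapping_intervals_merge(self):
        excl = ExclusionIntervals(((10.0, 20.0), (15.0, 30.0), (30.0, 35.0)))
        assert excl.intervals == ((10.0, 35.0),)

    def test_masking_everything_errors(self):
        s = make_series(np.arange(10.0), np.ones(10))
        with pytest.raises(EmptySeriesError):
            mask_series(s, ExclusionIntervals(((-1.0, 11.0),)))

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            ExclusionIntervals(((5.0, 5.0),))


class TestBlockAverage:
    def test_constant_series_unchanged_values(self):
        s = make_series(np.arange(3600.0), np.full(3600, 7.5))
        avg = block_average(s, 900.0)
        assert len(avg) == 4
        assert np.allclose(avg.values, 7.5)
        assert avg.window_s == 900.0

    def test_fifteen_minute_blocks_on_1hz_data(self):
        s = make_series(np.arange(1800.0), np.arange(1800.0))
        avg = block_average(s, 900.0)
        # each output point averages 900 samples: mean of 0..899 and 900..1799
        assert np.allclose(avg.values, [449.5, 1349.5])

    def test_linear_ramp_points_lie_on_ramp(self):
        a, b = 3.0, 0.004
        t = np.arange(0.0, 7200.0, 2.0)
        s = make_series(t, a + b * t)
        avg = block_average(s, 900.0)
        assert np.allclose(avg.values, a + b * avg.timestamps_s, rtol=1e-12)

    def test_blocks_spanning_gap_dropped(self):
        s = make_series(np.arange(3600.0), np.ones(3600))
        masked = mask_series(s, ExclusionIntervals(((1000.0, 1100.0),)))
        avg = block_average(masked, 900.0)
        # the block containing the gap straddles two segments and is dropped
        assert len(avg) < 4
        assert avg.segments.max() >= 1

    def test_window_shorter_than_sampling_rejected(self):
        s = make_series(np.arange(0.0, 100.0, 10.0), np.ones(10))
        with pytest.raises(ValueError):
            block_average(s, 15.0)

    def test_mask_then_average_matches_average_with_windows_dropped(self):
        # exclusion aligned with block boundaries: orders must agree exactly
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 9000.0)
        s = make_series(t, rng.uniform(1.0, 2.0, t.size))
        excl = ExclusionIntervals(((1800.0, 2700.0),))
        a = block_average(mask_series(s, excl), 900.0)
        full = block_average(s, 900.0)
        keep = (full.timestamps_s < 1800.0) | (full.timestamps_s >= 2700.0)
        assert np.allclose(a.timestamps_s, full.timestamps_s[keep])
        assert np.allclose(a.values, full.values[keep])


class TestDerivativeStats:
    def test_constant_series_zero_mean_zero_sd(self):
        s = make_series(np.arange(10.0), np.full(10, 3.3))
        st = derivative_stats(s)
        assert st.mean == 0.0 and st.sd == 0.0
        assert st.n_windows == 9

    def test_noiseless_line_recovers_slope_exactly(self):
        slope = 0.02
        t = np.arange(0.0, 900.0, 10.0)
        st = derivative_stats(make_series(t, 1.0 + slope * t))
        assert st.mean == pytest.approx(slope, rel=1e-10)
        assert st.sd == pytest.approx(0.0, abs=1e-12)

    def test_never_differentiates_across_gap(self):
        t = np.arange(100.0)
        v = np.where(t < 50, 1.0, 100.0)  # huge step hidden inside the gap
        s = make_series(t, v)
        masked = mask_series(s, ExclusionIntervals(((49.0, 51.0),)))
        st = derivative_stats(masked)
        assert st.mean == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            derivative_stats(make_series([0.0, 1.0], [1.0, 1.0]))


class TestEmissionBound:
    def test_chamber_upper_range_from_derivative_stats(self):
        # mean 1e-4, sd 0.02 1/(cm3 s) in a 220 L chamber -> 4422 -> 4400 at 2 sf
        st = DerivativeStats(mean=1e-4, sd=0.02, n_windows=288, window_length_s=900.0)
        bound = emission_bound(st, 0.22, k_sigma=1.0)
        assert bound.upper == pytest.approx(4422.0, rel=1e-12)
        assert bound.point == pytest.approx(22.0, rel=1e-12)
        assert bound.unit == "1/s"

    def test_zero_sd_upper_equals_point(self):
        st = DerivativeStats(mean=1e-3, sd=0.0, n_windows=10, window_length_s=None)
        bound = emission_bound(st, 1.0)
        assert bound.upper == bound.point

    def test_net_loss_upper_floored_at_zero(self):
        st = DerivativeStats(mean=-0.01, sd=0.005, n_windows=10, window_length_s=None)
        assert emission_bound(st, 5.0).upper == 0.0

    def test_mass_metric_uses_m3_volume(self):
        st = DerivativeStats(mean=2.0, sd=0.0, n_windows=5, window_length_s=None, metric="mass")
        bound = emission_bound(st, 20.0)
        assert bound.point == pytest.approx(40.0)  # ng/s
        assert bound.unit == "ng/s"
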