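"""2 Hz resampling, moving-polynomial detrending, Kaiser band-pass, epochs."""
import numpy as np
import pytest

import pulsecam as pc
from pulsecam import hrv
from pulsecam.cpvd import IbiSeries
from pulsecam.hrv import Hp2HzSeries, SegmentLog
from pulsecam.series import UniformSeries


def ibi_from_intervals(intervals_ms, t0=0.0):
    beats = t0 + np.concatenate([[0.0], np.cumsum(intervals_ms) / 1000.0])
    return IbiSeries(beat_times=beats, ibis=np.asarray(intervals_ms, float))


class TestSegmentation:
    def test_uniform_series_sliced_at_boundaries(self):
        s = UniformSeries(values=np.arange(120000, dtype=float), fs=1000.0)
        log = SegmentLog([("task", 10.0, 40.0)])
        seg = hrv.segment_by_tasks(s, log)["task"]
        assert seg.duration == pytest.approx(30.0)
        assert seg.t0 == pytest.approx(10.0)

    def test_adjacent_segments_partition_their_union(self):
        s = UniformSeries(values=np.arange(10000, dtype=float), fs=1000.0)
        log = SegmentLog([("a", 1.0, 4.0), ("b", 4.001, 8.0)])
        parts = hrv.segment_by_tasks(s, log)
        total = len(parts["a"]) + len(parts["b"])
        full = int(7.0 * 1000) + 2
        assert abs(total - full) <= 2

    def test_segment_beyond_span_rejected(self):
        s = UniformSeries(values=np.zeros(1000), fs=1000.0)
        with pytest.raises(ValueError, match="outside"):
            hrv.segment_by_tasks(s, SegmentLog([("x", 0.0, 5.0)]))

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SegmentLog([("a", 0.0, 5.0), ("b", 4.0, 8.0)])


class TestResample2Hz:
    def test_constant_ibis_give_constant_series(self):
        h = hrv.resample_2hz(ibi_from_intervals([800.0] * 100))
        assert np.allclose(h.values, 800.0)

    def test_alternating_ibis_time_weighted_mean(self):
        # 700/900 alternating: long beats cover more time, mean = 812.5 ms
        h = hrv.resample_2hz(ibi_from_intervals([700.0, 900.0] * 150))
        expected = (700.0 * 0.7 + 900.0 * 0.9) / 1.6
        assert hrv.heart_period(h) == pytest.approx(expected, abs=0.5)

    def test_single_interval_fills_two_bins(self):
        h = hrv.resample_2hz(ibi_from_intervals([1000.0]))
        assert len(h) == 2
        assert np.allclose(h.values, 1000.0)

    def test_artifact_interval_leaves_missing_bins(self):
        intervals = [800.0] * 20 + [3500.0] + [800.0] * 20
        ibi = ibi_from_intervals(intervals)
        assert ibi.artifact.sum() == 1
        h = hrv.resample_2hz(ibi)
        assert np.isnan(h.values).sum() >= 5  # the 3.5 s gap is not invented

    def test_hp_invariance_to_time_weighted_mean(self, modulated_truth):
        ibi = IbiSeries(beat_times=modulated_truth.beat_times,
                        ibis=modulated_truth.true_ibis)
        h = hrv.resample_2hz(ibi)
        w = np.diff(ibi.beat_times)
        tw_mean = float(np.sum(ibi.ibis * w) / np.sum(w))
        assert hrv.heart_period(h) == pytest.approx(tw_mean, abs=0.5)


class TestMovingPolynomialFilter:
    @pytest.mark.parametrize("points", [21, 51])
    @pytest.mark.parametrize("degree", [0, 1, 2, 3])
    def test_polynomial_reproduction(self, points, degree):
        # any global polynomial of degree <= 3 leaves zero interior residual
        t = np.arange(300) / 2.0
        coeffs = [1.5, -0.02, 3e-4, -1e-6][: degree + 1]
        values = 800.0 + sum(c * t**k for k, c in enumerate(coeffs))
        h = Hp2HzSeries(values=values)
        _, resid = hrv.moving_polynomial_filter(h, order=3, points=points)
        assert np.max(np.abs(resid.values)) < 1e-9

    def test_residual_gain_matches_frequency_response_oracle(self):
        # cubic trend + 0.3 Hz sine: interior residual amplitude equals the
        # empirical 1 - (trend gain at 0.3 Hz), measured on the sine alone
        t = np.arange(600) / 2.0
        sine = np.sin(2 * np.pi * 0.3 * t)
        h_sine = Hp2HzSeries(values=800.0 + 30.0 * sine)
        _, resid_sine = hrv.moving_polynomial_filter(h_sine, points=21)
        oracle_amp = np.max(np.abs(resid_sine.values[40:-40]))

        cubic = 750.0 + 0.8 * t - 4e-3 * t**2 + 6e-6 * t**3
        h_both = Hp2HzSeries(values=cubic + 30.0 * sine)
        _, resid_both = hrv.moving_polynomial_filter(h_both, points=21)
        got = np.max(np.abs(resid_both.values[40:-40]))
        assert got == pytest.approx(oracle_amp, rel=1e-6)

    def test_edges_trimmed(self):
        h = Hp2HzSeries(values=np.full(100, 800.0))
        trend, resid = hrv.moving_polynomial_filter(h, points=21)
        assert len(trend) == 100 - 20
        assert trend.t0 == pytest.approx(h.t0 + 10 / 2.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            hrv.moving_polynomial_filter(Hp2HzSeries(values=np.full(20, 800.0)), points=21)


class TestKaiserBandpass:
    def test_passband_and_stopband_gains(self):
        t = np.arange(1200) / 2.0  # 600 s, long enough to ignore edges
        for f, band, expect_pass in [
            (0.25, hrv.RSA_BAND, True),
            (0.05, hrv.RSA_BAND, False),
            (0.07, hrv.LF_BAND, True),
            (0.25, hrv.LF_BAND, False),
        ]:
            s = UniformSeries(values=np.sin(2 * np.pi * f * t), fs=2.0)
            out = hrv.kaiser_bandpass(s, band)
            amp = np.max(np.abs(out.values[200:-200]))
            if expect_pass:
                assert amp >= 0.95, (f, band)
            else:
                assert amp <= 0.05, (f, band)

    def test_zeros_map_to_zeros(self):
        out = hrv.kaiser_bandpass(UniformSeries(values=np.zeros(600), fs=2.0))
        assert np.allclose(out.values, 0.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="tap"):
            hrv.kaiser_bandpass(UniformSeries(values=np.zeros(100), fs=2.0))


class TestEpochLnVariance:
    def test_full_cycle_sine_epoch_variance(self):
        # 0.25 Hz, amplitude 50 ms, 30 s epochs hold full cycles: var = A^2/2
        t = np.arange(120) / 2.0
        s = UniformSeries(values=50.0 * np.sin(2 * np.pi * 0.25 * t), fs=2.0)
        epoch_values, mean = hrv.epoch_ln_variance(s)
        assert len(epoch_values) == 2
        assert mean == pytest.approx(np.log(1250.0), abs=0.02)

    def test_amplitude_doubling_adds_ln4(self):
        t = np.arange(120) / 2.0
        a = UniformSeries(values=50.0 * np.sin(2 * np.pi * 0.25 * t), fs=2.0)
        b = UniformSeries(values=100.0 * np.sin(2 * np.pi * 0.25 * t), fs=2.0)
        _, ma = hrv.epoch_ln_variance(a)
        _, mb = hrv.epoch_ln_variance(b)
        assert mb - ma == pytest.approx(np.log(4.0), abs=1e-9)

    def test_partial_trailing_epoch_discarded(self):
        rng = np.random.default_rng(0)
        s = UniformSeries(values=rng.normal(0, 10, 150), fs=2.0)  # 75 s
        epoch_values, _ = hrv.epoch_ln_variance(s)
        assert len(epoch_values) == 2

    def test_zero_variance_epoch_rejected(self):
        with pytest.raises(ValueError, match="[Zz]ero variance"):
            hrv.epoch_ln_variance(UniformSeries(values=np.zeros(60) + 5.0, fs=2.0))


def pipeline_gain(band_estimate, freq, base_hp=800.0, amp=50.0):
    """Full-chain gain correction, measured on a noise-free generated IBI
    series with a single sinusoidal modulation at a reference amplitude."""
    kw = dict(beat_noise_sd=0.0, duration=300.0, transit_jitter_sd=0.0, seed=0,
              base_hp=base_hp)
    if band_estimate is hrv.rsa_estimate:
        cfg = pc.SynthConfig(rsa_amp=amp, rsa_freq=freq, lf_amp=0.0, **kw)
    else:
        cfg = pc.SynthConfig(lf_amp=amp, lf_freq=freq, rsa_amp=0.0, **kw)
    truth = pc.generate_ibi_series(cfg)
    h = hrv.resample_2hz(IbiSeries(beat_times=truth.beat_times, ibis=truth.true_ibis))
    _, est = band_estimate(h)
    return est - np.log(amp**2 / 2.0)


class TestBandEstimates:
    def test_rsa_parameter_recovery_and_monotonicity(self):
        gain = pipeline_gain(hrv.rsa_estimate, 0.25)
        recovered = []
        for amp in (20.0, 40.0, 80.0):
            cfg = pc.SynthConfig(rsa_amp=amp, lf_amp=0.0, beat_noise_sd=2.0,
                                 duration=300.0, seed=4)
            truth = pc.generate_ibi_series(cfg)
            h = hrv.resample_2hz(IbiSeries(beat_times=truth.beat_times,
                                           ibis=truth.true_ibis))
            _, rsa = hrv.rsa_estimate(h)
            assert rsa == pytest.approx(np.log(amp**2 / 2.0) + gain, abs=0.2)
            recovered.append(rsa)
        assert recovered[0] < recovered[1] < recovered[2]

    def test_band_separation_both_directions(self):
        # pure respiratory modulation: RSA >> LF; pure vasomotor: reversed
        for rsa_amp, lf_amp in ((40.0, 0.0), (0.0, 40.0)):
            cfg = pc.SynthConfig(rsa_amp=rsa_amp, lf_amp=lf_amp, beat_noise_sd=2.0,
                                 duration=300.0, seed=5)
            truth = pc.generate_ibi_series(cfg)
            h = hrv.resample_2hz(IbiSeries(beat_times=truth.beat_times,
                                           ibis=truth.true_ibis))
            _, rsa = hrv.rsa_estimate(h)
            _, lf = hrv.lf_estimate(h)
            if rsa_amp > 0:
                assert rsa - lf > 2.0
            else:
                assert lf - rsa > 2.0

    def test_doubling_amplitude_raises_estimate_by_ln4(self):
        vals = []
        for amp in (30.0, 60.0):
            cfg = pc.SynthConfig(rsa_amp=amp, lf_amp=0.0, beat_noise_sd=0.0,
                                 duration=300.0, seed=6)
            truth = pc.generate_ibi_series(cfg)
            h = hrv.resample_2hz(IbiSeries(beat_times=truth.beat_times,
                                           ibis=truth.true_ibis))
            vals.append(hrv.rsa_estimate(h)[1])
        assert vals[1] - vals[0] == pytest.approx(np.log(4.0), abs=0.1)

    def test_unavailable_when_too_many_bins_missing(self):
        intervals = [800.0] * 200 + [3500.0] * 30 + [800.0] * 200
        h = hrv.resample_2hz(ibi_from_intervals(intervals))
        assert h.missing_frac > 0.1
        with pytest.raises(ValueError, match="missing"):
            hrv.rsa_estimate(h)


class TestWindowAverage:
    def test_constant_ibis_every_window_800(self):
        w = hrv.window_average(ibi_from_intervals([800.0] * 100), 2.0)
        assert np.allclose(w.values[np.isfinite(w.values)], 800.0)

    def test_grand_mean_preserved(self):
        ibi = ibi_from_intervals([800.0] * 75)  # exactly 60 s: windows align
        w = hrv.window_average(ibi, 5.0)
        assert np.nanmean(w.values) == pytest.approx(800.0, abs=1.0)

    def test_window_averaging_reduces_dispersion(self):
        rng = np.random.default_rng(7)
        intervals = 800.0 + rng.normal(0, 30.0, 400)
        ibi = ibi_from_intervals(intervals)
        w = hrv.window_average(ibi, 5.0)
        finite = w.values[np.isfinite(w.values)]
        assert np.std(finite) < np.std(intervals)


class TestHrvSummary:
    def test_per_segment_estimates(self, modulated_truth):
        ibi = IbiSeries(beat_times=modulated_truth.beat_times,
                        ibis=modulated_truth.true_ibis)
        log = SegmentLog([("baseline", 0.0, 150.0), ("task", 150.0, 295.0)])
        ests = hrv.hrv_summary(ibi, log)
        assert [e.segment_label for e in ests] == ["baseline", "task"]
        for e in ests:
            assert 700.0 < e.hp < 900.0
            assert np.isfinite(e.rsa) and np.isfinite(e.lf)
            assert np.mean(e.rsa_epoch_values) == pytest.approx(e.rsa)

    def test_short_segment_reports_unavailable_not_crash(self, modulated_truth):
        ibi = IbiSeries(beat_times=modulated_truth.beat_times,
                        ibis=modulated_truth.true_ibis)
        log = SegmentLog([("short", 0.0, 40.0)])
        est = hrv.hrv_summary(ibi, log)[0]
        assert np.isfinite(est.hp)
        assert np.isnan(est.rsa) and "unavailable" in est.note
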