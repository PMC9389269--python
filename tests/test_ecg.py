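"""ECG preprocessing: filters, R-peak detection, relocation, rendering."""

import numpy as np
import pytest

from stressfuse import ecg
from stressfuse.errors import (
    ContextTooShort,
    DegenerateInput,
    EmptyResult,
    InvalidConfiguration,
    PeriodNotFound,
)

FS = 2000


def sine_record(freq: float, seconds: float = 2.0, fs: float = FS) -> ecg.ECGRecord:
    t = np.arange(int(seconds * fs)) / fs
    return ecg.ECGRecord(np.sin(2 * np.pi * freq * t), fs)


def fft_amplitude(x: np.ndarray, freq: float, fs: float) -> float:
    spectrum = np.abs(np.fft.rfft(x))
    k = int(round(freq * x.size / fs))
    return spectrum[k]


class TestFilters:
    def test_notch_kills_mains_and_keeps_passband(self):
        hum = sine_record(50.0, seconds=6.0)
        out = ecg.apply_notch(hum)
        assert np.sqrt(np.mean(out.samples**2)) <= 0.1 * np.sqrt(np.mean(hum.samples**2))
        ten = sine_record(10.0)
        out10 = ecg.apply_notch(ten)
        rms_ratio = np.sqrt(np.mean(out10.samples**2) / np.mean(ten.samples**2))
        assert abs(rms_ratio - 1) < 0.05

    def test_notch_fft_oracle(self):
        hum = sine_record(50.0)
        out = ecg.apply_notch(hum)
        assert fft_amplitude(out.samples, 50.0, FS) <= 0.05 * fft_amplitude(
            hum.samples, 50.0, FS
        )

    def test_bandpass_attenuates_out_of_band(self):
        # the 0.5 Hz corner rings for seconds at the clip edges, so the
        # comparison uses the steady-state middle section
        mid_slice = slice(2 * FS, 4 * FS)
        hi = sine_record(100.0, seconds=6.0)
        out = ecg.apply_bandpass(hi)
        rms = lambda x: np.sqrt(np.mean(x[mid_slice] ** 2))  # noqa: E731
        assert rms(out.samples) <= 0.1 * rms(hi.samples)
        mid = sine_record(10.0, seconds=6.0)
        outm = ecg.apply_bandpass(mid)
        assert abs(rms(outm.samples) / rms(mid.samples) - 1) < 0.1

    def test_zero_input_stays_zero(self):
        zero = ecg.ECGRecord(np.zeros(2 * FS), FS)
        assert np.allclose(ecg.apply_notch(zero).samples, 0.0)
        assert np.allclose(ecg.apply_bandpass(zero).samples, 0.0)

    def test_filters_are_linear_and_length_preserving(self, rng):
        x = ecg.ECGRecord(rng.normal(size=4 * FS), FS)
        y = ecg.ECGRecord(rng.normal(size=4 * FS), FS)
        a, b = 2.5, -1.3
        combo = ecg.ECGRecord(a * x.samples + b * y.samples, FS)
        for f in (ecg.apply_notch, ecg.apply_bandpass):
            lhs = f(combo).samples
            rhs = a * f(x).samples + b * f(y).samples
            assert lhs.size == x.samples.size
            assert np.allclose(lhs, rhs, atol=1e-9)

    def test_invalid_configurations_rejected(self):
        rec = sine_record(10.0)
        with pytest.raises(InvalidConfiguration):
            ecg.apply_notch(ecg.ECGRecord(rec.samples, fs=90.0), f0=50.0)
        with pytest.raises(InvalidConfiguration):
            ecg.apply_bandpass(rec, low=50.0, high=0.5)


class TestStandardize:
    def test_zero_mean_unit_sd_and_invariances(self):
        rec = ecg.ECGRecord(np.array([1.0, 2.0, 3.0] * 2000), FS)
        out = ecg.standardize(rec)
        assert abs(out.samples.mean()) < 1e-12
        assert abs(out.samples.std() - 1) < 1e-12
        scaled = ecg.standardize(ecg.ECGRecord(5 * rec.samples, FS))
        assert np.allclose(out.samples, scaled.samples)
        twice = ecg.standardize(out)
        assert np.allclose(out.samples, twice.samples)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInput):
            ecg.standardize(ecg.ECGRecord(np.ones(2 * FS), FS))


def gaussian_peaks(positions, n=6000, width=10.0):
    x = np.zeros(n)
    t = np.arange(n)
    for p in positions:
        x += np.exp(-0.5 * ((t - p) / width) ** 2)
    return x


class TestRPeaks:
    def test_clean_peaks_found_exactly(self):
        rec = ecg.ECGRecord(gaussian_peaks([1000, 2600, 4200]), FS)
        peaks = ecg.detect_r_peaks(rec, threshold_frac=0.5)
        assert peaks.indices.tolist() == [1000, 2600, 4200]

    def test_noisy_peaks_within_tolerance(self, rng):
        truth = [1000, 2600, 4200]
        x = gaussian_peaks(truth) + rng.normal(0, 0.05, 6000)
        peaks = ecg.detect_r_peaks(ecg.ECGRecord(x, FS), threshold_frac=0.5)
        assert len(peaks) == 3
        for p, tr in zip(peaks.indices, truth):
            # oracle: the local argmax around the known position
            window = x[tr - 50 : tr + 51]
            assert abs(p - (tr - 50 + np.argmax(window))) == 0
            assert abs(p - tr) <= 5

    def test_flat_signal_raises(self):
        with pytest.raises(EmptyResult):
            ecg.detect_r_peaks(ecg.ECGRecord(np.zeros(2 * FS), FS))

    def test_refractory_deduplication(self):
        # two bumps 100 samples apart: physiologically one beat
        rec = ecg.ECGRecord(gaussian_peaks([1000, 1100, 3000]), FS)
        peaks = ecg.detect_r_peaks(rec, threshold_frac=0.3)
        assert len(peaks) == 2


class TestAutocorr:
    def test_impulse_train_maxima_at_period_multiples(self):
        x = np.zeros(400)
        x[::40] = 1.0
        acf = ecg.short_time_autocorr(x, max_lag=200)
        # brute-force quadratic oracle
        brute = np.array([np.sum(x[: 400 - k] * x[k:]) for k in range(201)])
        brute = brute / brute[0]
        assert np.allclose(acf, brute, atol=1e-12)
        for lag in (40, 80, 120):
            assert acf[lag] > acf[lag - 5] and acf[lag] > acf[lag + 5]

    def test_white_noise_acf_small_off_zero(self, rng):
        x = rng.normal(size=4000)
        acf = ecg.short_time_autocorr(x, max_lag=100)
        assert acf[0] == pytest.approx(1.0)
        # each lag is a mean of ~n products, so |acf[k]| ~ 1/sqrt(n);
        # allow the rare 3-sigma excursion among the 100 lags
        violations = np.sum(np.abs(acf[1:]) >= 3 / np.sqrt(4000))
        assert violations <= 2

    def test_normalization_and_errors(self, rng):
        x = rng.normal(size=100)
        assert ecg.short_time_autocorr(x, 50)[0] == pytest.approx(1.0)
        with pytest.raises(InvalidConfiguration):
            ecg.short_time_autocorr(x, 100)


class TestClip:
    def test_printed_formula_example(self):
        out = ecg.clip_autocorr(np.array([0.5, 0.05, -0.3]), alpha=0.1, beta=-0.1)
        assert np.allclose(out, [0.4, 0.0, -0.2])

    def test_inside_band_is_zeroed(self, rng):
        x = rng.uniform(-0.1, 0.1, 100)
        assert np.all(ecg.clip_autocorr(x) == 0.0)

    def test_monotone(self, rng):
        x = rng.normal(size=200)
        y = x + np.abs(rng.normal(size=200))
        assert np.all(ecg.clip_autocorr(x) <= ecg.clip_autocorr(y))

    def test_matches_elementwise_oracle(self, rng):
        alpha, beta = 0.1, -0.1
        for _ in range(200):
            x = rng.normal(scale=0.3, size=50)
            expected = np.array(
                [
                    v - alpha if v > alpha else (v - beta if v < beta else 0.0)
                    for v in x
                ]
            )
            assert np.array_equal(ecg.clip_autocorr(x, alpha, beta), expected)

    def test_alpha_beta_order_enforced(self):
        with pytest.raises(InvalidConfiguration):
            ecg.clip_autocorr(np.zeros(3), alpha=-0.1, beta=0.1)


class TestPeriodEstimate:
    def test_single_peak(self):
        clipped = np.zeros(100)
        clipped[0] = 0.9
        clipped[40] = 0.5
        assert ecg.estimate_rr_interval(clipped) == 40

    def test_first_harmonic_not_double(self):
        # strictly periodic signal with max_lag >= 2P
        x = np.zeros(600)
        x[::100] = 1.0
        acf = ecg.short_time_autocorr(x, max_lag=250)
        clipped = ecg.clip_autocorr(acf)
        assert ecg.estimate_rr_interval(clipped) == 100

    def test_true_rr_recovered_from_synthetic_ecg(self):
        from stressfuse.synth import SynthConfig, gen_ecg

        cfg = SynthConfig(
            seed=5,
            hr_bpm={"calm": (75.0, 75.0), "control": (90.0, 90.0), "experimental": (100.0, 100.0)},
            rr_jitter_ms={"calm": 0.0, "control": 0.0, "experimental": 0.0},
        )
        rec, truth = gen_ecg(cfg, "calm", 0)
        pre = ecg.standardize(ecg.apply_bandpass(ecg.apply_notch(rec)))
        window = pre.samples[6000:10001]
        acf = ecg.short_time_autocorr(window, 4000)
        period = ecg.estimate_rr_interval(ecg.clip_autocorr(acf))
        assert abs(period - 1600) <= 20

    def test_nothing_survives_clipping(self):
        clipped = np.zeros(50)
        clipped[0] = 0.9
        with pytest.raises(PeriodNotFound):
            ecg.estimate_rr_interval(clipped)


class TestRelocation:
    def periodic_record(self, period=1600, n=24000):
        x = gaussian_peaks(list(range(800, n - 400, period)), n=n)
        return ecg.ECGRecord(x, FS)

    def test_boundaries_at_interbeat_midpoints(self):
        period = 1600
        rec = self.periodic_record(period)
        peaks = ecg.detect_r_peaks(rec, threshold_frac=0.5)
        inner = peaks.indices[(peaks.indices >= 2 * FS) & (peaks.indices < len(rec) - 2 * FS)]
        seg = ecg.relocate_heartbeat(rec, ecg.RPeakList(inner, 0.5))
        assert abs(seg.start_index - (inner[0] - period // 2)) <= 20
        assert abs(seg.end_index - (inner[-1] + period // 2)) <= 20
        # every detected R peak lies inside the segment
        assert seg.start_index < inner[0] and seg.end_index > inner[-1]

    def test_context_too_short(self):
        rec = self.periodic_record()
        peaks = ecg.detect_r_peaks(rec, threshold_frac=0.5)
        with pytest.raises(ContextTooShort):
            ecg.relocate_heartbeat(rec, peaks)  # first peak at 800 lacks 2 s context

    def test_midpoint_arithmetic_floors(self):
        # start = R1 - T1 // 2 with odd T1 floors the half-interval
        assert 4000 - 1601 // 2 == 3200
        seg_end = 10000 + 1501 // 2
        assert seg_end == 10750


class TestRender:
    def test_shape_range_and_determinism(self, rng):
        x = rng.normal(size=5000)
        seg = ecg.HeartbeatSegment(x, 0, 4999, FS)
        img1 = ecg.render_ecg_image(seg)
        img2 = ecg.render_ecg_image(seg)
        assert img1.pixels.shape == (230, 307)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert img1.pixels.min() >= 0.0 and img1.pixels.max() <= 1.0

    def test_constant_signal_single_line(self):
        seg = ecg.HeartbeatSegment(np.full(1000, 3.3), 0, 999, FS)
        img = ecg.render_ecg_image(seg)
        rows = np.flatnonzero(img.pixels.any(axis=1))
        assert rows.tolist() == [(230 - 1) // 2]
        assert np.all(img.pixels[rows[0]] == 1.0)

    def test_empty_segment_rejected(self):
        with pytest.raises(DegenerateInput):
            ecg.render_ecg_image(np.empty(0))


class TestIO:
    def test_csv_roundtrip(self, tmp_path, rng):
        import pandas as pd

        x = rng.normal(size=100)
        path = tmp_path / "trace.csv"
        pd.DataFrame({"ecg_mv fs=2000": x}).to_csv(path, index=False)
        rec = ecg.read_ecg_csv(path)
        assert rec.fs == 2000
        assert np.allclose(rec.samples, x)

    def test_missing_fs_rejected(self, tmp_path):
        path = tmp_path / "trace.csv"
        path.write_text("v\n1.0\n2.0\n")
        with pytest.raises(InvalidConfiguration):
            ecg.read_ecg_csv(path)
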