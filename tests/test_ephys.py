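"""Ripple detection, MUA, EMG gating and extrema-triggered averaging."""

import numpy as np
import pytest

from ripplecortex import DetectionParams, SynthConfig, generate_lfp
from ripplecortex.ephys import (
    RippleEvent,
    compute_mua,
    compute_ripple_power,
    detect_ripples,
    exclude_by_emg,
    extrema_triggered_power,
    match_events,
    merge_close_events,
    ripple_band_filter,
    ripple_band_kernel,
)

RATE = 1000.0


class TestRipplePower:
    def test_zero_signal_gives_zero_power(self):
        assert np.allclose(compute_ripple_power(np.zeros(2000), RATE), 0.0)

    def test_output_length_equals_input(self):
        x = np.random.default_rng(0).standard_normal(3456)
        assert compute_ripple_power(x, RATE).size == x.size

    def test_band_response_matches_kernel_transfer_function(self):
        """Oracle: the analytic frequency response of the summed kernel."""
        kernel = ripple_band_kernel(RATE)
        freqs = np.fft.rfftfreq(8192, 1 / RATE)
        transfer = np.abs(np.fft.rfft(kernel, 8192))
        t = np.arange(0, 4.0, 1 / RATE)
        for f0 in (150.0, 10.0):
            x = np.sin(2 * np.pi * f0 * t)
            power = compute_ripple_power(x, RATE)
            mid = power[1000:-1000].mean()
            expected = transfer[np.argmin(np.abs(freqs - f0))] * (2 / np.pi)
            assert mid == pytest.approx(expected, rel=0.05)
        # in-band passes, out-of-band is blocked
        g150 = transfer[np.argmin(np.abs(freqs - 150.0))]
        g10 = transfer[np.argmin(np.abs(freqs - 10.0))]
        assert g150 > 0.2 and g10 < 1e-3

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist|rate"):
            compute_ripple_power(np.zeros(1000), 400.0)


class TestDetect:
    def test_constant_signal_yields_no_events(self):
        assert detect_ripples(np.ones(5000), RATE) == []

    def test_nan_signal_raises(self):
        x = np.zeros(5000)
        x[100] = np.nan
        with pytest.raises(ValueError, match="finite"):
            detect_ripples(x, RATE)

    def test_close_centers_are_concatenated(self):
        """Two bursts 40 ms apart merge into one event (50 ms rule)."""
        rng = np.random.default_rng(1)
        x = 0.05 * rng.standard_normal(int(4 * RATE))
        t = np.arange(x.size) / RATE
        for c in (2.0, 2.04):
            tau = t - c
            x += -3.0 * np.exp(-(tau**2) / (2 * 0.004**2)) * np.cos(2 * np.pi * 160 * tau)
        events = detect_ripples(x, RATE)
        assert len(events) == 1
        assert events[0].onset < 2.0 < 2.04 < events[0].offset

    def test_detection_recovers_implanted_events(self, default_session):
        truth = default_session["truth"]
        events = detect_ripples(default_session["lfp"], RATE)
        centers = np.array([e.center for e in events])
        matched, fp, miss = match_events(centers, truth.ripple_times, 0.010)
        n = truth.ripple_times.size
        assert matched >= 0.9 * n
        assert matched >= 0.9 * len(events)

    def test_false_positive_rate_on_pure_noise(self):
        total_fp, total_s = 0, 0.0
        for seed in range(10):
            cfg = SynthConfig(rng_seed=900 + seed, ripple_rate_per_min=0.0, duration_s=20.0)
            noise, _ = generate_lfp(cfg)
            total_fp += len(detect_ripples(noise, RATE))
            total_s += cfg.duration_s
        assert total_fp / total_s < 0.05

    def test_raising_threshold_never_adds_detections(self, default_session):
        counts = [
            len(detect_ripples(default_session["lfp"], RATE, DetectionParams(detect_k=k)))
            for k in (3.0, 4.0, 5.0, 6.0, 8.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_merge_is_idempotent(self):
        rng = np.random.default_rng(2)
        filtered = rng.standard_normal(10000)
        power = np.abs(filtered)
        events = [
            RippleEvent(o, o + 0.03, o + 0.01, 0.03, 5.0)
            for o in (1.0, 1.02, 1.08, 2.0, 2.03, 5.0)
        ]
        once = merge_close_events(events, filtered, power, RATE, 0.05)
        twice = merge_close_events(once, filtered, power, RATE, 0.05)
        assert [(e.onset, e.offset) for e in once] == [
            (e.onset, e.offset) for e in twice
        ]
        gaps = np.diff([e.center for e in once])
        assert np.all(gaps >= 0.05)


class TestEMG:
    def _events(self, centers):
        return [RippleEvent(c - 0.02, c + 0.02, c, 0.04, 5.0) for c in centers]

    def test_flat_emg_excludes_nothing(self):
        emg = np.random.default_rng(0).standard_normal(int(10 * RATE))
        kept, excluded = exclude_by_emg(self._events([3.0, 6.0]), emg, RATE)
        assert len(kept) == 2 and excluded == []

    def test_burst_within_half_second_excludes_event(self):
        rng = np.random.default_rng(0)
        emg = rng.standard_normal(int(10 * RATE))
        burst = slice(int(3.3 * RATE), int(3.5 * RATE))  # center + 0.3 s
        emg[burst] *= 10.0
        kept, excluded = exclude_by_emg(self._events([3.0, 6.0]), emg, RATE)
        assert [e.center for e in excluded] == [3.0]
        assert [e.center for e in kept] == [6.0]

    def test_burst_outside_window_keeps_event(self):
        rng = np.random.default_rng(0)
        emg = rng.standard_normal(int(10 * RATE))
        emg[int(3.8 * RATE) : int(4.0 * RATE)] *= 10.0
        kept, _ = exclude_by_emg(self._events([3.0]), emg, RATE)
        assert len(kept) == 1

    def test_exclusion_fraction_tracks_follow_probability(self):
        """Generator oracle: excluded fraction ~ emg_follow_prob."""
        from ripplecortex import generate_emg

        n_followed = n_excluded = n_total = 0
        for seed in range(6):
            cfg = SynthConfig(rng_seed=300 + seed, duration_s=240.0)
            lfp, truth = generate_lfp(cfg)
            emg = generate_emg(cfg, truth)
            events = detect_ripples(lfp, RATE)
            kept, excluded = exclude_by_emg(events, emg, RATE)
            n_excluded += len(excluded)
            n_total += len(events)
            n_followed += truth.emg_followed.sum()
        frac = n_excluded / n_total
        p = SynthConfig().emg_follow_prob
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n_total) + 0.05

    def test_order_and_partition_preserved(self, default_session):
        events = detect_ripples(default_session["lfp"], RATE)
        kept, excluded = exclude_by_emg(events, default_session["emg"], RATE)
        assert len(kept) + len(excluded) == len(events)
        merged = sorted(kept + excluded, key=lambda e: e.center)
        assert [e.center for e in merged] == [e.center for e in events]

    def test_negative_halfwidth_rejected(self):
        with pytest.raises(ValueError):
            exclude_by_emg([], np.zeros(100), RATE, halfwidth=-1.0)


class TestMUA:
    def test_dc_signal_gives_zero(self):
        mua = compute_mua(np.full(5000, 3.3), RATE)
        assert np.all(mua < 1e-8)

    def test_white_noise_mean_matches_rectified_gaussian(self):
        """Oracle: E|X| = sigma*sqrt(2/pi), scaled by the filter gain."""
        rng = np.random.default_rng(0)
        sigma = 2.0
        x = sigma * rng.standard_normal(int(60 * RATE))
        mua = compute_mua(x, RATE)
        from scipy import signal as sps

        sos = sps.butter(4, 300.0, btype="highpass", fs=RATE, output="sos")
        gain = np.sqrt(np.mean(sps.sosfiltfilt(sos, rng.standard_normal(200000)) ** 2))
        expected = sigma * gain * np.sqrt(2 / np.pi)
        assert mua.mean() == pytest.approx(expected, rel=0.02)

    def test_mua_elevated_at_ripples(self, default_session):
        truth = default_session["truth"]
        mua = compute_mua(default_session["lfp"], RATE)
        idx = np.round(truth.ripple_times * RATE).astype(int)
        at_events = mua[idx].mean()
        assert at_events > 1.5 * np.median(mua)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            compute_mua(np.zeros(1000), 500.0)


class TestExtremaTriggered:
    def test_trough_triggered_sine_has_minimum_at_zero_lag(self):
        t = np.arange(0, 20, 1 / 100.0)
        sig = np.sin(2 * np.pi * 1.0 * t)
        lags, mean, _, trig = extrema_triggered_power(
            sig, sig, 100.0, mode="troughs", window=0.4
        )
        assert lags[np.argmin(mean)] == pytest.approx(0.0, abs=1e-9)
        assert trig.size >= 15

    def test_independent_signals_give_flat_average(self):
        rng = np.random.default_rng(0)
        n = 60000
        power = np.abs(rng.standard_normal(n))
        ref = np.cumsum(rng.standard_normal(n))  # smooth-ish random walk
        from scipy.ndimage import uniform_filter1d

        ref = uniform_filter1d(ref, 200)
        lags, mean, sem, trig = extrema_triggered_power(
            power, ref, 1000.0, mode="peaks", window=0.2
        )
        # shuffle oracle: triggered average of shuffled trigger times
        sh_means = []
        for _ in range(50):
            fake = rng.integers(200, n - 200, size=trig.size)
            chunks = power[fake[:, None] + np.arange(-200, 201)[None, :]]
            sh_means.append(chunks.mean(axis=0))
        band = np.std(sh_means)
        # max over ~400 lags of a null deviation concentrates near
        # sqrt(2 ln 400) ~ 3.5 sigma; 5 sigma bounds it comfortably
        assert np.abs(mean - power.mean()).max() < 5 * band
        assert np.abs(mean - power.mean()).mean() < 2 * band

    def test_no_extrema_raises(self):
        with pytest.raises(ValueError, match="extrema"):
            extrema_triggered_power(np.zeros(1000), np.zeros(1000), 100.0)

    def test_ripple_power_peaks_before_stack_troughs(self, widefield_session):
        """Construction oracle: aRSC dips follow ripples, so trough-
        triggered ripple power is maximal at negative lag."""
        from ripplecortex.ephys import compute_ripple_power
        from ripplecortex.imaging import extract_region_trace

        cfg = widefield_session["cfg"]
        power = compute_ripple_power(widefield_session["lfp"], RATE)
        trace = extract_region_trace(
            widefield_session["stack"], widefield_session["masks"], "aRSC"
        )
        # common 100 Hz base
        p100 = power[:: int(RATE / cfg.stack_rate)][: trace.size]
        lags, mean, _, _ = extrema_triggered_power(
            p100, trace[: p100.size], cfg.stack_rate, mode="troughs", window=0.5
        )
        peak_lag = lags[np.argmax(mean)]
        assert peak_lag < 0
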