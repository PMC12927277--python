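"""Signal-conditioning unit tests with closed-form and brute-force oracles."""

import numpy as np
import pytest

from pupilpipe.preprocess import (
    INTERPOLATED,
    VALID,
    InvalidWindow,
    RecordingUnusableError,
    derivative_pass,
    detect_blinks,
    interpolate_windows,
    lowpass_downsample,
)


class TestLowpassDownsample:
    def test_dc_gain_is_unity(self):
        out = lowpass_downsample(np.full(5000, 42.0), 1000.0)
        assert np.allclose(out, 42.0)

    def test_output_length_floor(self):
        for n in (5000, 5004, 5009, 5010):
            out = lowpass_downsample(np.zeros(n), 1000.0)
            assert len(out) == n // 10

    def test_transfer_function_at_10hz(self):
        # [DERIVED] forward-backward 4th-order Butterworth at fc = 6 Hz:
        # analog prototype gain at 10 Hz is 1/(1 + (10/6)^8) = 0.016519; the
        # digital (bilinear, fs = 1000 Hz) squared magnitude is 0.015684.
        # The oracle is the designed filter's frequency response, which
        # checks the zero-phase application and decimation independently.
        from scipy import signal as sps

        sos = sps.butter(4, 6.0, btype="low", fs=1000.0, output="sos")
        _, h = sps.sosfreqz(sos, worN=[10.0], fs=1000.0)
        expected = float(np.abs(h[0]) ** 2)  # applied forward and backward
        assert expected == pytest.approx(0.016491, rel=1e-3)
        t = np.arange(20000) / 1000.0
        out = lowpass_downsample(np.sin(2 * np.pi * 10.0 * t), 1000.0)
        mid = out[500:1500]  # avoid filtfilt edge transients
        t_mid = np.arange(500, 1500) / 100.0
        # demodulated amplitude (max-of-samples underestimates at 10
        # samples per cycle)
        amp = 2.0 * np.abs(np.mean(mid * np.exp(-2j * np.pi * 10.0 * t_mid)))
        assert amp == pytest.approx(expected, rel=0.02)

    def test_passband_tone_preserved(self):
        t = np.arange(20000) / 1000.0
        out = lowpass_downsample(np.sin(2 * np.pi * 1.0 * t), 1000.0)
        mid = out[500:1500]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.01)

    def test_nan_passthrough(self):
        x = np.sin(np.arange(5000) / 200.0)
        x[1000:1200] = np.nan
        out = lowpass_downsample(x, 1000.0)
        assert np.isnan(out[100:120]).all()
        assert np.isfinite(out[:100]).all()

    def test_non_integer_decimation_rejected(self):
        with pytest.raises(ValueError):
            lowpass_downsample(np.zeros(5000), 1000.0, out_rate=300.0)


class TestDetectBlinks:
    def test_merge_and_pad_worked_example(self):
        # [DERIVED] NaN runs [1000, 1100) and [1200, 1300) ms: gap 100 < 250
        # merges them; +/-150 ms padding gives a single window [850, 1450)
        x = np.zeros(5000)
        x[1000:1100] = np.nan
        x[1200:1300] = np.nan
        wins = detect_blinks(x, 1000.0)
        assert len(wins) == 1
        assert wins[0].start_ms == pytest.approx(850.0)
        assert wins[0].end_ms == pytest.approx(1450.0)
        assert wins[0].source == "blink"

    def test_distant_runs_stay_separate(self):
        x = np.zeros(5000)
        x[1000:1100] = np.nan
        x[2000:2100] = np.nan  # gap 900 >= 250
        wins = detect_blinks(x, 1000.0)
        assert [(w.start_ms, w.end_ms) for w in wins] == [(850.0, 1250.0), (1850.0, 2250.0)]

    def test_clipped_at_edges(self):
        x = np.zeros(1000)
        x[:50] = np.nan
        (w,) = detect_blinks(x, 1000.0)
        assert w.start_ms == 0.0
        assert w.end_ms == pytest.approx(200.0)

    def test_clean_trace_no_windows(self):
        assert detect_blinks(np.zeros(1000), 1000.0) == []


def brute_force_derivative_windows(values, fs, sd_multiplier,
                                   quiet_ms=60.0, pre_ms=150.0, post_ms=250.0):
    """Naive O(n^2) restatement of the quiet-period rule.

    Threshold: sd_multiplier times the SD of the first difference. A sample
    index j of the derivative is an artifact core if |d[j]| >= threshold.
    The artifact start point is the last index at or before the core that is
    preceded by quiet_ms of sub-threshold derivative; the end point is the
    first index at or after the core that is followed by quiet_ms of
    sub-threshold derivative. The invalid sample window spans those points,
    extended pre_ms before and post_ms after, clipped, with overlaps merged.
    """
    values = np.asarray(values, float)
    d = np.diff(values)
    thr = sd_multiplier * np.std(d)
    bad = np.abs(d) >= thr
    if not bad.any():
        return []
    step = 1000.0 / fs
    q = max(1, int(round(quiet_ms * fs / 1000.0)))
    n_d = len(d)
    total_ms = len(values) * step

    def quiet_before(j):
        return all(not bad[i] for i in range(max(0, j - q), j))

    def quiet_after(j):
        return all(not bad[i] for i in range(j + 1, min(n_d, j + 1 + q)))

    intervals = []
    for j in range(n_d):
        if not bad[j]:
            continue
        s = 0
        for k in range(j, -1, -1):
            if quiet_before(k):
                s = k
                break
        e = n_d - 1
        for k in range(j, n_d):
            if quiet_after(k):
                e = k
                break
        start = max(0.0, s * step - pre_ms)
        end = min(total_ms, (e + 2) * step + post_ms)
        intervals.append((start, end))
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


class TestDerivativePass:
    def _random_trace(self, rng, n=1000):
        x = np.cumsum(rng.normal(0.0, 0.3, n))
        for _ in range(rng.integers(1, 5)):
            i = rng.integers(10, n - 10)
            x[i:] += rng.normal(0.0, 30.0)  # step discontinuity
        return x

    @pytest.mark.parametrize("sd_mult", [0.75, 3.5])
    def test_matches_brute_force_on_random_traces(self, rng, sd_mult):
        for _ in range(25):
            x = self._random_trace(rng)
            got = [(w.start_ms, w.end_ms) for w in derivative_pass(x, 100.0, sd_mult)]
            expected = brute_force_derivative_windows(x, 100.0, sd_mult)
            assert got == pytest.approx(expected)

    def test_flat_trace_warns_and_returns_nothing(self):
        with pytest.warns(UserWarning):
            assert derivative_pass(np.zeros(500), 100.0, 0.75) == []

    def test_single_jump_window_covers_it(self):
        x = np.zeros(1000)
        x[500:] = 100.0
        (w,) = derivative_pass(x, 100.0, 3.5)
        # jump between samples 499 and 500 must lie inside the window
        assert w.start_ms <= 4990.0 and w.end_ms >= 5010.0

    def test_nan_input_rejected(self):
        x = np.zeros(500)
        x[10] = np.nan
        with pytest.raises(ValueError):
            derivative_pass(x, 100.0, 0.75)

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError):
            derivative_pass(np.zeros(500), 100.0, 0.0)


class TestInterpolateWindows:
    def test_closed_form_line_between_neighbours(self):
        # [DERIVED] t^2 data with window [30, 60) at 10 ms sampling: samples
        # at 30/40/50 ms are replaced by the line through (20, 400) and
        # (60, 3600): values 1200, 2000, 2800
        t = np.arange(10) * 10.0
        x = t**2
        flags = np.full(10, VALID, np.int8)
        out, fl = interpolate_windows(t, x, flags, [InvalidWindow(30.0, 60.0, "w")])
        assert out[3:6] == pytest.approx([1200.0, 2000.0, 2800.0])
        assert list(fl[3:6]) == [INTERPOLATED] * 3
        assert np.array_equal(out[:3], x[:3]) and np.array_equal(out[6:], x[6:])

    def test_no_windows_is_identity(self):
        t = np.arange(10) * 10.0
        x = np.sin(t)
        out, fl = interpolate_windows(t, x, np.full(10, VALID, np.int8), [])
        np.testing.assert_array_equal(out, x)
        assert (fl == VALID).all()

    def test_edge_windows_constant_extension(self):
        t = np.arange(10) * 10.0
        x = np.arange(10.0)
        out, _ = interpolate_windows(t, x, np.full(10, VALID, np.int8),
                                     [InvalidWindow(0.0, 30.0, "w")])
        assert out[:3] == pytest.approx([3.0, 3.0, 3.0])

    def test_total_coverage_raises(self):
        t = np.arange(10) * 10.0
        with pytest.raises(RecordingUnusableError):
            interpolate_windows(t, np.zeros(10), np.full(10, VALID, np.int8),
                                [InvalidWindow(0.0, 100.0, "w")])

    def test_conservation_outside_windows(self, rng):
        t = np.arange(200) * 10.0
        x = rng.normal(size=200)
        wins = [InvalidWindow(200.0, 400.0, "a"), InvalidWindow(1000.0, 1200.0, "b")]
        out, fl = interpolate_windows(t, x, np.full(200, VALID, np.int8), wins)
        untouched = fl == VALID
        np.testing.assert_array_equal(out[untouched], x[untouched])
        # flags only ever escalate
        assert set(np.unique(fl)) <= {VALID, INTERPOLATED}
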