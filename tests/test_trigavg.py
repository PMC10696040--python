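"""Burst-triggered averaging and amplitude readout from averaged waveforms."""

import numpy as np
import pytest

from phrenic import Trace, amplitude_from_average, postinsp_vna_amplitude, triggered_average
from phrenic.types import EventSeries, TriggeredAverage


def _itrace(x, fs=100.0, channel="PNA", t0=0.0):
    return Trace(channel, fs, x, t0=t0, kind="integrated")


def brute_force_average(x, fs, trig_times, window, step, lag_range, duration):
    """Stack-and-mean reference implementation."""
    il, ih = int(round(lag_range[0] * fs)), int(round(lag_range[1] * fs))
    out = []
    start = 0.0
    while start < duration:
        segs = []
        for t in trig_times:
            if start <= t < start + window:
                i = int(round(t * fs))
                if i + il >= 0 and i + ih <= len(x):
                    segs.append(x[i + il:i + ih])
        if segs:
            out.append((start, np.mean(segs, axis=0), len(segs)))
        start += step
    return out


class TestTriggeredAverage:
    def test_single_trigger_returns_aligned_segment(self, rng):
        x = rng.standard_normal(2000) ** 2
        tr = _itrace(x, fs=100.0)
        trig = EventSeries("on", np.array([10.0]))
        avgs = triggered_average({"PNA": tr}, trig, window=20.0, step=10.0,
                                 lag_range=(-1.0, 2.0))
        got = avgs[0].mean_traces["PNA"]
        assert np.array_equal(got, x[900:1200])
        assert avgs[0].n_triggers == 1

    def test_identical_cycles_average_to_one_cycle(self):
        fs = 100.0
        period = int(4 * fs)
        cycle = np.concatenate([np.linspace(0, 1, int(fs)), np.zeros(period - int(fs))])
        x = np.tile(cycle, 10)
        tr = _itrace(x, fs)
        trig = EventSeries("on", np.arange(8.0, 32.0, 4.0))
        avgs = triggered_average({"PNA": tr}, trig, window=40.0, step=40.0,
                                 lag_range=(-1.0, 3.0))
        single = x[int(7 * fs):int(11 * fs)]
        assert np.allclose(avgs[0].mean_traces["PNA"], single)

    def test_averaging_reduces_noise_as_sqrt_n(self):
        rng = np.random.default_rng(0)
        fs = 100.0
        ramp = np.linspace(0, 1, int(fs))
        cycle = np.concatenate([np.zeros(int(fs)), ramp])  # ramp starts at odd s
        clean = np.tile(cycle, 64)
        noisy = clean + 0.5 * rng.standard_normal(clean.size)
        noisy -= noisy.min()  # keep integrated-trace non-negativity
        trig = EventSeries("on", np.arange(1.0, 127.0, 2.0))

        def resid_sd(window):
            avgs = triggered_average({"PNA": _itrace(noisy, fs)}, trig,
                                     window=window, step=1e9,
                                     lag_range=(0.0, 1.0))
            a = avgs[0]
            return float(np.std(a.mean_traces["PNA"] - ramp)), a.n_triggers

        sd16, n16 = resid_sd(32.0)  # triggers 1,3,...,31
        sd4, n4 = resid_sd(8.0)     # triggers 1,3,5,7
        assert (n16, n4) == (16, 4)
        assert sd4 / sd16 == pytest.approx(2.0, rel=0.35)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            n = 3000
            fs = 50.0
            x = np.abs(rng.standard_normal(n))
            trig_times = np.sort(rng.uniform(0, n / fs, size=12))
            trig_times = trig_times[np.diff(trig_times, prepend=-1) > 0.1]
            trig = EventSeries("on", trig_times)
            lag = (-0.5, 1.5)
            avgs = triggered_average({"PNA": _itrace(x, fs)}, trig,
                                     window=20.0, step=10.0, lag_range=lag)
            want = brute_force_average(x, fs, trig_times, 20.0, 10.0, lag, n / fs)
            assert len(avgs) == len(want)
            for got, (ws, mean, cnt) in zip(avgs, want):
                assert got.window_start == pytest.approx(ws)
                assert got.n_triggers == cnt
                assert np.allclose(got.mean_traces["PNA"], mean, rtol=1e-12, atol=0)

    def test_shift_equivariance(self, rng):
        x = np.abs(rng.standard_normal(4000))
        fs = 100.0
        trig_times = np.array([5.0, 9.0, 13.0, 21.0])
        a = triggered_average({"PNA": _itrace(x, fs)}, EventSeries("on", trig_times),
                              window=40.0, step=40.0, lag_range=(-1.0, 1.0))
        dt = 7.0
        b = triggered_average({"PNA": _itrace(x, fs, t0=dt)},
                              EventSeries("on", trig_times + dt),
                              window=40.0, step=40.0, lag_range=(-1.0, 1.0))
        assert np.array_equal(a[0].mean_traces["PNA"], b[0].mean_traces["PNA"])

    def test_window_bookkeeping(self, rng):
        x = np.abs(rng.standard_normal(6000))
        fs = 100.0
        trig_times = np.sort(rng.uniform(5.0, 55.0, size=15))
        avgs = triggered_average({"PNA": _itrace(x, fs)},
                                 EventSeries("on", trig_times),
                                 window=20.0, step=10.0, lag_range=(-0.2, 0.2))
        for a in avgs:
            manual = np.sum((trig_times >= a.window_start) &
                            (trig_times < a.window_end))
            assert a.n_triggers == manual

    def test_edge_triggers_skipped_not_fatal(self):
        x = np.abs(np.random.default_rng(0).standard_normal(500))
        tr = _itrace(x, fs=100.0)
        trig = EventSeries("on", np.array([0.1, 2.5]))  # first too close to edge
        avgs = triggered_average({"PNA": tr}, trig, window=5.0, step=5.0,
                                 lag_range=(-1.0, 1.0))
        assert avgs[0].n_triggers == 1


def _avg_from(x, fs=100.0, lag0=-1.0, channel="PNA"):
    lag = lag0 + np.arange(len(x)) / fs
    return TriggeredAverage(0.0, 20.0, lag, {channel: np.asarray(x, float)}, 4)


class TestAmplitude:
    def test_triangle_on_baseline(self):
        fs = 100.0
        wave = np.full(300, 0.2)
        wave[100:150] = np.linspace(0.2, 2.0, 50)
        wave[150:200] = np.linspace(2.0, 0.2, 50)
        amp = amplitude_from_average(_avg_from(wave, fs), "PNA",
                                     burst_interval=(0.0, 1.0))
        assert amp == pytest.approx(1.8, abs=0.05)

    def test_zero_average(self):
        assert amplitude_from_average(_avg_from(np.zeros(300)), "PNA",
                                      burst_interval=(0.0, 1.0)) == 0.0

    def test_amplitude_linearity_exact(self, rng):
        wave = np.abs(rng.standard_normal(300))
        a1 = amplitude_from_average(_avg_from(wave), "PNA", (0.0, 1.0))
        a3 = amplitude_from_average(_avg_from(3.0 * wave), "PNA", (0.0, 1.0))
        assert a3 == pytest.approx(3.0 * a1, rel=1e-12)

    def test_empty_burst_interval_error(self):
        with pytest.raises(ValueError):
            amplitude_from_average(_avg_from(np.zeros(300)), "PNA", (50.0, 60.0))


class TestPostInspiratoryVNA:
    def test_pure_postinsp_exponential(self):
        # VNA: zero during inspiration, exp decay of height 1 after offset
        fs = 1000.0
        lag = -0.5 + np.arange(2500) / fs
        offset = 0.9
        vna = np.where(lag > offset, np.exp(-(lag - offset) / 0.8), 0.0)
        avg = TriggeredAverage(0.0, 20.0, lag, {"VNA": vna}, 3)
        amp = postinsp_vna_amplitude(avg, pna_offset_lag=offset, w_pi=1.0)
        assert amp == pytest.approx(1.0, abs=0.01)

    def test_no_postinsp_component_small(self):
        # VNA identical to an inspiratory ramp: only residual smoothing tail
        fs = 1000.0
        lag = -0.5 + np.arange(2500) / fs
        ramp = np.where((lag >= 0) & (lag < 0.9), 0.3 + 0.7 * lag / 0.9, 0.0)
        avg = TriggeredAverage(0.0, 20.0, lag, {"VNA": ramp}, 3)
        amp = postinsp_vna_amplitude(avg, pna_offset_lag=0.9, w_pi=1.0)
        assert amp < 0.2 * ramp.max()

    def test_zero_vna(self):
        lag = -0.5 + np.arange(2500) / 1000.0
        avg = TriggeredAverage(0.0, 20.0, lag, {"VNA": np.zeros(2500)}, 3)
        assert postinsp_vna_amplitude(avg, 0.9, 1.0) == 0.0

    def test_interval_outside_lag_axis(self):
        lag = -0.5 + np.arange(100) / 1000.0
        avg = TriggeredAverage(0.0, 20.0, lag, {"VNA": np.zeros(100)}, 1)
        with pytest.raises(ValueError):
            postinsp_vna_amplitude(avg, 5.0, 1.0)
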