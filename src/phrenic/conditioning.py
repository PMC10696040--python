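"""Raw-signal conditioning: rectify/integrate nerve traces, R peaks, heart rate.

The integrated (∫) trace is the full-wave rectified signal smoothed with a
0.05-s centered moving average; at record edges the window shrinks to the
available samples so no spurious zeros appear.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import INTEGRATED, RAW, EventSeries, MetricTimeCourse, Trace

__all__ = ["bandpass", "integrate", "detect_r_peaks", "heart_rate"]


def bandpass(trace: Trace, lo: float, hi: float, order: int = 4) -> Trace:
    """Zero-phase Butterworth band-pass (optional stage; synthetic signals
    are generated in-band, real acquisitions typically use 100–5000 Hz)."""
    if trace.kind != RAW:
        raise TypeError("bandpass expects a raw trace")
    nyq = trace.fs / 2.0
    if not (0 < lo < hi):
        raise ValueError(f"require 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= nyq:
        raise ValueError(f"upper corner {hi} Hz must be below the Nyquist rate {nyq} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=trace.fs, output="sos")
    out = sps.sosfiltfilt(sos, trace.samples)
    return Trace(trace.channel, trace.fs, out, t0=trace.t0, kind=RAW, units=trace.units)


def integrate(trace: Trace, window: float = 0.05) -> Trace:
    """Rectified, moving-average-smoothed trace.

    ``out[i]`` is the mean of ``|x|`` over a centered window of
    ``round(window * fs)`` samples, shrinking at the edges.  Output has the
    same length and time base as the input and satisfies
    ``0 <= out <= max|x|`` and 1-homogeneity ``integrate(a*x) = |a|*integrate(x)``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    length = int(round(window * trace.fs))
    if length < 1:
        raise ValueError(
            f"window {window} s is shorter than one sample at fs={trace.fs} Hz"
        )
    x = np.abs(trace.samples)
    n = x.size
    left = (length - 1) // 2
    right = length // 2
    out = np.empty(n)
    if n > length:
        # interior: full windows via a strided view (pairwise-summation mean)
        view = np.lib.stride_tricks.sliding_window_view(x, length)
        out[left:n - right] = view.mean(axis=1)
        edge = [*range(left), *range(n - right, n)]
    else:
        edge = range(n)
    for i in edge:  # shrinking windows at the record edges
        out[i] = x[max(i - left, 0):min(i + right + 1, n)].mean()
    return Trace(trace.channel, trace.fs, out, t0=trace.t0, kind=INTEGRATED,
                 units=trace.units)


def robust_sd(x: np.ndarray) -> float:
    """SD estimate from the median absolute deviation (Gaussian-consistent)."""
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def detect_r_peaks(ecg: Trace, k: float = 4.0, refractory: float = 0.15) -> EventSeries:
    """R-wave times: local maxima above ``k`` robust SDs with a refractory period.

    A flat record yields an empty series rather than an error.
    """
    if ecg.duration <= 2.0:
        raise ValueError("need more than 2 s of ECG")
    x = ecg.samples
    sd = robust_sd(x)
    if sd == 0 and np.ptp(x) == 0:
        return EventSeries("R", np.empty(0))
    height = np.median(x) + k * sd if sd > 0 else np.median(x) + 0.5 * np.ptp(x)
    distance = max(int(round(refractory * ecg.fs)), 1)
    peaks, _ = sps.find_peaks(x, height=height, distance=distance)
    return EventSeries("R", ecg.t0 + peaks / ecg.fs)


def heart_rate(rpeaks: EventSeries, step: float = 10.0,
               duration: float | None = None) -> MetricTimeCourse:
    """Instantaneous heart rate 60/RR (beats/min) binned to the 10-s grid.

    Each R-R interval contributes at its midpoint; bins average the
    intervals whose midpoints they contain; empty bins are NaN gaps.
    """
    times = rpeaks.times
    if len(times) < 2:
        import warnings

        warnings.warn("fewer than 2 R peaks; heart-rate time course is empty")
        return MetricTimeCourse("HR", np.empty(0), np.empty(0))
    rr = np.diff(times)
    hr = 60.0 / rr
    mid = times[:-1] + 0.5 * rr
    if duration is None:
        duration = float(times[-1])
    n_bins = int(np.ceil(duration / step))
    idx = np.floor(mid / step).astype(int)
    ok = (idx >= 0) & (idx < n_bins)
    sums = np.bincount(idx[ok], weights=hr[ok], minlength=n_bins)
    counts = np.bincount(idx[ok], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * step
    return MetricTimeCourse("HR", centers, values)
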