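"""Burst-triggered averaging over sliding windows and amplitude readout.

Averages are computed per 20-s window advanced in 10-s steps: segments of
the integrated channels are extracted around each burst-onset trigger inside
the window and averaged pointwise.  Windows without usable triggers yield
gaps (no average), never zeros, so downstream time courses stay unbiased.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import INTEGRATED, EventSeries, Trace, TriggeredAverage

__all__ = ["triggered_average", "amplitude_from_average", "postinsp_vna_amplitude"]

log = logging.getLogger(__name__)


def triggered_average(
    traces: dict[str, Trace],
    triggers: EventSeries,
    window: float = 20.0,
    step: float = 10.0,
    lag_range: tuple[float, float] = (-1.0, 5.0),
) -> list[TriggeredAverage]:
    """Sliding-window burst-triggered averages of integrated channels.

    Triggers whose lag segment would run past either record edge are
    skipped (and logged); a window in which every trigger is skipped
    produces no entry.
    """
    if not traces:
        raise ValueError("need at least one trace")
    ref = next(iter(traces.values()))
    for tr in traces.values():
        if tr.kind != INTEGRATED:
            raise TypeError(f"channel {tr.channel!r} is not integrated")
        if tr.fs != ref.fs or tr.n != ref.n or tr.t0 != ref.t0:
            raise ValueError("all channels must share fs, length and t0")
    fs, n, t0 = ref.fs, ref.n, ref.t0
    il = int(round(lag_range[0] * fs))
    ih = int(round(lag_range[1] * fs))
    if ih <= il:
        raise ValueError("empty lag range")
    lag_axis = np.arange(il, ih) / fs

    t_end = t0 + n / fs
    out: list[TriggeredAverage] = []
    n_skipped = 0
    start = t0
    while start < t_end:
        sel = triggers.times[(triggers.times >= start) & (triggers.times < start + window)]
        tidx = np.round((sel - t0) * fs).astype(int)
        ok = (tidx + il >= 0) & (tidx + ih <= n)
        n_skipped += int((~ok).sum())
        tidx = tidx[ok]
        if tidx.size:
            gather = tidx[:, None] + np.arange(il, ih)[None, :]
            mean_traces = {
                label: tr.samples[gather].mean(axis=0)
                for label, tr in traces.items()
            }
            out.append(
                TriggeredAverage(
                    window_start=start, window_end=start + window,
                    lag_axis=lag_axis, mean_traces=mean_traces,
                    n_triggers=int(tidx.size),
                )
            )
        start += step
    if n_skipped:
        log.info("triggered_average: skipped %d trigger(s) at record edges", n_skipped)
    return out


def _baseline(avg: TriggeredAverage, channel: str,
              baseline_interval: tuple[float, float]) -> float:
    m = (avg.lag_axis >= baseline_interval[0]) & (avg.lag_axis < baseline_interval[1])
    if not m.any():
        raise ValueError("pre-trigger baseline interval outside the lag axis")
    return float(avg.channel(channel)[m].mean())


def amplitude_from_average(
    avg: TriggeredAverage,
    channel: str = "PNA",
    burst_interval: tuple[float, float] = (0.0, 2.0),
    baseline_interval: tuple[float, float] = (-0.5, -0.1),
) -> float:
    """Burst amplitude measured from the averaged waveform.

    Maximum of the mean trace inside the burst lag interval minus the mean
    over the pre-trigger baseline span.
    """
    m = (avg.lag_axis >= burst_interval[0]) & (avg.lag_axis < burst_interval[1])
    if not m.any():
        raise ValueError("burst interval outside the lag axis")
    peak = float(avg.channel(channel)[m].max())
    return peak - _baseline(avg, channel, baseline_interval)


def postinsp_vna_amplitude(
    avg: TriggeredAverage,
    pna_offset_lag: float,
    w_pi: float,
    channel: str = "VNA",
    baseline_interval: tuple[float, float] = (-0.5, -0.1),
) -> float:
    """Post-inspiratory VNA amplitude from the averaged waveform.

    Maximum of the mean ∫VNA inside ``(pna_offset_lag, pna_offset_lag + w_pi]``
    — the early-expiratory window after the phrenic offset — minus the
    pre-trigger VNA baseline.  ``w_pi`` is conventionally half the median Te.
    """
    m = (avg.lag_axis > pna_offset_lag) & (avg.lag_axis <= pna_offset_lag + w_pi)
    if not m.any():
        raise ValueError("post-inspiratory interval outside the lag axis")
    peak = float(avg.channel(channel)[m].max())
    return peak - _baseline(avg, channel, baseline_interval)
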