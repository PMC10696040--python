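"""Core containers shared by all pipeline stages.

Time convention: seconds from session start (``t0``); all intervals are
half-open ``[start, end)``.  Amplitudes are in arbitrary units throughout —
only percent-of-baseline changes are meaningful downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

RAW = "raw"
INTEGRATED = "integrated"

#: channel labels recognised by the pipeline
CHANNELS = ("PNA", "VNA", "ECG", "PP")


@dataclass
class Trace:
    """One uniformly sampled channel.

    Parameters
    ----------
    channel : str
        Channel label, e.g. ``"PNA"``.
    fs : float
        Sampling rate in Hz.
    samples : numpy.ndarray
        Signal values (a.u.).
    t0 : float
        Start time in seconds.
    kind : str
        ``"raw"`` or ``"integrated"`` (rectified + smoothed).
    """

    channel: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0
    kind: str = RAW
    units: str = "a.u."

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"non-finite samples in channel {self.channel!r}")
        if self.kind == INTEGRATED and self.samples.size and self.samples.min() < 0:
            raise ValueError("integrated trace must be non-negative")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class EventSeries:
    """Strictly increasing event times (R waves, burst onsets, injections)."""

    label: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"event times of {self.label!r} must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class BurstEvent:
    """One detected inspiratory burst on the integrated phrenic trace.

    ``offset`` is the onset of the sharp terminal decrease of the burst,
    which marks the end of inspiration.
    """

    onset: float
    peak_time: float
    offset: float
    peak_amp: float
    baseline_amp: float

    def __post_init__(self) -> None:
        if not (self.onset < self.peak_time <= self.offset):
            raise ValueError(
                f"require onset < peak_time <= offset, got "
                f"{self.onset}, {self.peak_time}, {self.offset}"
            )
        if not (self.peak_amp > self.baseline_amp >= 0):
            raise ValueError("require peak_amp > baseline_amp >= 0")

    @property
    def duration(self) -> float:
        """Inspiratory duration Ti of this burst."""
        return self.offset - self.onset


@dataclass
class RespCycle:
    """One respiratory cycle, spanning inspiratory offset to the next offset.

    Ti is the inspiratory duration paired with the cycle, Te the expiratory
    duration obtained by subtraction (Te = Ttot - Ti), ``ratio`` the
    inspiratory fraction Ti/Ttot and ``f_inst`` the instantaneous frequency
    in cycles/min.
    """

    Ti: float
    Te: float
    Ttot: float
    ratio: float
    f_inst: float
    t_ref: float
    amp_pna: float = float("nan")
    amp_vna_postinsp: float = float("nan")

    def __post_init__(self) -> None:
        if self.Ti <= 0:
            raise ValueError("Ti must be positive")
        if self.Te < 0:
            raise ValueError("Te must be non-negative")
        if not (0 < self.ratio < 1):
            raise ValueError("ratio must lie in (0, 1)")


@dataclass
class TriggeredAverage:
    """Mean waveforms of integrated channels aligned on burst triggers."""

    window_start: float
    window_end: float
    lag_axis: np.ndarray
    mean_traces: dict[str, np.ndarray]
    n_triggers: int

    def channel(self, label: str) -> np.ndarray:
        if label not in self.mean_traces:
            raise KeyError(f"channel {label!r} not in triggered average")
        return self.mean_traces[label]

    @property
    def center(self) -> float:
        return 0.5 * (self.window_start + self.window_end)


@dataclass
class MetricTimeCourse:
    """A metric sampled on the common 10-s grid.

    ``values`` are in the metric's native units; ``percent`` is filled by
    :func:`phrenic.response.percent_of_baseline` and is relative to the
    pre-injection baseline (baseline mean == 100).  Gaps are NaN, never 0.
    """

    metric: str
    times: np.ndarray
    values: np.ndarray
    percent: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal shape")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.percent is not None:
            self.percent = np.asarray(self.percent, dtype=float)


@dataclass
class GroupStats:
    """Group summary for one metric: mean ± SEM plus a significance test."""

    metric: str
    n: int
    mean: float
    sem: float
    test: str
    statistic: float
    pvalue: float
    df: Optional[float] = None
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.pvalue < 0.05


@dataclass
class DrugProtocol:
    """Microinjection protocol: where, what, and when.

    ``injection_times`` are absolute session times (s).  ``pre_duration`` is
    the recorded time before the first injection and must accommodate the
    100-s baseline window.
    """

    site: str
    agent: str
    injection_times: list[float]
    pre_duration: float = 300.0
    post_duration: float = 600.0

    SITES = ("BotC", "preBotC", "rVRG")
    AGENTS = ("HA", "KYN", "B+S", "vehicle")

    def __post_init__(self) -> None:
        times = np.asarray(self.injection_times, dtype=float)
        if times.size == 0:
            raise ValueError("at least one injection time required")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("injection_times must be strictly increasing")
        if self.pre_duration < 100.0:
            raise ValueError(
                "pre_duration must be >= 100 s so the baseline window fits"
            )
        if times[0] < self.pre_duration:
            raise ValueError("first injection earlier than pre_duration")
        self.injection_times = [float(t) for t in times]

    @property
    def duration(self) -> float:
        return self.injection_times[-1] + self.post_duration


@dataclass
class RecordingSession:
    """A multi-channel recording plus protocol and (optional) ground truth.

    ``truth`` is a per-cycle table filled by the synthetic generator
    (columns: onset, offset, Ti, Te, amp_pna, amp_vna_postinsp, weight);
    it is absent for real recordings.
    """

    traces: dict[str, Trace]
    events: dict[str, EventSeries]
    protocol: Optional[DrugProtocol] = None
    truth: Optional[pd.DataFrame] = None
    subject_id: str = "s0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.traces:
            ref = next(iter(self.traces.values()))
            for tr in self.traces.values():
                if abs(tr.t0 - ref.t0) > 1.0 / tr.fs:
                    raise ValueError("traces must share a start time")
                if abs(tr.duration - ref.duration) > max(1.0 / tr.fs, 1.0 / ref.fs):
                    raise ValueError("traces must share a duration")
        if self.truth is not None and len(self.truth) > 1:
            if not np.all(np.diff(self.truth["onset"].to_numpy()) > 0):
                raise ValueError("truth cycles must be in increasing time order")

    @property
    def duration(self) -> float:
        return next(iter(self.traces.values())).duration

    def trace(self, channel: str) -> Trace:
        if channel not in self.traces:
            raise KeyError(f"channel {channel!r} not in session")
        return self.traces[channel]
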