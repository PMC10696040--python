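"""Convenience plots: response time courses and triggered-average waveforms.

Requires matplotlib (``pip install phrenic[plot]``); nothing else in the
package depends on it.
"""

from __future__ import annotations

from .types import MetricTimeCourse, TriggeredAverage


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_timecourse(tc: MetricTimeCourse, injection_time: float,
                    baseline_dur: float = 100.0,
                    analysis_window: tuple[float, float] | None = None, ax=None):
    """Percent-of-baseline time course with the baseline and analysis
    windows shaded and the injection marked."""
    ax = _ax(ax)
    y = tc.percent if tc.percent is not None else tc.values
    ax.plot(tc.times, y, "-o", ms=2.5, lw=1)
    ax.axvspan(injection_time - baseline_dur, injection_time, alpha=0.12,
               color="tab:blue", label="baseline")
    if analysis_window is not None:
        ax.axvspan(injection_time + analysis_window[0],
                   injection_time + analysis_window[1], alpha=0.15,
                   color="gray", label="analysis window")
    ax.axvline(injection_time, color="k", lw=0.8, ls="--")
    if tc.percent is not None:
        ax.axhline(100.0, color="k", lw=0.5)
        ax.set_ylabel(f"{tc.metric} (% of baseline)")
    else:
        ax.set_ylabel(tc.metric)
    ax.set_xlabel("time (s)")
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_triggered_average(avg: TriggeredAverage, ax=None):
    """Averaged ∫ waveforms against lag from the burst-onset trigger."""
    ax = _ax(ax)
    for label, y in avg.mean_traces.items():
        ax.plot(avg.lag_axis, y, label=f"∫{label}")
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("lag from burst onset (s)")
    ax.set_ylabel("a.u.")
    ax.set_title(f"[{avg.window_start:.0f}, {avg.window_end:.0f}) s, "
                 f"n={avg.n_triggers}")
    ax.legend(loc="best", fontsize=8)
    return ax
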