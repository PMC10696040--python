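"""Phrenic-burst detection and respiratory-phase segmentation.

Definitions used throughout:

* Inspiration (Ti) runs from the onset of the phrenic burst to the onset of
  its sharp terminal decrease (the burst ``offset``).
* A respiratory cycle spans one inspiratory offset to the next
  (``Ttot = offset_{k+1} - offset_k``); Te is obtained by subtraction,
  ``Te = Ttot - Ti``.
* By default the Ti paired with a cycle is that of the inspiration
  *terminating* it (burst k+1), so Te is the expiratory pause the cycle
  actually contains; ``ti_assignment="opening"`` switches to the opening
  burst.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import INTEGRATED, BurstEvent, MetricTimeCourse, RespCycle, Trace

__all__ = ["BurstDetectionParams", "detect_bursts", "segment_cycles",
           "metric_timecourses"]

log = logging.getLogger(__name__)


@dataclass
class BurstDetectionParams:
    """Tunable burst-detection thresholds (all exposed, defaults documented).

    ``k_on``: onset threshold in robust SDs above the rolling baseline.
    ``min_dur``: minimum supra-threshold duration for a burst (s).
    ``d_frac``: the burst offset is the first time the trace derivative falls
    below ``-d_frac * (peak - baseline) / Ti_est`` — the start of the steep
    terminal fall.
    ``refractory_frac``: runs closer than this fraction of the median
    burst-to-burst interval are merged.
    ``baseline_quantile`` / ``baseline_block``: the rolling baseline is the
    per-block low quantile of the trace, linearly interpolated.
    """

    k_on: float = 3.0
    min_dur: float = 0.1
    d_frac: float = 0.5
    refractory_frac: float = 0.3
    baseline_quantile: float = 0.2
    baseline_block: float = 5.0


def _rolling_baseline(x: np.ndarray, fs: float, q: float, block: float) -> np.ndarray:
    """Low-quantile baseline per block, interpolated back to the sample grid."""
    nb = max(int(round(block * fs)), 1)
    n = x.size
    edges = np.arange(0, n, nb)
    centers = np.minimum(edges + nb / 2.0, n - 1.0)
    levels = np.array([np.quantile(x[s:min(s + nb, n)], q) for s in edges])
    if levels.size == 1:
        return np.full(n, levels[0])
    return np.interp(np.arange(n), centers, levels)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs where mask is True."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def detect_bursts(ipna: Trace, params: BurstDetectionParams | None = None) -> list[BurstEvent]:
    """Detect inspiratory bursts on an integrated phrenic trace.

    Onset is an upward crossing of ``baseline + k_on * noiseSD`` sustained
    for ``min_dur``; peak is the maximum between onset and offset; offset is
    the start of the steep terminal fall located by the derivative
    criterion.  A trace with no crossings yields an empty list.
    """
    if ipna.kind != INTEGRATED:
        raise TypeError("detect_bursts expects an integrated trace")
    if params is None:
        params = BurstDetectionParams()
    x = ipna.samples
    fs = ipna.fs
    n = x.size
    if n == 0:
        return []

    base = _rolling_baseline(x, fs, params.baseline_quantile, params.baseline_block)
    resid = x - base
    med = np.median(resid)
    sigma = 1.4826 * np.median(np.abs(resid - med))
    # floor for noise-free records: a sliver of the dynamic range
    sigma = max(sigma, 1e-3 * max(np.ptp(x), 1e-300), 1e-300)
    mask = x > base + params.k_on * sigma

    min_len = max(int(round(params.min_dur * fs)), 1)
    runs = [(s, e) for s, e in _runs_above(mask) if e - s >= min_len]
    if not runs:
        return []

    # merge runs closer than the refractory period
    if len(runs) > 1:
        onsets = np.array([s for s, _ in runs])
        med_int = np.median(np.diff(onsets)) if len(onsets) > 1 else n
        refractory = params.refractory_frac * med_int
        merged = [list(runs[0])]
        for s, e in runs[1:]:
            if s - merged[-1][1] < refractory:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        runs = [tuple(r) for r in merged]

    bursts: list[BurstEvent] = []
    for j, (s, e) in enumerate(runs):
        search_end = runs[j + 1][0] if j + 1 < len(runs) else n
        seg = x[s:search_end]
        peak_rel = int(np.argmax(seg[: max(e - s, 1)]))
        peak_idx = s + peak_rel
        peak_amp = x[peak_idx]
        base_amp = max(base[s], 0.0)
        ti_est = (e - s) / fs
        d_thresh = -params.d_frac * (peak_amp - base_amp) / max(ti_est, 1.0 / fs)
        deriv = np.gradient(seg) * fs
        after = deriv[peak_rel:]
        below = np.flatnonzero(after < d_thresh)
        off_idx = peak_idx + int(below[0]) if below.size else e - 1
        off_idx = max(off_idx, s + 1)
        peak_idx = min(peak_idx, off_idx)
        if peak_idx <= s:
            peak_idx = s + 1
        bursts.append(
            BurstEvent(
                onset=ipna.t0 + s / fs,
                peak_time=ipna.t0 + peak_idx / fs,
                offset=ipna.t0 + off_idx / fs,
                peak_amp=float(peak_amp),
                baseline_amp=float(base_amp),
            )
        )
    return bursts


def segment_cycles(bursts: list[BurstEvent], fs: float,
                   ti_assignment: str = "terminating") -> list[RespCycle]:
    """Offset-to-offset respiratory cycles from consecutive bursts.

    Cycles with a negative expiratory duration (overlapping bursts) are
    logged and excluded, never silently dropped.
    """
    if ti_assignment not in ("terminating", "opening"):
        raise ValueError("ti_assignment must be 'terminating' or 'opening'")
    if len(bursts) < 2:
        return []
    cycles: list[RespCycle] = []
    dropped = 0
    for k in range(len(bursts) - 1):
        b0, b1 = bursts[k], bursts[k + 1]
        ttot = b1.offset - b0.offset
        ti_burst = b1 if ti_assignment == "terminating" else b0
        ti = ti_burst.duration
        te = ttot - ti
        if te < 0 or ttot <= 0 or not (0 < ti / ttot < 1):
            dropped += 1
            continue
        cycles.append(
            RespCycle(
                Ti=ti, Te=te, Ttot=ttot, ratio=ti / ttot, f_inst=60.0 / ttot,
                t_ref=b1.offset,
                amp_pna=ti_burst.peak_amp - ti_burst.baseline_amp,
            )
        )
    if dropped:
        log.warning("segment_cycles: excluded %d cycle(s) with negative Te", dropped)
    return cycles


def metric_timecourses(cycles: list[RespCycle], step: float = 10.0,
                       duration: float | None = None,
                       freq_mode: str = "mean_ttot") -> dict[str, MetricTimeCourse]:
    """Bin per-cycle metrics onto the common 10-s grid.

    Each cycle contributes to the bin containing its reference time (the
    terminating inspiratory offset).  Frequency is ``60 / mean(Ttot)`` per
    bin by default (cycles per minute); ``freq_mode="count"`` uses the
    cycle count scaled to per-minute instead.  Empty bins are NaN gaps.
    """
    if not cycles:
        raise ValueError("need at least one cycle")
    if freq_mode not in ("mean_ttot", "count"):
        raise ValueError("freq_mode must be 'mean_ttot' or 'count'")
    t_ref = np.array([c.t_ref for c in cycles])
    if duration is None:
        duration = float(t_ref.max()) + step
    n_bins = int(np.ceil(duration / step))
    idx = np.floor(t_ref / step).astype(int)
    ok = (idx >= 0) & (idx < n_bins)
    idx = idx[ok]
    counts = np.bincount(idx, minlength=n_bins).astype(float)

    def binmean(vals: np.ndarray) -> np.ndarray:
        sums = np.bincount(idx, weights=vals[ok], minlength=n_bins)
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    ttot = np.array([c.Ttot for c in cycles])
    out_vals = {
        "Ti": binmean(np.array([c.Ti for c in cycles])),
        "Te": binmean(np.array([c.Te for c in cycles])),
        "ratio": binmean(np.array([c.ratio for c in cycles])),
        "amp_PNA_cycle": binmean(np.array([c.amp_pna for c in cycles])),
    }
    if freq_mode == "mean_ttot":
        mean_ttot = binmean(ttot)
        with np.errstate(invalid="ignore", divide="ignore"):
            out_vals["f"] = np.where(np.isfinite(mean_ttot), 60.0 / mean_ttot, np.nan)
    else:
        out_vals["f"] = np.where(counts > 0, counts * 60.0 / step, np.nan)

    centers = (np.arange(n_bins) + 0.5) * step
    return {m: MetricTimeCourse(m, centers, v) for m, v in out_vals.items()}
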