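"""End-to-end orchestration: simulate/load -> condition -> detect -> average
-> respond -> group statistics, with serialisable configuration and a run
manifest for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conditioning import detect_r_peaks, heart_rate, integrate
from .cycles import BurstDetectionParams, detect_bursts, metric_timecourses, segment_cycles
from .response import RMANOVAResult, change_rate, one_sample_t, percent_of_baseline, rm_anova_dunnett
from .synthgen import SynthConfig, simulate_cohort
from .trigavg import amplitude_from_average, postinsp_vna_amplitude, triggered_average
from .types import DrugProtocol, EventSeries, MetricTimeCourse, RecordingSession

log = logging.getLogger(__name__)

#: metrics carried through the response stage
RESPONSE_METRICS = ("amp_PNA", "amp_postinsp_VNA", "f", "Ti", "Te", "ratio", "HR")


@dataclass
class PipelineConfig:
    """Everything needed to rerun an analysis identically.

    ``analysis_window`` is relative to the injection time and corresponds to
    the shaded region over which change rates are averaged.
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    protocol: DrugProtocol = field(
        default_factory=lambda: DrugProtocol("BotC", "vehicle", [300.0])
    )
    detection: BurstDetectionParams = field(default_factory=BurstDetectionParams)
    n_subjects: int = 3
    seed: int = 0
    integrate_window: float = 0.05
    trig_window: float = 20.0
    trig_step: float = 10.0
    lag_pre: float = 1.0
    lag_post: Optional[float] = None  # default: 1.5 * median Ttot
    baseline_dur: float = 100.0
    analysis_window: tuple[float, float] = (60.0, 180.0)
    step: float = 10.0
    ti_assignment: str = "terminating"
    freq_mode: str = "mean_ttot"
    # Dunnett matrix span relative to the injection: control = last
    # pre-injection bin inside the span
    dunnett_span: tuple[float, float] = (-60.0, 300.0)

    def __post_init__(self) -> None:
        if self.baseline_dur <= 0:
            raise ValueError("baseline_dur must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.trig_window <= 0 or self.trig_step <= 0 or self.step <= 0:
            raise ValueError("window/step parameters must be positive")
        w0, w1 = self.analysis_window
        if w1 <= w0 or w0 < 0:
            raise ValueError("analysis_window must be a positive-length post-injection interval")

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analysis_window"] = list(self.analysis_window)
        d["dunnett_span"] = list(self.dunnett_span)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synth" in d:
            d["synth"] = SynthConfig(**d["synth"])
        if "protocol" in d:
            d["protocol"] = DrugProtocol(**d["protocol"])
        if "detection" in d:
            d["detection"] = BurstDetectionParams(**d["detection"])
        if "analysis_window" in d:
            d["analysis_window"] = tuple(d["analysis_window"])
        if "dunnett_span" in d:
            d["dunnett_span"] = tuple(d["dunnett_span"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SubjectResult:
    """Per-subject pipeline output."""

    subject_id: str
    cycles: pd.DataFrame
    timecourses: dict[str, MetricTimeCourse]
    change_rates: dict[str, float]
    n_bursts: int
    injection_time: float
    analysis_window: tuple[float, float]


def analyze_session(session: RecordingSession, cfg: PipelineConfig) -> SubjectResult:
    """Run conditioning, burst detection, triggered averaging and the
    percent-of-baseline response analysis on one session."""
    if "injection" not in session.events or len(session.events["injection"]) == 0:
        raise ValueError("session has no injection events; response analysis "
                         "requires at least one")
    t_inj = float(session.events["injection"].times[0])
    duration = session.duration

    ipna = integrate(session.trace("PNA"), cfg.integrate_window)
    ivna = integrate(session.trace("VNA"), cfg.integrate_window)

    bursts = detect_bursts(ipna, cfg.detection)
    if len(bursts) < 2:
        raise ValueError("fewer than two bursts detected; cannot segment cycles")
    cycles = segment_cycles(bursts, ipna.fs, cfg.ti_assignment)
    tcs = metric_timecourses(cycles, cfg.step, duration=duration,
                             freq_mode=cfg.freq_mode)

    med_ti = float(np.median([c.Ti for c in cycles]))
    med_te = float(np.median([c.Te for c in cycles]))
    med_ttot = float(np.median([c.Ttot for c in cycles]))
    lag_post = cfg.lag_post if cfg.lag_post is not None else 1.5 * med_ttot

    onsets = EventSeries("burst_onset", np.array([b.onset for b in bursts]))
    avgs = triggered_average({"PNA": ipna, "VNA": ivna}, onsets,
                             window=cfg.trig_window, step=cfg.trig_step,
                             lag_range=(-cfg.lag_pre, lag_post))
    amp_times, amp_pna, amp_vna = [], [], []
    for avg in avgs:
        amp_times.append(avg.center)
        amp_pna.append(amplitude_from_average(avg, "PNA",
                                              burst_interval=(0.0, 2.0 * med_ti)))
        amp_vna.append(postinsp_vna_amplitude(avg, pna_offset_lag=med_ti,
                                              w_pi=0.5 * med_te))
    tcs["amp_PNA"] = MetricTimeCourse("amp_PNA", np.array(amp_times), np.array(amp_pna))
    tcs["amp_postinsp_VNA"] = MetricTimeCourse("amp_postinsp_VNA",
                                               np.array(amp_times), np.array(amp_vna))

    if "ECG" in session.traces:
        rpeaks = detect_r_peaks(session.trace("ECG"))
        if len(rpeaks) >= 2:
            tcs["HR"] = heart_rate(rpeaks, cfg.step, duration=duration)

    change_rates: dict[str, float] = {}
    for name in RESPONSE_METRICS:
        if name not in tcs:
            continue
        tcs[name] = percent_of_baseline(tcs[name], t_inj, cfg.baseline_dur)
        change_rates[name] = change_rate(tcs[name], cfg.analysis_window, t_inj)

    cyc_df = pd.DataFrame(
        [dict(t_ref=c.t_ref, Ti=c.Ti, Te=c.Te, Ttot=c.Ttot, ratio=c.ratio,
              f_inst=c.f_inst, amp_pna=c.amp_pna) for c in cycles]
    )
    return SubjectResult(session.subject_id, cyc_df, tcs, change_rates,
                         len(bursts), t_inj, cfg.analysis_window)


def group_change_stats(results: Sequence[SubjectResult],
                       metrics: Sequence[str] = RESPONSE_METRICS) -> dict:
    """One-sample t vs 100 % on per-subject change rates, per metric."""
    out = {}
    for m in metrics:
        vals = [r.change_rates[m] for r in results if m in r.change_rates]
        if len(vals) >= 2:
            out[m] = one_sample_t(vals, 100.0, metric=m)
    return out


def group_timecourse_matrix(results: Sequence[SubjectResult], metric: str
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-subject percent time courses onto the shared grid."""
    n_t = min(len(r.timecourses[metric].times) for r in results)
    times = results[0].timecourses[metric].times[:n_t]
    mat = np.vstack([r.timecourses[metric].percent[:n_t] for r in results])
    return times, mat


def group_dunnett(results: Sequence[SubjectResult], metric: str,
                  span: tuple[float, float] = (-60.0, 300.0)
                  ) -> tuple[np.ndarray, RMANOVAResult]:
    """RM-ANOVA + Dunnett vs the last pre-injection timepoint for one metric.

    ``span`` limits the tested timepoints to an interval around the
    injection so the comparison family matches the displayed time course.
    """
    times, mat = group_timecourse_matrix(results, metric)
    t_inj = results[0].injection_time
    keep = (times >= t_inj + span[0]) & (times < t_inj + span[1])
    times, mat = times[keep], mat[:, keep]
    pre = np.flatnonzero(times < t_inj)
    if pre.size == 0:
        raise ValueError("no pre-injection timepoint available as control")
    control = int(pre[-1])
    res = rm_anova_dunnett(mat, control_index=control, metric=metric)
    return times, res


def run_pipeline(cfg: PipelineConfig, sessions: Optional[Sequence[RecordingSession]] = None,
                 outdir=None) -> dict:
    """Run the whole analysis; optionally write tables and a manifest.

    Returns a bundle with per-subject results, group statistics and the
    Dunnett tables.  Deterministic given (config, seed, inputs): rerunning
    writes byte-identical tables.
    """
    if sessions is None:
        synth = dataclasses.replace(cfg.synth, seed=cfg.seed)
        sessions = simulate_cohort(cfg.n_subjects, synth, cfg.protocol)
    results = [analyze_session(s, cfg) for s in sessions]
    stats = group_change_stats(results)
    dunnett = {}
    for m in ("amp_PNA", "f", "Ti", "Te", "ratio"):
        if all(m in r.timecourses for r in results) and len(results) >= 2:
            dunnett[m] = group_dunnett(results, m, span=cfg.dunnett_span)

    bundle = {"results": results, "group_stats": stats, "dunnett": dunnett,
              "config": cfg}
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg: PipelineConfig = bundle["config"]
    results: list[SubjectResult] = bundle["results"]

    for r in results:
        r.cycles.to_csv(outdir / f"cycles_{r.subject_id}.csv", index=False,
                        float_format="%.10g")

    rows = []
    for r in results:
        for m, tc in r.timecourses.items():
            for i in range(tc.times.size):
                rows.append(dict(subject=r.subject_id, metric=m,
                                 time=tc.times[i], value=tc.values[i],
                                 percent=(tc.percent[i] if tc.percent is not None
                                          else np.nan)))
    pd.DataFrame(rows).to_csv(outdir / "timecourses.csv", index=False,
                              float_format="%.10g")

    pd.DataFrame(
        [dict(subject=r.subject_id, metric=m, change_rate=v)
         for r in results for m, v in r.change_rates.items()]
    ).to_csv(outdir / "change_rates.csv", index=False, float_format="%.10g")

    pd.DataFrame(
        [dict(metric=m, n=g.n, mean=g.mean, sem=g.sem, test=g.test,
              statistic=g.statistic, pvalue=g.pvalue, significant=g.significant)
         for m, g in bundle["group_stats"].items()]
    ).to_csv(outdir / "group_stats.csv", index=False, float_format="%.10g")

    drows = []
    for m, (times, res) in bundle["dunnett"].items():
        non_control = [i for i in range(len(times)) if i != res.control_index]
        for i, g in zip(non_control, res.timepoints):
            drows.append(dict(metric=m, time=times[i], mean=g.mean, sem=g.sem,
                              statistic=g.statistic, pvalue=g.pvalue,
                              significant=g.significant, F=res.F,
                              anova_p=res.pvalue))
    pd.DataFrame(drows).to_csv(outdir / "dunnett.csv", index=False,
                               float_format="%.10g")

    manifest = {
        "package": "phrenic",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "n_subjects": len(results),
        "n_bursts": {r.subject_id: r.n_bursts for r in results},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    cfg.to_yaml(outdir / "config.yaml")
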