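"""Synthetic phrenic/vagus/ECG session generator with ground truth.

Emulates the nerve output of an arterially perfused in situ rodent
preparation: rhythmic inspiratory phrenic bursts with an augmenting envelope
terminated by an abrupt fall, vagal activity carrying an inspiratory plus a
decrementing post-inspiratory component, an R-wave train for heart rate, and
a slowly varying perfusion pressure.  A microinjected drug acts as
multiplicative modifiers on burst amplitude and on the inspiratory and
expiratory durations, weighted by a rise-and-recover temporal kernel.

The multiunit character of nerve recordings is emulated as
amplitude-modulated Gaussian noise, ``raw = envelope * N(0,1) +
noise_floor * N(0,1)``, so that rectification followed by a moving average
recovers the envelope up to the known factor E|N(0,1)| = sqrt(2/pi).  For
analytically exact tests ``carrier_mode="envelope"`` emits the noiseless
envelope itself.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import DrugProtocol, EventSeries, RecordingSession, Trace

__all__ = ["SynthConfig", "effect_kernel", "simulate_subject", "simulate_cohort"]

#: hard cap on the session length a single call will generate (s)
MAX_DURATION = 7200.0

#: fraction of the peak at which the augmenting phrenic ramp starts
RAMP_START_FRAC = 0.3

#: post-inspiratory VNA decay time constant, as a fraction of Te0
POSTINSP_TAU_FRAC = 0.4


@dataclass
class SynthConfig:
    """Ground-truth parameters of a synthetic recording.

    Baseline respiratory timing defaults (Ti0 = 0.9 s, Te0 = 3.2 s) give an
    inspiratory ratio of 0.22 and ~14.6 cycles/min, typical of eupnoea-like
    output in the perfused preparation.  ``m_amp``, ``m_Ti`` and ``m_Te``
    are the drug-effect multipliers at peak effect; ``m_* = 1`` everywhere
    is a null (vehicle-like) protocol.  The effect rises linearly over
    ``t_peak`` seconds and recovers exponentially with time constant
    ``tau_rec`` (defaults: peak at 2 min, < 5 % residual by 10 min).
    """

    fs: float = 500.0          # sampling rate, Hz
    Ti0: float = 0.9           # baseline inspiratory duration, s
    Te0: float = 3.2           # baseline expiratory duration, s
    ampPNA0: float = 1.0       # phrenic burst envelope scale, a.u.
    ampVNA0: float = 1.0       # vagal inspiratory envelope scale, a.u.
    postinsp_frac: float = 0.6  # post-inspiratory VNA scale relative to ampVNA0
    cv_cycle: float = 0.03     # cycle-to-cycle CV of Ti, Te
    cv_subject: float = 0.08   # between-subject CV of baseline parameters
    noise_floor: float = 0.02  # tonic noise SD, a.u.
    hr0: float = 320.0         # baseline heart rate, beats/min
    m_amp: float = 1.0         # amplitude multiplier at peak effect
    m_Ti: float = 1.0          # inspiratory-duration multiplier at peak
    m_Te: float = 1.0          # expiratory-duration multiplier at peak
    t_peak: float = 120.0      # time to peak effect, s
    tau_rec: float = 150.0     # recovery time constant, s
    seed: int = 0
    carrier_mode: str = "am-noise"  # "am-noise" | "envelope" (noise-free)

    def __post_init__(self) -> None:
        for name in ("fs", "Ti0", "Te0", "ampPNA0", "ampVNA0", "hr0",
                     "m_amp", "m_Ti", "m_Te", "t_peak", "tau_rec"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cv_cycle", "cv_subject", "noise_floor", "postinsp_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.carrier_mode not in ("am-noise", "envelope"):
            raise ValueError(f"unknown carrier_mode {self.carrier_mode!r}")

    @property
    def is_null(self) -> bool:
        return self.m_amp == self.m_Ti == self.m_Te == 1.0


def effect_kernel(t_since_injection, t_peak: float, tau_rec: float):
    """Drug-effect weight w(t) in [0, 1].

    Zero before the injection, linear rise to 1 at ``t_peak``, exponential
    recovery with time constant ``tau_rec`` afterwards.  The applied
    multiplier at time t is ``1 + w(t) * (m - 1)``.
    """
    if t_peak <= 0:
        raise ValueError("t_peak must be positive")
    if tau_rec <= 0:
        raise ValueError("tau_rec must be positive")
    t = np.asarray(t_since_injection, dtype=float)
    w = np.where(
        t <= 0,
        0.0,
        np.where(t <= t_peak, t / t_peak, np.exp(-(np.maximum(t, t_peak) - t_peak) / tau_rec)),
    )
    if np.isscalar(t_since_injection):
        return float(w)
    return w


def _weight_at(t: float, protocol: DrugProtocol, cfg: SynthConfig) -> float:
    """Combined effect weight at absolute session time t (max over injections)."""
    if cfg.is_null:
        return 0.0
    w = 0.0
    for t_inj in protocol.injection_times:
        w = max(w, effect_kernel(t - t_inj, cfg.t_peak, cfg.tau_rec))
    return w


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Lognormal draw with the requested arithmetic mean and CV (exact at cv=0)."""
    if cv == 0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def simulate_subject(config: SynthConfig, protocol: DrugProtocol) -> RecordingSession:
    """Generate one synthetic session, cycle by cycle, with a truth table.

    Fully reproducible from ``config.seed``: two calls with identical
    arguments return bit-identical arrays.
    """
    duration = protocol.duration
    if duration > MAX_DURATION:
        raise ValueError(f"protocol duration {duration:.0f} s exceeds {MAX_DURATION:.0f} s")
    fs = config.fs
    n = int(round(duration * fs))
    rng = np.random.default_rng(config.seed)

    # --- cycle sequence -------------------------------------------------
    rows = []
    # open with a partial expiration so the first burst is not at t = 0
    t = 0.5 * config.Te0
    while True:
        w = _weight_at(t, protocol, config)
        mult_amp = 1.0 + w * (config.m_amp - 1.0)
        Ti = _lognormal(rng, config.Ti0 * (1.0 + w * (config.m_Ti - 1.0)), config.cv_cycle)
        Te = _lognormal(rng, config.Te0 * (1.0 + w * (config.m_Te - 1.0)), config.cv_cycle)
        # keep a margin so the trailing expiration fits in the record
        if t + Ti + Te > duration - 1.0 / fs:
            break
        amp = config.ampPNA0 * mult_amp
        amp_vna = config.ampVNA0 * mult_amp
        amp_pi = config.postinsp_frac * config.ampVNA0 * mult_amp
        rows.append(
            dict(onset=t, offset=t + Ti, Ti=Ti, Te=Te,
                 amp_pna=amp, amp_vna=amp_vna, amp_vna_postinsp=amp_pi, weight=w)
        )
        t += Ti + Te
    truth = pd.DataFrame(rows)

    # --- nerve envelopes ------------------------------------------------
    env_pna = np.zeros(n)
    env_vna = np.zeros(n)
    tau_pi = POSTINSP_TAU_FRAC * config.Te0
    for r in rows:
        i0 = int(round(r["onset"] * fs))
        i1 = int(round(r["offset"] * fs))
        i1 = min(max(i1, i0 + 1), n)
        ramp = RAMP_START_FRAC + (1.0 - RAMP_START_FRAC) * (
            np.arange(i1 - i0) / max(i1 - i0 - 1, 1)
        )
        env_pna[i0:i1] = r["amp_pna"] * ramp
        env_vna[i0:i1] = r["amp_vna"] * ramp
        # decrementing post-inspiratory component on VNA only
        i2 = min(int(round((r["offset"] + r["Te"]) * fs)), n)
        if i2 > i1:
            lag = np.arange(i2 - i1) / fs
            env_vna[i1:i2] += r["amp_vna_postinsp"] * np.exp(-lag / tau_pi)

    if config.carrier_mode == "envelope":
        pna = env_pna.copy()
        vna = env_vna.copy()
    else:
        pna = env_pna * rng.standard_normal(n) + config.noise_floor * rng.standard_normal(n)
        vna = env_vna * rng.standard_normal(n) + config.noise_floor * rng.standard_normal(n)

    # --- ECG: R-wave train with slight interval jitter ------------------
    rr0 = 60.0 / config.hr0
    n_beats = int(duration / rr0) + 8
    jitter = rng.standard_normal(n_beats) * 0.01 * rr0
    r_times = 0.5 * rr0 + np.arange(n_beats) * rr0 + jitter
    r_times = r_times[(r_times > 0) & (r_times < duration - 2.0 / fs)]
    ecg = 0.02 * rng.standard_normal(n)
    spike = np.array([0.15, 1.0, -0.35])  # crude biphasic R wave, 3 samples
    idx = np.round(r_times * fs).astype(int)
    for k, off in enumerate(range(-1, 2)):
        sel = idx + off
        ok = (sel >= 0) & (sel < n)
        ecg[sel[ok]] += spike[k]

    # --- perfusion pressure: slow oscillation, storage only -------------
    tt = np.arange(n) / fs
    pp = 70.0 + 3.0 * np.sin(2 * np.pi * tt / 60.0)

    traces = {
        "PNA": Trace("PNA", fs, pna),
        "VNA": Trace("VNA", fs, vna),
        "ECG": Trace("ECG", fs, ecg, units="mV"),
        "PP": Trace("PP", fs, pp, units="mmHg"),
    }
    events = {"injection": EventSeries("injection", np.asarray(protocol.injection_times))}
    return RecordingSession(
        traces=traces, events=events, protocol=protocol, truth=truth,
        meta={"config": dataclasses.asdict(config)},
    )


def _child_seed(master: int, subject: int, stream: int) -> int:
    """Deterministic per-subject seed derived from the master seed."""
    ss = np.random.SeedSequence(master, spawn_key=(subject, stream))
    return int(ss.generate_state(1)[0] % (2**31))


def derived_subject_config(config: SynthConfig, index: int) -> SynthConfig:
    """The jittered config simulate_cohort uses for subject ``index``."""
    jit = np.random.default_rng(_child_seed(config.seed, index, 0))
    if config.cv_subject > 0:
        sigma = np.sqrt(np.log1p(config.cv_subject**2))
        f = np.exp(jit.standard_normal(5) * sigma - 0.5 * sigma * sigma)
    else:
        f = np.ones(5)
    return dataclasses.replace(
        config,
        Ti0=config.Ti0 * f[0],
        Te0=config.Te0 * f[1],
        ampPNA0=config.ampPNA0 * f[2],
        ampVNA0=config.ampVNA0 * f[3],
        hr0=config.hr0 * f[4],
        seed=_child_seed(config.seed, index, 1),
    )


def simulate_cohort(n: int, config: SynthConfig, protocol: DrugProtocol) -> list[RecordingSession]:
    """Generate ``n`` subjects with baselines jittered by ``cv_subject``.

    Per-subject seeds derive deterministically from ``config.seed`` via
    ``numpy.random.SeedSequence(seed, spawn_key=(subject, stream))``; the
    cohort is order-stable and reproducible.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    sessions = []
    for i in range(n):
        cfg_i = derived_subject_config(config, i)
        sess = simulate_subject(cfg_i, protocol)
        sess.subject_id = f"s{i}"
        sessions.append(sess)
    return sessions
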