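"""Canned validation experiments on synthetic cohorts.

These are the package's reference study designs: a multiplier-recovery
cohort, a null-calibration study for the group tests, and the nine-fixture
direction regression.  Each is deterministic given its seed and returns
plain numbers, so the same entry points back both the test suite and the
reproduction script.

Problem sizes are deliberately modest (a few hundred seconds of signal at a
few hundred Hz per subject); the quantities under study — change rates in
percent of baseline, test rejection rates, response signs — are already
stable at these sizes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .pipeline import PipelineConfig, analyze_session, group_change_stats, group_dunnett, run_pipeline
from .protocols import DIRECTION_FIXTURES, DirectionFixture, expected_directions
from .response import one_sample_t
from .synthgen import SynthConfig, simulate_cohort
from .types import DrugProtocol

__all__ = ["recovery_experiment", "null_calibration", "direction_regression"]

#: analysis window bracketing the peak drug effect (the effect kernel's mean
#: weight over (100, 140) s post-injection is 0.93, so recovered change
#: rates approximate the injected peak multipliers)
PEAK_WINDOW = (100.0, 140.0)


def recovery_experiment(seed: int, n: int = 20, m_amp: float = 0.80,
                        m_Ti: float = 1.00, m_Te: float = 0.70) -> dict:
    """Inject known multipliers into an n-subject cohort and measure the
    group-mean change rates the pipeline recovers."""
    cfg = PipelineConfig(
        synth=SynthConfig(m_amp=m_amp, m_Ti=m_Ti, m_Te=m_Te),
        protocol=DrugProtocol("BotC", "HA", [300.0], pre_duration=300.0,
                              post_duration=400.0),
        n_subjects=n,
        seed=seed,
        analysis_window=PEAK_WINDOW,
    )
    bundle = run_pipeline(cfg)
    return {m: g for m, g in bundle["group_stats"].items()}


def _calibration_config(n_subjects: int) -> PipelineConfig:
    return PipelineConfig(
        synth=SynthConfig(fs=200.0),
        protocol=DrugProtocol("BotC", "vehicle", [150.0], pre_duration=150.0,
                              post_duration=250.0),
        n_subjects=n_subjects,
        seed=0,
        analysis_window=PEAK_WINDOW,
        dunnett_span=(-60.0, 200.0),
    )


def null_calibration(seed: int, n_reps: int = 500, n_subjects: int = 5,
                     metric: str = "amp_PNA") -> dict:
    """Rejection rates of the group tests under the null protocol (m_* = 1).

    Each replicate simulates a fresh cohort, runs the full pipeline, and
    applies (a) the one-sample t vs 100 % on change rates and (b) the
    RM-ANOVA + Dunnett family across timepoints.  Both should reject ~5 %
    of replicates at alpha = 0.05.
    """
    cfg = _calibration_config(n_subjects)
    rej_t = rej_fwe = 0
    base = int(seed) % (2**30)
    for rep in range(n_reps):
        synth = dataclasses.replace(cfg.synth, seed=base + rep)
        sessions = simulate_cohort(n_subjects, synth, cfg.protocol)
        results = [analyze_session(s, cfg) for s in sessions]
        g = group_change_stats(results, [metric])[metric]
        rej_t += int(g.significant)
        _, res = group_dunnett(results, metric, span=cfg.dunnett_span)
        rej_fwe += int(res.any_significant)
    return {
        "n_reps": n_reps,
        "t_rejection_rate": rej_t / n_reps,
        "dunnett_fwe": rej_fwe / n_reps,
    }


def _call_sign(stats) -> str:
    if stats.pvalue < 0.05:
        return "+" if stats.mean > 100.0 else "-"
    return "0"


def direction_regression(seed: int, n_subjects: int = 6) -> dict:
    """Run all nine site x agent fixtures and compare recovered response
    signs (+ / - / 0, with 0 meaning p >= 0.05) against the injected ones."""
    metrics = ("amp_PNA", "f", "Ti", "Te", "ratio")
    base = int(seed) % (2**30)
    details = []
    fixtures_ok = cells_ok = cells_total = 0
    for k, fx in enumerate(DIRECTION_FIXTURES):
        cfg = PipelineConfig(
            synth=SynthConfig(fs=250.0, m_amp=fx.m_amp, m_Ti=fx.m_Ti,
                              m_Te=fx.m_Te),
            protocol=DrugProtocol(fx.site, fx.agent, [300.0],
                                  pre_duration=300.0, post_duration=400.0),
            n_subjects=n_subjects,
            seed=base + 101 * k,
            analysis_window=PEAK_WINDOW,
        )
        bundle = run_pipeline(cfg)
        expected = expected_directions(fx)
        got = {m: _call_sign(bundle["group_stats"][m]) for m in metrics}
        match = {m: got[m] == expected[m] for m in metrics}
        cells_total += len(metrics)
        cells_ok += sum(match.values())
        fixtures_ok += int(all(match.values()))
        details.append(dict(site=fx.site, agent=fx.agent, expected=expected,
                            got=got))
    return {
        "fixtures_matched": fixtures_ok,
        "n_fixtures": len(DIRECTION_FIXTURES),
        "cells_matched": cells_ok,
        "n_cells": cells_total,
        "details": details,
    }
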