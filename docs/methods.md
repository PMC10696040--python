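# Methods

## The analysis problem

`phrenic` quantifies how a microinjected agent changes the respiratory
motor pattern recorded from peripheral nerves in an arterially perfused
(in situ) rodent preparation. The raw material is multiunit nerve activity:
the phrenic nerve (PNA) carries the inspiratory drive as rhythmic bursts
with an augmenting envelope and an abrupt termination; the central vagus
nerve (VNA) carries an inspiratory component plus a decrementing
*post-inspiratory* component that outlasts the phrenic burst. An ECG
channel provides heart rate, and perfusion pressure (PP) is stored for
display only.

The pipeline answers, per subject and per cohort: how did burst amplitude,
respiratory frequency, inspiratory duration (Ti), expiratory duration (Te)
and the inspiratory ratio Ti/Ttot change after an injection, expressed as a
percent of the pre-injection baseline, and are those changes statistically
reliable?

## Signal conditioning

Nerve channels are full-wave rectified and smoothed with a centered moving
average of 0.05 s, giving the integrated traces ∫PNA and ∫VNA. The window
is *centered* (a trailing window would bias every onset estimate late by
half a window, which would propagate into Ti and into trigger alignment)
and *shrinks at the record edges* (a mean over the available samples, so no
artificial zeros appear at the boundaries). The implementation is an exact
windowed mean — interior windows via a strided view with pairwise
summation, edge windows computed directly — and is tested against a
per-sample brute-force oracle at 1e-12 relative error.

An optional zero-phase Butterworth band-pass (default corners 100–5000 Hz,
order 4) is provided for real acquisitions; the synthetic generator
produces signals already in band, so the stage is off by default.

R waves are detected as local maxima above `k = 4` robust standard
deviations (1.4826·MAD) with a 0.15-s refractory period; heart rate is
60/RR assigned to the interval midpoint and averaged within 10-s bins.
These values are exposed in the configuration; they are algorithmic
defaults chosen for clean synthetic ECG, not physiological claims.

## Burst detection and phase segmentation

Inspiration is defined from the onset of the phrenic burst to the onset of
its sharp terminal decrease. On the integrated trace:

* **Baseline** — rolling low quantile (default q = 0.2 over 5-s blocks,
  linearly interpolated).
* **Onset** — upward crossing of `baseline + 3·robust SD` sustained for at
  least 0.1 s; supra-threshold runs closer than 0.3 of the median
  burst-to-burst interval are merged.
* **Offset ("onset of the sharp decrease")** — the first time after the
  peak at which the trace derivative falls below
  `−d_frac·(peak − baseline)/Ti_est` with `d_frac = 0.5`. For an
  augmenting burst that collapses abruptly this fires within one smoothing
  window of the true fall; the criterion is a stated operational choice,
  exposed as a parameter, since no published numeric rule exists.

A respiratory cycle spans one inspiratory offset to the next
(`Ttot = offset_{k+1} − offset_k`); Te is obtained by subtraction
(`Te = Ttot − Ti`). Which inspiration's Ti is paired with the cycle is
genuinely ambiguous under the offset-to-offset convention; the default
pairs the *terminating* inspiration (burst k+1), which makes Te exactly the
expiratory pause contained in the cycle, and `ti_assignment="opening"`
switches the convention. Cycles with negative Te (overlapping bursts) are
excluded with a logged warning, never silently.

Per-cycle metrics are binned onto a common 10-s grid. Respiratory
frequency is `60 / mean(Ttot)` per bin by default; a count-based
alternative (`cycles per bin × 6`) is available. Empty bins are NaN gaps —
never zeros — and gaps propagate through normalisation.

## Burst-triggered averaging

Averaged waveforms are computed in 20-s windows advanced in 10-s steps:
segments of ∫PNA and ∫VNA are extracted around each burst **onset** inside
the window (onset rather than peak, because the phase definitions are
onset-anchored) and averaged pointwise. The default lag span is
[−1 s, 1.5·median Ttot], enough to show one full cycle. Amplitude is read
from the averaged waveform: maximum inside the burst interval minus the
mean over a pre-trigger span (default [−0.5, −0.1] s, kept clear of the
preceding burst's tail). Post-inspiratory VNA amplitude is the maximum in
(offset_lag, offset_lag + 0.5·median Te] minus the VNA pre-trigger
baseline. Windows with no usable trigger yield gaps.

## Percent-of-baseline responses and statistics

The mean of each metric over the 100 s before the injection defines 100 %.
The *change rate* is the mean percent value over a post-injection analysis
window; the package default is [60, 180] s after injection, and the window
is configurable per experiment (it plays the role of the shaded analysis
region on a response plot, which legitimately differs between protocols).

Group inference (all two-sided, α = 0.05, results as mean ± SEM):

* **One-sample t vs 100 %** on per-subject change rates (closed form;
  zero-variance inputs are handled explicitly: t = 0, p = 1 when the mean
  equals the null, otherwise flagged degenerate with p reported as 0).
* **Paired t** between conditions, as a one-sample t on differences.
* **RM-ANOVA + Dunnett** across timepoints of the percent time course.
  The control is the last pre-injection bin on the 10-s grid. Contrasts
  use the within-subject error term,
  `t_j = (mean_j − mean_c)/sqrt(2·MS_err/n)`, df = (n−1)(k−1); subjects
  with gaps in the tested span are dropped listwise and logged. The
  multiplicity-adjusted p-value is `1 − P(max_i |T_i| ≤ |t_j|)` for the
  equicorrelated (ρ = ½) multivariate-t family. That probability is
  evaluated by exact 2-D quadrature using the factor representation
  `T_i = (Z_i + Z_0)/(√2·W)`, `W² = χ²_df/df` — an 80-node Gauss–Hermite
  rule over `Z_0` times an 80-node Gauss–Legendre rule over the χ²
  quantile — which is deterministic and accurate to ~1e-5. It reduces to
  the Student-t tail at m = 1 and is cross-checked against Monte-Carlo
  simulation in the tests. The tested timepoint span defaults to
  [−60, +300] s around the injection so the comparison family matches the
  displayed time course. No correction is applied *across* metrics.

The whole response stage is invariant to rescaling raw amplitudes by any
positive constant, so the arbitrary units of nerve recordings never matter.

## The synthetic generator

Because no raw recordings are available, the generator is a first-class,
tested module that defines the study conditions:

* **Cycle timing** — Ti and Te drawn independently and lognormally around
  their current targets with cycle-to-cycle CV 0.03; baselines Ti0 = 0.9 s,
  Te0 = 3.2 s give an inspiratory ratio of 0.22 and ~14.6 cycles/min,
  typical of eupnoea-like output in this preparation.
* **Envelopes** — PNA: linear augmenting ramp from 0.3 to 1.0 of the burst
  scale over Ti, instantaneous fall. VNA: the same inspiratory ramp plus a
  post-inspiratory exponential (initial height 0.6 of the VNA scale, time
  constant 0.4·Te0) starting at the phrenic offset.
* **Multiunit character** — `raw = envelope·N(0,1) + noise_floor·N(0,1)`.
  This amplitude-modulated-noise model is chosen because rectification and
  smoothing then recover the envelope up to the known constant
  E|N(0,1)| = √(2/π), making amplitude recovery analytically checkable.
  `carrier_mode="envelope"` instead emits the noise-free envelope itself;
  the deterministic tests (sub-window onset/offset recovery) use this mode,
  since a stochastic carrier keeps ~10 % fluctuation in the integrated
  trace even with `noise_floor = 0`.
* **Drug effect** — a weight w(t) that is 0 at injection, rises linearly
  to 1 at t_peak = 120 s and recovers as exp(−(t−t_peak)/150 s) (<5 %
  residual by 10 min). Every affected quantity is multiplied by
  `1 + w(t)·(m − 1)` with peak multipliers `m_amp`, `m_Ti`, `m_Te`;
  `m_* = 1` is a vehicle-like null. The exact kernel shape is a modelling
  choice; only its timing (peak ~2 min, recovery <10 min) is anchored.
* **ECG / PP** — an R-wave train at 320 beats/min with 1 % RR jitter; PP
  is a slow 70 ± 3 mmHg oscillation, stored but not analysed.
* **Cohorts** — per-subject baselines jittered lognormally with
  between-subject CV 0.08; per-subject seeds derive deterministically from
  the master seed via `SeedSequence(seed, spawn_key=(subject, stream))`,
  so cohorts are order-stable and bit-reproducible.

What the generator does **not** emulate: unit recruitment and
rate-coding structure within bursts, baroreceptor/cardiorespiratory
coupling, slow drift or electrode artefacts, apnoeas and sighs, and any
site-specific circuit mechanism — drug action is imposed
phenomenologically as multipliers. Passing tests therefore demonstrate
that the *analysis chain* is correct and calibrated under realistic
amplitudes, rhythms and noise; they are not evidence about biology.

## Reference experiments and problem sizes

`phrenic.experiments` fixes three canned designs used by the tests and the
reproduction script:

* **Recovery** — n = 20 subjects, injection at 300 s, multipliers
  (0.80, 1.00, 0.70). The change-rate window here is (100, 140) s
  post-injection, bracketing the kernel peak: the kernel's mean weight over
  that window is 0.93, so measured change rates approximate the injected
  peak multipliers. (Over the wider default window [60, 180] s the mean
  weight is only 0.79, which caps recovered changes at ~79 % of the
  injected effect by construction — a property of time-averaging a
  transient, not a measurement error.)
* **Null calibration** — 500 cohorts of n = 5 at fs = 200 Hz, 400-s
  sessions; rejection rates of the one-sample t and of the Dunnett family
  should sit at the nominal 5 %.
* **Direction regression** — nine fixtures (three medullary sites × three
  agents) whose multipliers encode the expected response directions;
  recovered signs (+/−/0, with 0 ⇔ p ≥ 0.05) must match the injected ones.

Session lengths, sampling rates and replicate counts in these designs are
the package's chosen study sizes; the measured quantities are stable well
below these sizes.

## Known limitations

* The burst-offset rule is one reasonable operationalisation of "onset of
  the sharp decrease"; bursts that decay gradually (no sharp fall) will
  take the end of the supra-threshold run as offset.
* The Dunnett adjustment assumes compound symmetry across timepoints
  (exact for the equicorrelated contrast family); strongly non-spherical
  real data would call for a corrected error term.
* Frequency from `60/mean(Ttot)` is undefined in bins without cycles
  (gaps), and very long cycles spanning several bins register only in the
  bin containing their terminal offset.
* Heart-rate analysis assumes clean R waves; no arrhythmia handling.
* Percent-of-baseline requires a non-zero, stationary baseline; the
  pipeline refuses records without a usable baseline window rather than
  guessing.
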