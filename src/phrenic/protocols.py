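"""Shipped site x agent effect fixtures and expected response directions.

Each fixture encodes, as peak-effect multipliers, the qualitative action of
one agent at one medullary site on the respiratory pattern:

* HA (hydroxylamine, H2S-synthesis inhibition) at the BötC shortens
  expiration and raises frequency; at the preBötC it shortens both phases;
  at the rVRG it lengthens expiration and slows the rhythm.  All sites show
  a reduced inspiratory burst.
* KYN (kynurenic acid, excitatory blockade) acts like a stronger HA at the
  BötC/preBötC; at the rVRG it only attenuates the burst amplitude.
* B+S (bicuculline + strychnine, inhibitory blockade) leaves timing
  unchanged at the BötC/preBötC but attenuates the burst; at the rVRG it
  shortens expiration and accelerates the rhythm.

``expected_directions`` derives the implied sign for every reported metric
directly from the multipliers ("0" = no injected change), so regression
tests compare pipeline output against the injected truth.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DirectionFixture", "DIRECTION_FIXTURES", "expected_directions"]


@dataclass(frozen=True)
class DirectionFixture:
    site: str
    agent: str
    m_amp: float
    m_Ti: float
    m_Te: float


DIRECTION_FIXTURES: tuple[DirectionFixture, ...] = (
    DirectionFixture("BotC",    "HA",  0.80, 1.00, 0.65),
    DirectionFixture("preBotC", "HA",  0.80, 0.85, 0.78),
    DirectionFixture("rVRG",    "HA",  0.85, 0.88, 1.30),
    DirectionFixture("BotC",    "KYN", 0.55, 0.70, 0.40),
    DirectionFixture("preBotC", "KYN", 0.65, 0.82, 0.60),
    DirectionFixture("rVRG",    "KYN", 0.60, 1.00, 1.00),
    DirectionFixture("BotC",    "B+S", 0.85, 1.00, 1.00),
    DirectionFixture("preBotC", "B+S", 0.85, 1.00, 1.00),
    DirectionFixture("rVRG",    "B+S", 0.75, 1.00, 0.65),
)


def _sign(x: float, tol: float = 1e-9) -> str:
    if x > tol:
        return "+"
    if x < -tol:
        return "-"
    return "0"


def expected_directions(fx: DirectionFixture, Ti0: float = 0.9,
                        Te0: float = 3.2) -> dict[str, str]:
    """Metric signs implied by the injected multipliers at peak effect.

    Frequency and inspiratory-ratio directions follow from the timing
    algebra: f ∝ 1/(Ti0*m_Ti + Te0*m_Te), ratio = Ti/(Ti+Te).
    """
    ti, te = Ti0 * fx.m_Ti, Te0 * fx.m_Te
    ratio0 = Ti0 / (Ti0 + Te0)
    return {
        "amp_PNA": _sign(fx.m_amp - 1.0),
        "Ti": _sign(fx.m_Ti - 1.0),
        "Te": _sign(fx.m_Te - 1.0),
        "f": _sign((Ti0 + Te0) - (ti + te)),
        "ratio": _sign(ti / (ti + te) - ratio0),
    }
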