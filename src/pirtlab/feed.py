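"""Mixing-vessel feed dynamics for retentostat cultivation.

A level-controlled mixing vessel of working volume ``V_S`` sits between
the medium reservoir and the bioreactor.  At the retentostat switch
(t = 0) the reservoir is exchanged for one with a lower glucose
concentration, so the glucose concentration entering the bioreactor
washes out of the mixing vessel exponentially:

    C_S,in(t) = (C_S,MC - C_S,MR) * exp(-phi_V t / V_S) + C_S,MR

with ``C_S,MC`` / ``C_S,MR`` the reservoir glucose concentrations during
the chemostat and retentostat phases and ``phi_V`` the constant flow
rate.  The chemostat phase (t < 0) corresponds to constant feed at
``C_S,MC``; the vessel is treated as ideally mixed at constant volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MixingVesselFeed", "feed_concentration", "substrate_supplied"]


@dataclass(frozen=True)
class MixingVesselFeed:
    """Mixing-vessel geometry and reservoir glucose concentrations.

    Defaults are the retentostat setup used throughout the package:
    V_S = 1.2 L, phi_V = 0.035 L/h, 10 g/L -> 5 g/L reservoir swap.
    """

    V_S: float = 1.2
    phi_V: float = 0.035
    C_S_MC: float = 10.0
    C_S_MR: float = 5.0

    def __post_init__(self) -> None:
        if self.V_S <= 0:
            raise ValueError("V_S must be > 0")
        if self.phi_V <= 0:
            raise ValueError("phi_V must be > 0")
        if not (self.C_S_MC >= self.C_S_MR >= 0):
            raise ValueError("require C_S_MC >= C_S_MR >= 0")


def feed_concentration(t, feed: MixingVesselFeed):
    """Feed glucose concentration C_S,in(t) in g/L at time t >= 0 (hours).

    Monotone non-increasing, decaying from C_S,MC at t = 0 towards the
    asymptote C_S,MR.
    """
    scalar = np.isscalar(t)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0 (t = 0 is the reservoir switch)")
    c = (feed.C_S_MC - feed.C_S_MR) * np.exp(-feed.phi_V * t_arr / feed.V_S) + feed.C_S_MR
    return float(c) if scalar else c


def substrate_supplied(t1: float, t2: float, feed: MixingVesselFeed) -> float:
    """Glucose supplied to the reactor over [t1, t2], in grams.

    Closed-form time integral of ``feed_concentration`` multiplied by the
    constant flow rate phi_V; additive over adjacent intervals.
    """
    if t1 < 0 or t2 < t1:
        raise ValueError("require 0 <= t1 <= t2")
    b = feed.phi_V / feed.V_S
    decay_part = (feed.C_S_MC - feed.C_S_MR) / b * (np.exp(-b * t1) - np.exp(-b * t2))
    return feed.phi_V * (feed.C_S_MR * (t2 - t1) + decay_part)
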