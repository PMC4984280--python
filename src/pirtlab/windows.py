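"""Interval rates and moving-window Herbert-Pirt regression.

Between two retentostat sampling points (t1, t2) with biomass
concentrations (C_X1, C_X2):

    mu    = ln(C_X2/C_X1) / (t2 - t1)
    S2-S1 = integral of C_S,in(t) dt * phi_V        (glucose supplied, g)
    Y_X/S = (C_X2 - C_X1) V / (S2 - S1)             (apparent yield)
    q_S   = mu / Y_X/S

assuming complete consumption of the glucose entering the reactor.
Pooling such interval estimates with chemostat steady states gives
(mu, q_S) points across the whole growth-rate range; OLS on moving
windows of four consecutive mu levels (all replicates included) then
resolves how the maintenance coefficient (intercept) and maximum yield
(reciprocal slope) depend on the growth rate.  A window is accepted
only when its q_S-mu relation is effectively linear (R^2 > 0.99).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .feed import MixingVesselFeed, substrate_supplied
from .simulator import ReactorConfig

__all__ = [
    "IntervalRates",
    "WindowEstimate",
    "interval_mu",
    "interval_rates",
    "intervals_from_series",
    "moving_window_regression",
]

# relative biomass change below which an interval is treated as zero growth
_ZERO_GROWTH_RTOL = 1e-12


@dataclass(frozen=True)
class IntervalRates:
    """Rates over one sampling interval of a retentostat."""

    t1: float
    t2: float
    C_X1: float
    C_X2: float
    mu: float
    S_consumed: float
    Y_app: float
    q_S: float


def interval_mu(t1: float, C_X1: float, t2: float, C_X2: float) -> float:
    """Average specific growth rate ln(C_X2/C_X1)/(t2-t1) over [t1, t2]."""
    if C_X1 <= 0 or C_X2 <= 0:
        raise ValueError("biomass concentrations must be > 0")
    if t2 <= t1:
        raise ValueError("require t2 > t1")
    return float(np.log(C_X2 / C_X1) / (t2 - t1))


def interval_rates(
    t1: float,
    C_X1: float,
    t2: float,
    C_X2: float,
    feed: MixingVesselFeed,
    reactor: ReactorConfig,
) -> IntervalRates:
    """Mass-balance rates over [t1, t2] under full glucose consumption.

    In the zero-growth limit (C_X2 = C_X1) the yield quotient is 0/0;
    q_S is then the supply rate per unit biomass (maintenance-only
    consumption) and Y_app is 0.
    """
    mu = interval_mu(t1, C_X1, t2, C_X2)
    S = substrate_supplied(t1, t2, feed)
    if S <= 0:
        raise ValueError("no substrate supplied over the interval")
    dCX = C_X2 - C_X1
    if abs(dCX) <= _ZERO_GROWTH_RTOL * C_X1:
        y_app = 0.0
        q_S = S / ((t2 - t1) * 0.5 * (C_X1 + C_X2) * reactor.V)
    else:
        y_app = dCX * reactor.V / S
        q_S = mu / y_app
    return IntervalRates(
        t1=t1, t2=t2, C_X1=C_X1, C_X2=C_X2, mu=mu, S_consumed=S, Y_app=y_app, q_S=q_S
    )


def intervals_from_series(
    times, biomass, feed: MixingVesselFeed, reactor: ReactorConfig
) -> pd.DataFrame:
    """Interval rates for every pair of consecutive sampling points."""
    t = np.asarray(times, dtype=float)
    cx = np.asarray(biomass, dtype=float)
    rows = [
        interval_rates(t[i], cx[i], t[i + 1], cx[i + 1], feed, reactor)
        for i in range(len(t) - 1)
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass(frozen=True)
class WindowEstimate:
    """Pirt parameters over one window of consecutive mu levels.

    ``accepted`` is a pure function of the window's R^2
    (accepted iff r_squared > the configured threshold).
    """

    mu_min: float
    mu_max: float
    m_S: float
    Y_max: float
    se_mS: float
    se_Y: float
    r_squared: float
    n_points: int
    accepted: bool


def moving_window_regression(
    mu,
    q_S,
    *,
    levels=None,
    window: int = 4,
    r2_min: float = 0.99,
) -> list[WindowEstimate]:
    """OLS of q_S on mu over moving windows of consecutive mu levels.

    Points sharing a level label (replicate experiments at one set
    point or interval) enter the same window together; windows span
    ``window`` consecutive levels ordered by descending mu and advance
    one level at a time.  ``levels`` defaults to treating each distinct
    mu value as its own level.  The standard error of Y_max is
    propagated from the slope SE (delta method).
    """
    mu = np.asarray(mu, dtype=float)
    qs = np.asarray(q_S, dtype=float)
    if levels is None:
        levels = mu
    levels = np.asarray(levels)
    df = pd.DataFrame({"mu": mu, "q_S": qs, "level": levels})
    order = (
        df.groupby("level")["mu"].mean().sort_values(ascending=False).index.to_numpy()
    )
    if len(order) < window:
        raise ValueError(f"need >= {window} distinct mu levels, got {len(order)}")
    if (df.groupby("level").size() == 1).any():
        warnings.warn("some mu levels have a single replicate", stacklevel=2)

    estimates = []
    for i in range(len(order) - window + 1):
        sel = df[df["level"].isin(order[i : i + window])]
        x = sel["mu"].to_numpy()
        y = sel["q_S"].to_numpy()
        res = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = res.params
        se_i, se_s = res.bse
        if slope <= 0:
            y_max, se_y = np.nan, np.nan
        else:
            y_max = 1.0 / slope
            se_y = se_s / slope**2
        r2 = float(res.rsquared)
        estimates.append(
            WindowEstimate(
                mu_min=float(x.min()),
                mu_max=float(x.max()),
                m_S=float(intercept),
                Y_max=float(y_max),
                se_mS=float(se_i),
                se_Y=float(se_y),
                r_squared=r2,
                n_points=len(x),
                accepted=bool(r2 > r2_min),
            )
        )
    return estimates


def window_estimates_frame(estimates: list[WindowEstimate]) -> pd.DataFrame:
    """Tabular view matching the window-pirt CLI output columns."""
    return pd.DataFrame(
        [
            {
                "mu_min": e.mu_min,
                "mu_max": e.mu_max,
                "m_S": e.m_S,
                "se_mS": e.se_mS,
                "Y_max": e.Y_max,
                "se_Y": e.se_Y,
                "r2": e.r_squared,
                "accepted": e.accepted,
            }
            for e in estimates
        ]
    )
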