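"""Forward simulation of retentostat growth kinetics.

The retentostat is a chemostat whose effluent passes through a filter so
that biomass is fully retained.  With a declining feed glucose
concentration C_S,in(t), total biomass keeps accumulating while the
specific growth rate decays towards zero.  The model couples

    dC_Xv/dt = mu C_Xv - k_d C_Xv      (viable biomass)
    dC_Xd/dt = k_d C_Xv                (dead biomass, retains weight)
    dC_S/dt  = D (C_S,in - C_S) - q_S C_Xv

with the Herbert-Pirt relation q_S = mu/Y_max + m_S.  Dead biomass
consumes no substrate.  Two integration modes are provided:

``pseudo_steady``
    Residual glucose is assumed negligible and quasi-equilibrated
    (dC_S/dt ~ 0, C_S ~ 0), so consumption equals supply:
    q_S C_Xv = D C_S,in(t).  This is the operating regime of
    glucose-limited retentostats, where C_S,in >> C_S.

``full_ode``
    C_S is integrated explicitly with Monod-saturable uptake
    q_S = q_S_max C_S/(K_S + C_S).  The mass balances alone do not fix
    an uptake law; the Monod form with a small K_S (high-affinity
    glucose transport, mg/L-scale residual glucose) reduces to the
    pseudo-steady limit whenever uptake capacity exceeds supply.

When supply does not cover maintenance (q_S < m_S) the growth rate goes
negative and biomass declines; such states are simulated, not clipped,
and flagged with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .energetics import MaintenanceProfile, PirtParameters, growth_rate_from_uptake
from .feed import MixingVesselFeed, feed_concentration

__all__ = [
    "ReactorConfig",
    "UptakeKinetics",
    "CultureState",
    "Trajectory",
    "simulate",
    "pseudo_steady_solution",
    "closed_form_biomass",
    "viability_series",
]

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = [
    "t_h",
    "C_S_in_gL",
    "C_Xv_gL",
    "C_Xd_gL",
    "C_X_gL",
    "C_S_gL",
    "mu_per_h",
    "qS_g_per_g_h",
    "viability",
]


@dataclass(frozen=True)
class ReactorConfig:
    """Bioreactor working volume V (L) and feed flow rate phi_V (L/h)."""

    V: float = 1.4
    phi_V: float = 0.035

    def __post_init__(self) -> None:
        if self.V <= 0 or self.phi_V <= 0:
            raise ValueError("V and phi_V must be > 0")

    @property
    def dilution_rate(self) -> float:
        """D = phi_V / V in h^-1."""
        return self.phi_V / self.V


@dataclass(frozen=True)
class UptakeKinetics:
    """Monod uptake law for full_ode mode: q_S = q_S_max C_S/(K_S + C_S).

    Defaults: q_S_max = 0.36 g g^-1 h^-1 (uptake at fast growth) and
    K_S = 0.005 g/L (high-affinity transport; residual glucose settles
    at mg/L-scale under glucose limitation).
    """

    q_S_max: float = 0.36
    K_S: float = 0.005


@dataclass(frozen=True)
class CultureState:
    """Culture state at one time point (concentrations in g/L)."""

    t: float
    C_Xv: float
    C_Xd: float = 0.0
    C_S: float = 0.0

    @property
    def C_X(self) -> float:
        return self.C_Xv + self.C_Xd


@dataclass
class Trajectory:
    """Time-indexed culture state with derived rate series.

    ``frame`` holds columns t_h, C_S_in_gL, C_Xv_gL, C_Xd_gL, C_X_gL,
    C_S_gL, mu_per_h, qS_g_per_g_h, viability on a strictly increasing
    time grid.  mu is the gross specific growth rate, so
    dC_Xv/dt = (mu - k_d) C_Xv.
    """

    frame: pd.DataFrame
    k_d: float = 0.0
    mode: str = "pseudo_steady"

    def __post_init__(self) -> None:
        t = self.frame["t_h"].to_numpy()
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("trajectory time grid must be strictly increasing")

    def at(self, t: float) -> pd.Series:
        """Linear interpolation of every column at time t."""
        grid = self.frame["t_h"].to_numpy()
        if not (grid[0] <= t <= grid[-1]):
            raise ValueError(f"t={t} outside trajectory range [{grid[0]}, {grid[-1]}]")
        return pd.Series(
            {c: np.interp(t, grid, self.frame[c].to_numpy()) for c in self.frame.columns}
        )

    @property
    def times(self) -> np.ndarray:
        return self.frame["t_h"].to_numpy()


def _maintenance_fn(params: PirtParameters, maintenance):
    if maintenance is None:
        return params.m_S
    if isinstance(maintenance, MaintenanceProfile):
        return maintenance
    return float(maintenance)


def simulate(
    reactor: ReactorConfig,
    feed: MixingVesselFeed,
    params: PirtParameters,
    C_X0: float,
    *,
    k_d: float = 0.0,
    t_grid=None,
    mode: str = "pseudo_steady",
    maintenance: MaintenanceProfile | None = None,
    kinetics: UptakeKinetics | None = None,
    C_Xd0: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the retentostat balances over ``t_grid`` (hours, from 0).

    ``params`` supplies Y_max and the constant m_S; passing a
    ``maintenance`` profile makes m_S a function of the instantaneous mu
    (the Pirt inversion then solves the fixed point
    mu = Y_max (q_S - m_S(mu))).  ``k_d`` is a first-order death rate
    converting viable into dead biomass; dead biomass consumes nothing.
    """
    if C_X0 <= 0:
        raise ValueError("C_X0 must be > 0")
    if k_d < 0:
        raise ValueError("k_d must be >= 0")
    if t_grid is None:
        t_grid = np.linspace(0.0, 600.0, 601)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0 (the retentostat switch)")
    if mode not in ("pseudo_steady", "full_ode"):
        raise ValueError(f"unknown mode {mode!r}")

    D = reactor.dilution_rate
    Y = params.Y_max
    m = _maintenance_fn(params, maintenance)
    kin = kinetics or UptakeKinetics()

    if mode == "pseudo_steady":

        def rhs(t, y):
            cxv = y[0]
            q = D * feed_concentration(t, feed) / cxv
            mu = growth_rate_from_uptake(q, Y, m)
            return [(mu - k_d) * cxv, k_d * cxv]

        y0 = [C_X0 - C_Xd0, C_Xd0]
    else:
        cs_in0 = feed_concentration(0.0, feed)
        cxv0 = C_X0 - C_Xd0
        # start residual glucose at its quasi-steady value
        def supply_gap(cs):
            return D * (cs_in0 - cs) - kin.q_S_max * cs / (kin.K_S + cs) * cxv0

        C_S0 = brentq(supply_gap, 0.0, cs_in0) if supply_gap(cs_in0) < 0 else cs_in0

        def rhs(t, y):
            cxv, _, cs = y
            cs = max(cs, 0.0)
            q = kin.q_S_max * cs / (kin.K_S + cs)
            mu = growth_rate_from_uptake(q, Y, m)
            dcs = D * (feed_concentration(t, feed) - cs) - q * cxv
            return [(mu - k_d) * cxv, k_d * cxv, dcs]

        y0 = [cxv0, C_Xd0, C_S0]

    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), y0, method="LSODA", t_eval=t_grid, rtol=rtol, atol=atol
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"integration failed: {sol.message}")

    cxv = sol.y[0]
    cxd = sol.y[1]
    cs = sol.y[2] if mode == "full_ode" else np.zeros_like(cxv)
    cs_in = feed_concentration(t_grid, feed)
    if mode == "pseudo_steady":
        qs = D * cs_in / cxv
    else:
        qs = kin.q_S_max * cs / (kin.K_S + cs)
    mu = np.array([growth_rate_from_uptake(q, Y, m) for q in qs])
    if np.any(mu < 0):
        logger.warning(
            "supply does not cover maintenance on part of the trajectory (mu < 0); "
            "biomass declines there"
        )
    cx = cxv + cxd
    frame = pd.DataFrame(
        {
            "t_h": t_grid,
            "C_S_in_gL": cs_in,
            "C_Xv_gL": cxv,
            "C_Xd_gL": cxd,
            "C_X_gL": cx,
            "C_S_gL": cs,
            "mu_per_h": mu,
            "qS_g_per_g_h": qs,
            "viability": cxv / cx,
        }
    )
    return Trajectory(frame=frame, k_d=k_d, mode=mode)


def pseudo_steady_solution(
    t,
    reactor: ReactorConfig,
    feed: MixingVesselFeed,
    params: PirtParameters,
    C_Xv0: float,
    *,
    k_d: float = 0.0,
    C_Xd0: float = 0.0,
):
    """Analytic solution of the pseudo-steady model with constant parameters.

    Under full consumption (q_S C_Xv = D C_S,in) the viable-biomass
    balance is linear:

        dC_Xv/dt = Y D C_S,in(t) - (Y m_S + k_d) C_Xv

    with C_S,in a shifted exponential, giving a sum of exponentials.
    Returns ``(C_Xv, C_Xd)`` arrays; dead biomass is the time integral
    of k_d C_Xv.  The degenerate case Y m_S + k_d = phi_V/V_S is handled
    by its limit form.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = np.isscalar(t)
    D = reactor.dilution_rate
    Y = params.Y_max
    a = Y * params.m_S + k_d
    b = feed.phi_V / feed.V_S
    A = D * (feed.C_S_MC - feed.C_S_MR)
    B = D * feed.C_S_MR

    e_at = np.exp(-a * t_arr)
    e_bt = np.exp(-b * t_arr)
    if np.isclose(a, b, rtol=1e-12, atol=0):
        f = t_arr * e_at
        F = (1 - (1 + a * t_arr) * e_at) / a**2
    else:
        f = (e_bt - e_at) / (a - b)
        F = ((1 - e_bt) / b - (1 - e_at) / a) / (a - b)
    if a > 0:
        g = (1 - e_at) / a
        G = t_arr / a - (1 - e_at) / a**2
        int_e = (1 - e_at) / a
    else:  # a = 0: no maintenance and no death
        g = t_arr
        G = t_arr**2 / 2
        int_e = t_arr

    cxv = C_Xv0 * e_at + Y * A * f + Y * B * g
    cxd = C_Xd0 + k_d * (C_Xv0 * int_e + Y * A * F + Y * B * G)
    if scalar:
        return float(cxv), float(cxd)
    return cxv, cxd


def closed_form_biomass(
    t, reactor: ReactorConfig, feed: MixingVesselFeed, params: PirtParameters, C_X0: float
):
    """Total biomass C_X(t) of the deathless pseudo-steady model.

    Independent analytic oracle for :func:`simulate` with constant
    PirtParameters and k_d = 0; asymptote D C_S,MR / m_S as t -> inf.
    """
    cxv, _ = pseudo_steady_solution(t, reactor, feed, params, C_X0)
    return cxv


def viability_series(traj: Trajectory) -> pd.Series:
    """Viable fraction C_Xv/(C_Xv + C_Xd) along the trajectory, in (0, 1]."""
    return traj.frame["viability"]
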