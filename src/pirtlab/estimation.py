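"""Parameter estimation for the Herbert-Pirt model.

Two estimators:

* :func:`fit_pirt_chemostat` — ordinary least squares of q_S on mu over
  steady-state chemostat observations (mu equals the dilution rate at
  steady state).  The intercept is the maintenance coefficient m_S and
  the reciprocal slope the maximum yield Y_X/S^max.

* :func:`fit_retentostat` — least-squares fit of the retentostat model
  (see :mod:`pirtlab.simulator`) to biomass dry-weight and, optionally,
  viable-biomass time series.  Y_max is supplied externally (from the
  chemostat regression); m_S and optionally the death rate k_d are
  estimated.  Each independent experiment is fitted separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .energetics import PirtParameters, doubling_time, pirt_qs
from .feed import MixingVesselFeed
from .simulator import ReactorConfig, Trajectory, pseudo_steady_solution, simulate

__all__ = [
    "ChemostatObservation",
    "PirtRegressionResult",
    "RetentostatFit",
    "fit_pirt_chemostat",
    "fit_retentostat",
    "derive_rates",
]


@dataclass(frozen=True)
class ChemostatObservation:
    """One steady-state glucose-limited chemostat.

    q_S is derived from the steady-state substrate balance:
    q_S = D (C_S_in - C_S_residual) / C_X.
    """

    D: float
    C_S_in: float
    C_X: float
    C_S_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("D must be > 0")
        if self.C_X <= 0:
            raise ValueError("C_X must be > 0")
        if min(self.C_S_in, self.C_S_residual) < 0:
            raise ValueError("concentrations must be >= 0")

    @property
    def q_S(self) -> float:
        return self.D * (self.C_S_in - self.C_S_residual) / self.C_X


@dataclass(frozen=True)
class PirtRegressionResult:
    """OLS estimates of the q_S-mu line from chemostat steady states.

    ``m_S`` is the raw fitted intercept (may be negative; returned with a
    warning, never clipped); ``se_slope`` is the standard error of the
    slope 1/Y_max.
    """

    m_S: float
    Y_max: float
    se_mS: float
    se_slope: float
    r_squared: float
    n_points: int

    @property
    def params(self) -> PirtParameters:
        """Validated PirtParameters (raises if the fit is unphysical)."""
        return PirtParameters(m_S=self.m_S, Y_max=self.Y_max)


def _observations_to_arrays(observations):
    if isinstance(observations, pd.DataFrame):
        df = observations
        resid = df.get("C_S_residual_gL", pd.Series(0.0, index=df.index))
        observations = [
            ChemostatObservation(r.D_per_h, r.C_S_in_gL, r.C_X_gL, cs)
            for r, cs in zip(df.itertuples(), resid)
        ]
    mu = np.array([o.D for o in observations])
    qs = np.array([o.q_S for o in observations])
    return mu, qs


def fit_pirt_chemostat(observations) -> PirtRegressionResult:
    """OLS regression of q_S on mu; intercept -> m_S, 1/slope -> Y_max.

    ``observations`` is a list of :class:`ChemostatObservation` or a
    DataFrame with columns D_per_h, C_S_in_gL, C_X_gL
    (and optionally C_S_residual_gL).  Requires >= 3 observations at
    >= 2 distinct dilution rates.
    """
    mu, qs = _observations_to_arrays(observations)
    if len(mu) < 3:
        raise ValueError("need at least 3 chemostat observations")
    if len(np.unique(mu)) < 2:
        raise ValueError("singular design: need at least 2 distinct dilution rates")
    res = sm.OLS(qs, sm.add_constant(mu)).fit()
    intercept, slope = res.params
    if intercept < 0:
        warnings.warn(
            f"fitted maintenance coefficient is negative ({intercept:.3g}); "
            "returned unclipped",
            stacklevel=2,
        )
    if slope <= 0:
        raise ValueError(f"fitted slope 1/Y_max is non-positive ({slope:.3g})")
    return PirtRegressionResult(
        m_S=float(intercept),
        Y_max=float(1.0 / slope),
        se_mS=float(res.bse[0]),
        se_slope=float(res.bse[1]),
        r_squared=float(res.rsquared),
        n_points=len(mu),
    )


@dataclass
class RetentostatFit:
    """Least-squares fit of the retentostat model to one experiment."""

    m_S_hat: float
    k_d_hat: float
    sse: float
    Y_max: float
    trajectory: Trajectory
    reactor: ReactorConfig
    feed: MixingVesselFeed
    C_X0: float
    n_points: int
    at_bound: bool = False

    @property
    def params(self) -> PirtParameters:
        return PirtParameters(m_S=self.m_S_hat, Y_max=self.Y_max)


def fit_retentostat(
    times,
    total_biomass,
    reactor: ReactorConfig,
    feed: MixingVesselFeed,
    Y_max: float,
    *,
    viable_fraction=None,
    k_d=None,
    m_S_bounds=(1e-5, 0.05),
    k_d_bounds=(0.0, 1e-2),
    n_starts: int = 3,
    relative_residuals: bool = False,
    C_X0: float | None = None,
) -> RetentostatFit:
    """Estimate m_S (and optionally k_d) from a retentostat time series.

    The model trajectory is the pseudo-steady solution with constant
    m_S; the sum of squared errors between observed and modelled total
    biomass — plus viable biomass when ``viable_fraction`` is given — is
    minimised over bounded parameters with a small log-spaced multistart
    in m_S to avoid local minima.

    ``k_d=None`` fits the death rate jointly when viability data exist,
    otherwise fixes it at 0.  A float fixes k_d.  ``C_X0`` defaults to
    the first observation (the series must then start at t = 0, the
    retentostat switch).
    """
    t = np.asarray(times, dtype=float)
    cx_obs = np.asarray(total_biomass, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    vf = None if viable_fraction is None else np.asarray(viable_fraction, dtype=float)

    if C_X0 is None:
        if t[0] != 0.0:
            raise ValueError("series must start at t=0 when C_X0 is not given")
        C_X0 = float(cx_obs[0])
    C_Xd0 = 0.0 if vf is None else float(C_X0 * (1.0 - vf[0]))
    C_Xv0 = C_X0 - C_Xd0

    fit_kd = k_d is None and vf is not None
    kd_fixed = 0.0 if k_d is None else float(k_d)

    cxv_obs = None if vf is None else cx_obs * vf

    def residuals(theta):
        m_S = theta[0]
        kd = theta[1] if fit_kd else kd_fixed
        params = PirtParameters(m_S=max(m_S, 0.0), Y_max=Y_max)
        cxv, cxd = pseudo_steady_solution(
            t, reactor, feed, params, C_Xv0, k_d=kd, C_Xd0=C_Xd0
        )
        r = [(cxv + cxd) - cx_obs]
        if cxv_obs is not None:
            r.append(cxv - cxv_obs)
        r = np.concatenate(r)
        if relative_residuals:
            obs = np.concatenate([cx_obs] + ([cxv_obs] if cxv_obs is not None else []))
            r = r / obs
        return r

    lo, hi = m_S_bounds
    starts = np.geomspace(max(lo, 1e-4), hi * 0.6, n_starts)
    bounds = ([lo] + ([k_d_bounds[0]] if fit_kd else []),
              [hi] + ([k_d_bounds[1]] if fit_kd else []))
    best = None
    for m0 in starts:
        x0 = [m0] + ([1e-4] if fit_kd else [])
        sol = least_squares(
            residuals, x0, bounds=bounds, method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError(
            f"retentostat fit failed to converge: {getattr(best, 'message', 'no solution')}"
        )

    m_S_hat = float(best.x[0])
    k_d_hat = float(best.x[1]) if fit_kd else kd_fixed
    span = hi - lo
    at_bound = min(m_S_hat - lo, hi - m_S_hat) < 1e-3 * span
    if fit_kd:
        at_bound = at_bound or (k_d_bounds[1] - k_d_hat) < 1e-3 * (k_d_bounds[1] - k_d_bounds[0])
    if at_bound:
        warnings.warn("fitted parameter at or near a bound", stacklevel=2)

    t_dense = np.linspace(0.0, float(t[-1]), max(201, len(t) * 20))
    traj = simulate(
        reactor, feed, PirtParameters(m_S=m_S_hat, Y_max=Y_max),
        C_X0, k_d=k_d_hat, C_Xd0=C_Xd0, t_grid=t_dense,
    )
    return RetentostatFit(
        m_S_hat=m_S_hat,
        k_d_hat=k_d_hat,
        sse=float(2 * best.cost),
        Y_max=Y_max,
        trajectory=traj,
        reactor=reactor,
        feed=feed,
        C_X0=C_X0,
        n_points=len(t),
        at_bound=at_bound,
    )


def derive_rates(fit: RetentostatFit) -> pd.DataFrame:
    """Time courses of mu, q_S and doubling time from a fitted model.

    mu comes from the fitted trajectory; q_S follows the Herbert-Pirt
    relation with the fitted m_S; doubling times are ln2/mu (infinite
    where mu <= 0).
    """
    frame = fit.trajectory.frame
    mu = frame["mu_per_h"].to_numpy()
    qs = pirt_qs(np.clip(mu, 0.0, None), fit.params)
    with np.errstate(divide="ignore"):
        td = np.where(mu > 0, np.log(2) / np.where(mu > 0, mu, np.nan), np.inf)
    return pd.DataFrame(
        {
            "t_h": frame["t_h"],
            "mu_per_h": mu,
            "qS_g_per_g_h": qs,
            "doubling_time_h": td,
        }
    )
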