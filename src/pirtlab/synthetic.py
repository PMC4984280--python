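"""Seeded synthetic chemostat tables and retentostat time series.

The generator emulates the statistical structure the analysis assumes,
so every pipeline stage can be exercised and parameter recovery can be
quantified without external data:

* steady-state chemostat tables at the experimental dilution-rate set
  points (0.025-0.10 h^-1, duplicate reactors) with mean-preserving
  lognormal measurement noise on biomass (default CV 3%, the
  steady-state acceptance threshold on biomass drift);
* retentostat series forward-simulated from a growth-rate-dependent
  maintenance truth (plateaus 0.0100 -> 0.0031 g g^-1 h^-1) with a small
  first-order death rate, sparse sampling (12 points over 600 h;
  sampling in real retentostats is minimised because every sample
  removes biomass), lognormal noise on biomass and feed-glucose samples
  and truncated-Gaussian noise on the viable fraction;
* storage-carbohydrate contents following a log-mu bell curve peaking
  near mu = 0.0013 h^-1 with maxima 0.12 (trehalose) and 0.07 g/g
  (glycogen) and a mild decline below the peak.

All randomness flows from an explicit integer seed through a single
``numpy.random.default_rng`` (PCG64) stream with a fixed draw order;
identical seeds give identical bytes on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energetics import (
    MaintenanceProfile,
    PirtParameters,
    chemostat_steady_state,
)
from .feed import MixingVesselFeed
from .simulator import ReactorConfig, simulate

__all__ = [
    "SyntheticConfig",
    "DEFAULT_SAMPLING_TIMES",
    "storage_content_curve",
    "generate_chemostat_table",
    "generate_retentostat_series",
]

# sparse sampling over 25 days; includes the transcriptome sampling days
# 1, 3, 5, 16 and 23 (24, 72, 120, 384, 552 h) plus the chemostat t = 0
DEFAULT_SAMPLING_TIMES = (
    0.0, 24.0, 72.0, 120.0, 192.0, 264.0, 336.0, 384.0, 456.0, 528.0, 552.0, 600.0,
)

D_LEVELS_DEFAULT = (0.025, 0.05, 0.075, 0.10)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth and noise model for the synthetic generators.

    ``maintenance`` (when not None) makes the true m_S growth-rate
    dependent; ``pirt.m_S`` is the constant-m_S truth otherwise and
    ``pirt.Y_max`` is always the true yield.  ``chemostat_pirt`` is the
    fast-growth parameter set used for chemostat tables and for the
    initial retentostat biomass (steady state at D = 0.025 h^-1).
    """

    pirt: PirtParameters = PirtParameters(m_S=0.0031, Y_max=0.584)
    maintenance: MaintenanceProfile | None = MaintenanceProfile(
        m_S_high=0.0100, m_S_low=0.0031, mu_mid=0.045, steepness=200.0
    )
    chemostat_pirt: PirtParameters = PirtParameters(m_S=0.0100, Y_max=0.584)
    k_d: float = 6e-5
    noise_cv: float = 0.03
    viability_noise_sd: float = 0.005
    sampling_times: tuple = DEFAULT_SAMPLING_TIMES
    seed: int = 0
    reactor: ReactorConfig = ReactorConfig(V=1.4, phi_V=0.035)
    feed: MixingVesselFeed = MixingVesselFeed(
        V_S=1.2, phi_V=0.035, C_S_MC=10.0, C_S_MR=5.0
    )
    trehalose_max: float = 0.12
    glycogen_max: float = 0.07
    mu_peak: float = 0.0013
    trehalose_width: float = 1.28
    glycogen_width: float = 0.667

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        st = np.asarray(self.sampling_times)
        if np.any(np.diff(st) <= 0):
            raise ValueError("sampling times must be strictly increasing")


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-preserving multiplicative noise factors with the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def storage_content_curve(mu, c_max: float, mu_peak: float, width: float):
    """Storage content (g/g biomass) as a log-mu Gaussian bump.

    Rises as mu decays towards ``mu_peak`` and falls off mildly below
    it; ``width`` is the log-space standard deviation.
    """
    mu_arr = np.clip(np.asarray(mu, dtype=float), 1e-8, None)
    return c_max * np.exp(-np.log(mu_arr / mu_peak) ** 2 / (2 * width**2))


def generate_chemostat_table(
    config: SyntheticConfig,
    D_levels=D_LEVELS_DEFAULT,
    replicates: int = 2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Steady-state chemostat table with noisy biomass dry weights.

    One row per reactor; q_S-consistent biomass from the steady-state
    balances with the ``chemostat_pirt`` truth, then multiplicative
    lognormal noise of CV ``noise_cv`` on the measured biomass.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for D in D_levels:
        ss = chemostat_steady_state(D, config.feed.C_S_MC, config.chemostat_pirt)
        for _ in range(replicates):
            rows.append(
                {
                    "D_per_h": D,
                    "C_S_in_gL": config.feed.C_S_MC,
                    "C_X_gL": ss.C_X,
                    "C_S_residual_gL": 0.0,
                }
            )
    df = pd.DataFrame(rows)
    df["C_X_gL"] *= _lognormal_factors(rng, config.noise_cv, len(df))
    return df


def generate_retentostat_series(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Sparse noisy retentostat observations plus the generating truth.

    Forward-simulates the truth model from the chemostat steady state at
    D = phi_V/V, samples at ``config.sampling_times`` and applies the
    noise model.  Returns ``(frame, truth)`` where ``truth`` records the
    generating parameters for recovery tests.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    D = config.reactor.dilution_rate
    C_X0 = chemostat_steady_state(D, config.feed.C_S_MC, config.chemostat_pirt).C_X
    t = np.asarray(config.sampling_times, dtype=float)
    traj = simulate(
        config.reactor,
        config.feed,
        config.pirt,
        C_X0,
        k_d=config.k_d,
        maintenance=config.maintenance,
        t_grid=t,
    )
    frame = traj.frame
    mu = frame["mu_per_h"].to_numpy()

    cx = frame["C_X_gL"].to_numpy() * _lognormal_factors(rng, config.noise_cv, len(t))
    viability = frame["viability"].to_numpy()
    if config.viability_noise_sd > 0:
        viability = np.clip(
            viability + rng.normal(0.0, config.viability_noise_sd, len(t)), 0.0, 1.0
        )
    feed_obs = frame["C_S_in_gL"].to_numpy() * _lognormal_factors(
        rng, config.noise_cv, len(t)
    )
    glycogen = storage_content_curve(
        mu, config.glycogen_max, config.mu_peak, config.glycogen_width
    ) * _lognormal_factors(rng, config.noise_cv, len(t))
    trehalose = storage_content_curve(
        mu, config.trehalose_max, config.mu_peak, config.trehalose_width
    ) * _lognormal_factors(rng, config.noise_cv, len(t))

    out = pd.DataFrame(
        {
            "t_h": t,
            "C_X_gL": cx,
            "viable_fraction": viability,
            "C_S_feed_gL": feed_obs,
            "glycogen_g_per_g": glycogen,
            "trehalose_g_per_g": trehalose,
        }
    )
    truth = {
        "Y_max": config.pirt.Y_max,
        "m_S": config.pirt.m_S,
        "k_d": config.k_d,
        "C_X0": C_X0,
        "noise_cv": config.noise_cv,
    }
    if config.maintenance is not None:
        truth.update(
            {
                "m_S_high": config.maintenance.m_S_high,
                "m_S_low": config.maintenance.m_S_low,
                "mu_mid": config.maintenance.mu_mid,
                "steepness": config.maintenance.steepness,
            }
        )
    return out, truth
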