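"""End-to-end orchestration: generate -> fit -> simulate -> windows -> storage.

``run_pipeline`` wires the individual stages together the way a full
study runs them: estimate Pirt parameters from (synthetic) chemostat
steady states, forward-simulate the retentostat feed design with those
estimates, fit the retentostat model to the (synthetic) biomass and
viability series, resolve the growth-rate dependence of m_S and
Y_X/S^max with moving-window regression over pooled chemostat and
retentostat (mu, q_S) points, and account for storage carbohydrates.

Every stage writes a machine-readable artifact (CSV or JSON) into the
output directory, and ``summary.json`` records the package version, the
configuration hash, the seed and the headline numbers, so each output is
traceable to its inputs.  The run is deterministic given config + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .energetics import chemostat_steady_state, doubling_time
from .estimation import derive_rates, fit_pirt_chemostat, fit_retentostat
from .io import RunConfig, write_timeseries
from .simulator import simulate
from .synthetic import SyntheticConfig, generate_chemostat_table, generate_retentostat_series
from .windows import intervals_from_series, moving_window_regression, window_estimates_frame
from .storage import storage_fraction_series

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _synthetic_config(config: RunConfig) -> SyntheticConfig:
    return SyntheticConfig(
        pirt=config.retentostat_pirt,
        maintenance=config.maintenance.profile(),
        chemostat_pirt=config.chemostat_pirt,
        k_d=config.retentostat.k_d,
        noise_cv=config.noise.cv,
        viability_noise_sd=config.noise.viability_sd,
        seed=config.seed,
        reactor=config.reactor,
        feed=config.feed,
    )


def run_pipeline(config: RunConfig, out_dir, seed: int | None = None) -> dict:
    """Run every stage and write artifacts under ``out_dir``.

    Returns the summary dictionary (also written to summary.json).
    Any stage failure raises with the stage name in the message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = replace(config, seed=seed)
    syn = _synthetic_config(config)
    summary: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }

    def stage(name):
        logger.info("stage %s", name)
        summary["stages"].append(name)

    try:
        stage("fit-chemostat")
        chem = generate_chemostat_table(
            syn, D_levels=config.chemostat.D_levels,
            replicates=config.chemostat.replicates, seed=config.seed,
        )
        write_timeseries(chem, out / "chemostats.csv")
        pirt_fit = fit_pirt_chemostat(chem)
        (out / "pirt.json").write_text(json.dumps({
            "m_S": pirt_fit.m_S, "Y_max": pirt_fit.Y_max,
            "se_mS": pirt_fit.se_mS, "se_slope": pirt_fit.se_slope,
            "r_squared": pirt_fit.r_squared, "n_points": pirt_fit.n_points,
        }, indent=2))
    except Exception as exc:
        raise RuntimeError(f"stage fit-chemostat failed: {exc}") from exc

    try:
        stage("simulate")
        D = config.reactor.dilution_rate
        C_X0 = chemostat_steady_state(D, config.feed.C_S_MC, pirt_fit.params).C_X
        t_grid = np.linspace(0.0, config.retentostat.t_end, int(config.retentostat.t_end) + 1)
        prediction = simulate(
            config.reactor, config.feed, pirt_fit.params, C_X0, t_grid=t_grid
        )
        write_timeseries(prediction.frame, out / "prediction.csv")
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc

    results = {"pirt": {"m_S": pirt_fit.m_S, "Y_max": pirt_fit.Y_max}}

    if config.retentostat.enabled:
        try:
            stage("fit-retentostat")
            series, truth = generate_retentostat_series(syn, seed=config.seed + 1)
            write_timeseries(series, out / "retentostat.csv")
            (out / "truth.json").write_text(json.dumps(truth, indent=2))
            fit = fit_retentostat(
                series["t_h"], series["C_X_gL"],
                config.reactor, config.feed, pirt_fit.Y_max,
                viable_fraction=series["viable_fraction"],
            )
            rates = derive_rates(fit)
            write_timeseries(rates, out / "rates.csv")
            (out / "fit.json").write_text(json.dumps({
                "m_S_hat": fit.m_S_hat, "k_d_hat": fit.k_d_hat,
                "sse": fit.sse, "Y_max": fit.Y_max, "n_points": fit.n_points,
            }, indent=2))
            final = fit.trajectory.frame.iloc[-1]
            results["retentostat"] = {
                "m_S_hat": fit.m_S_hat,
                "k_d_hat": fit.k_d_hat,
                "final_mu_per_h": float(final["mu_per_h"]),
                "final_qS_g_per_g_h": float(final["qS_g_per_g_h"]),
                "final_doubling_time_d": float(doubling_time(final["mu_per_h"]) / 24.0),
                "final_viability": float(final["viability"]),
            }
        except Exception as exc:
            raise RuntimeError(f"stage fit-retentostat failed: {exc}") from exc

        try:
            stage("window-pirt")
            ivals = intervals_from_series(
                series["t_h"], series["C_X_gL"], config.feed, config.reactor
            )
            chem_mu = chem["D_per_h"].to_numpy()
            chem_qs = (chem["D_per_h"] * (chem["C_S_in_gL"] - chem["C_S_residual_gL"])
                       / chem["C_X_gL"]).to_numpy()
            mu = np.concatenate([chem_mu, ivals["mu"]])
            qs = np.concatenate([chem_qs, ivals["q_S"]])
            levels = np.concatenate([
                chem_mu, np.round(ivals["mu"], decimals=12)
            ])
            windows = moving_window_regression(mu, qs, levels=levels)
            write_timeseries(window_estimates_frame(windows), out / "windows.csv")
            accepted = [w for w in windows if w.accepted]
            results["windows"] = {
                "n_windows": len(windows),
                "n_accepted": len(accepted),
            }
        except Exception as exc:
            raise RuntimeError(f"stage window-pirt failed: {exc}") from exc

        try:
            stage("storage-fraction")
            fractions = storage_fraction_series(series, config.feed, config.reactor)
            write_timeseries(fractions, out / "storage_fractions.csv")
            results["storage"] = {
                "max_fraction": float(fractions["storage_fraction"].max()),
            }
        except Exception as exc:
            raise RuntimeError(f"stage storage-fraction failed: {exc}") from exc

    summary["results"] = results
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
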