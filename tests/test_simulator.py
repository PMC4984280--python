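"""Forward retentostat simulation against its analytic oracle and balances."""

import numpy as np
import pytest

from pirtlab import (
    MixingVesselFeed,
    PirtParameters,
    chemostat_steady_state,
    closed_form_biomass,
    pseudo_steady_solution,
    simulate,
    substrate_supplied,
    viability_series,
)
from pirtlab.simulator import ReactorConfig, Trajectory


def test_zero_growth_fixed_point_is_stationary(reactor, chemostat_params):
    """With biomass retained, C_X = D C_S/m_S (supply = maintenance) is stationary.

    A retentostat has no biomass washout, so the only fixed point under
    constant feed is the zero-growth state where the entire glucose
    supply covers maintenance.
    """
    flat = MixingVesselFeed(V_S=1.2, phi_V=0.035, C_S_MC=10.0, C_S_MR=10.0)
    D = reactor.dilution_rate
    C_fix = D * 10.0 / chemostat_params.m_S
    traj = simulate(reactor, flat, chemostat_params, C_fix, t_grid=np.linspace(0, 400, 101))
    cx = traj.frame["C_X_gL"].to_numpy()
    assert np.max(np.abs(cx - C_fix) / C_fix) < 1e-7
    assert np.max(np.abs(traj.frame["mu_per_h"])) < 1e-10


def test_oracle_equivalence(reactor, feed, retentostat_params, C_X0, t_grid):
    """Numeric integrator matches the linear-ODE closed form to < 1e-6."""
    traj = simulate(reactor, feed, retentostat_params, C_X0, t_grid=t_grid)
    oracle = closed_form_biomass(t_grid, reactor, feed, retentostat_params, C_X0)
    rel = np.abs(traj.frame["C_X_gL"].to_numpy() - oracle) / oracle
    assert rel.max() < 1e-6


def test_closed_form_anchor_values(reactor, feed, retentostat_params, C_X0):
    # value at the switch, a frozen mid-course value, and the asymptote
    assert closed_form_biomass(0.0, reactor, feed, retentostat_params, C_X0) == pytest.approx(C_X0)
    assert closed_form_biomass(600.0, reactor, feed, retentostat_params, C_X0) == pytest.approx(
        29.2, abs=0.05
    )
    asymptote = reactor.dilution_rate * feed.C_S_MR / retentostat_params.m_S
    assert asymptote == pytest.approx(40.3, abs=0.05)
    assert closed_form_biomass(1e5, reactor, feed, retentostat_params, C_X0) == pytest.approx(
        asymptote, rel=1e-6
    )
    high = PirtParameters(m_S=0.0100, Y_max=0.584)
    assert reactor.dilution_rate * feed.C_S_MR / high.m_S == pytest.approx(12.5)


def test_paper_configuration_rates(reactor, feed, retentostat_params, C_X0, t_grid):
    """Growth slows from D to below 1e-3/h; uptake falls to ~0.004 g/g/h."""
    traj = simulate(reactor, feed, retentostat_params, C_X0, t_grid=t_grid)
    assert traj.at(120.0)["mu_per_h"] == pytest.approx(0.0037, rel=0.10)
    assert round(traj.at(600.0)["qS_g_per_g_h"], 3) == 0.004
    mu = traj.frame["mu_per_h"].to_numpy()
    assert np.all(np.diff(mu) < 0), "mu must decline strictly along the trajectory"


def test_viability_series(reactor, feed, retentostat_params, C_X0, t_grid):
    no_death = simulate(reactor, feed, retentostat_params, C_X0, t_grid=t_grid)
    assert np.allclose(viability_series(no_death), 1.0)

    with_death = simulate(reactor, feed, retentostat_params, C_X0, k_d=6e-5, t_grid=t_grid)
    v = viability_series(with_death).to_numpy()
    assert np.all(np.diff(v) <= 0)
    assert v[-1] >= 0.97

    # small-k_d linearity: doubling k_d about doubles the final dead fraction
    double = simulate(reactor, feed, retentostat_params, C_X0, k_d=1.2e-4, t_grid=t_grid)
    dead1 = 1 - v[-1]
    dead2 = 1 - viability_series(double).to_numpy()[-1]
    assert dead2 / dead1 == pytest.approx(2.0, rel=0.05)


def test_pseudo_steady_solution_matches_numeric_with_death(
    reactor, feed, retentostat_params, C_X0, t_grid
):
    """Analytic viable/dead solution (used by the fitter) matches the integrator."""
    k_d = 6e-5
    traj = simulate(reactor, feed, retentostat_params, C_X0, k_d=k_d, t_grid=t_grid)
    cxv, cxd = pseudo_steady_solution(t_grid, reactor, feed, retentostat_params, C_X0, k_d=k_d)
    assert np.max(np.abs(traj.frame["C_Xv_gL"] - cxv) / cxv) < 1e-6
    assert np.max(np.abs(traj.frame["C_Xd_gL"].to_numpy()[1:] - cxd[1:]) / cxd[1:]) < 1e-5


def test_full_ode_agrees_with_pseudo_steady(reactor, feed, retentostat_params, C_X0, t_grid):
    ps = simulate(reactor, feed, retentostat_params, C_X0, t_grid=t_grid)
    full = simulate(reactor, feed, retentostat_params, C_X0, t_grid=t_grid, mode="full_ode")
    cx_ps = ps.at(600.0)["C_X_gL"]
    cx_full = full.at(600.0)["C_X_gL"]
    assert abs(cx_full - cx_ps) / cx_ps < 0.01
    # residual glucose stays far below the feed concentration
    assert full.frame["C_S_gL"].max() < 0.01 * full.frame["C_S_in_gL"].min()


def test_full_ode_mass_conservation(reactor, feed, retentostat_params, C_X0):
    """Supplied glucose = growth + maintenance + residual + permeate loss (0.5%)."""
    t_grid = np.linspace(0.0, 600.0, 2401)
    full = simulate(reactor, feed, retentostat_params, C_X0, t_grid=t_grid, mode="full_ode")
    f = full.frame
    supplied = substrate_supplied(0.0, 600.0, feed)
    mu = f["mu_per_h"].to_numpy()
    cxv = f["C_Xv_gL"].to_numpy()
    growth = np.trapezoid(mu / retentostat_params.Y_max * cxv, t_grid) * reactor.V
    maint = np.trapezoid(retentostat_params.m_S * cxv, t_grid) * reactor.V
    residual = (f["C_S_gL"].iloc[-1] - f["C_S_gL"].iloc[0]) * reactor.V
    permeate = np.trapezoid(reactor.dilution_rate * f["C_S_gL"].to_numpy(), t_grid) * reactor.V
    balance = growth + maint + residual + permeate
    assert balance == pytest.approx(supplied, rel=0.005)


def test_maintenance_profile_mode_brackets_constant_runs(
    reactor, feed, C_X0, maintenance_profile, t_grid
):
    """mu-dependent m_S trajectory lies between the two constant-m_S runs."""
    y = 0.584
    lo = simulate(reactor, feed, PirtParameters(0.0031, y), C_X0, t_grid=t_grid)
    hi = simulate(reactor, feed, PirtParameters(0.0100, y), C_X0, t_grid=t_grid)
    var = simulate(
        reactor, feed, PirtParameters(0.0031, y), C_X0,
        maintenance=maintenance_profile, t_grid=t_grid,
    )
    cx_lo = lo.frame["C_X_gL"].to_numpy()
    cx_hi = hi.frame["C_X_gL"].to_numpy()
    cx_var = var.frame["C_X_gL"].to_numpy()
    assert np.all(cx_var <= cx_lo + 1e-9)
    assert np.all(cx_var >= cx_hi - 1e-9)


def test_simulate_input_validation(reactor, feed, retentostat_params):
    with pytest.raises(ValueError):
        simulate(reactor, feed, retentostat_params, 0.0)
    with pytest.raises(ValueError):
        simulate(reactor, feed, retentostat_params, 1.0, t_grid=np.array([5.0, 10.0]))
    with pytest.raises(ValueError):
        simulate(reactor, feed, retentostat_params, 1.0, mode="nope")


def test_trajectory_requires_increasing_grid():
    import pandas as pd

    frame = pd.DataFrame({c: [0.0, 0.0] for c in
                          ["t_h", "C_S_in_gL", "C_Xv_gL", "C_Xd_gL", "C_X_gL",
                           "C_S_gL", "mu_per_h", "qS_g_per_g_h", "viability"]})
    with pytest.raises(ValueError):
        Trajectory(frame=frame)
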