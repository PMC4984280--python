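"""Recovery of Pirt parameters from chemostat and retentostat data."""

import numpy as np
import pytest

from pirtlab import (
    ChemostatObservation,
    MixingVesselFeed,
    PirtParameters,
    chemostat_steady_state,
    derive_rates,
    fit_pirt_chemostat,
    fit_retentostat,
    pseudo_steady_solution,
)

TRUTH = PirtParameters(m_S=0.0100, Y_max=0.584)
D_LEVELS = (0.025, 0.05, 0.075, 0.10)


def exact_observations(params=TRUTH, cs_in=10.0, replicates=1):
    obs = []
    for D in D_LEVELS:
        ss = chemostat_steady_state(D, cs_in, params)
        obs.extend(ChemostatObservation(D, cs_in, ss.C_X) for _ in range(replicates))
    return obs


class TestChemostatRegression:
    def test_exact_recovery_on_affine_data(self):
        res = fit_pirt_chemostat(exact_observations())
        assert res.m_S == pytest.approx(TRUTH.m_S, abs=1e-12)
        assert res.Y_max == pytest.approx(TRUTH.Y_max, rel=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        """OLS agrees with hand-built normal equations on random instances."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(4, 12)
            mu = rng.uniform(0.01, 0.2, n)
            qs = 0.02 + 1.9 * mu + rng.normal(0, 1e-3, n)
            obs = [ChemostatObservation(m, 10.0, m * 10.0 / q) for m, q in zip(mu, qs)]
            res = fit_pirt_chemostat(obs)
            X = np.column_stack([np.ones(n), mu])
            beta = np.linalg.solve(X.T @ X, X.T @ qs)
            assert res.m_S == pytest.approx(beta[0], abs=1e-10)
            assert 1 / res.Y_max == pytest.approx(beta[1], abs=1e-10)

    def test_relative_se_consistency_identity(self):
        # a 23% relative SE on m_S = 0.0100 corresponds to +/- 0.0023
        assert 0.0023 / 0.0100 == pytest.approx(0.23)

    def test_singular_design_rejected(self):
        obs = [ChemostatObservation(0.05, 10.0, 4.0)] * 4
        with pytest.raises(ValueError, match="singular|distinct"):
            fit_pirt_chemostat(obs)
        with pytest.raises(ValueError, match="at least 3"):
            fit_pirt_chemostat(obs[:2])

    def test_negative_intercept_warned_not_clipped(self):
        obs = [
            ChemostatObservation(D, 10.0, D * 10.0 / (-0.002 + 2.0 * D))
            for D in D_LEVELS
        ]
        with pytest.warns(UserWarning, match="negative"):
            res = fit_pirt_chemostat(obs)
        assert res.m_S == pytest.approx(-0.002, abs=1e-10)


def make_series(reactor, feed, m_S=0.0031, k_d=0.0, y=0.584, times=None,
                noise_cv=0.0, seed=0, C_X0=None):
    """Noisy observations straight from the analytic model (local oracle)."""
    if times is None:
        times = np.array([0, 24, 72, 120, 192, 264, 336, 384, 456, 528, 552, 600.0])
    if C_X0 is None:
        C_X0 = chemostat_steady_state(reactor.dilution_rate, feed.C_S_MC,
                                      PirtParameters(0.0100, y)).C_X
    cxv, cxd = pseudo_steady_solution(
        times, reactor, feed, PirtParameters(m_S, y), C_X0, k_d=k_d
    )
    total, viab = cxv + cxd, cxv / (cxv + cxd)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        total = total * rng.lognormal(-0.5 * sigma**2, sigma, len(times))
        viab = np.clip(viab + rng.normal(0, 0.005, len(times)), 0, 1)
    return times, total, viab


class TestRetentostatFit:
    def test_noise_free_self_consistency(self, reactor, feed):
        t, cx, _ = make_series(reactor, feed, m_S=0.0031)
        fit = fit_retentostat(t, cx, reactor, feed, 0.584, k_d=0.0)
        assert fit.m_S_hat == pytest.approx(0.0031, rel=5e-5)  # 4 significant figures

    def test_noise_free_joint_kd(self, reactor, feed):
        t, cx, vf = make_series(reactor, feed, m_S=0.0031, k_d=6e-5)
        fit = fit_retentostat(t, cx, reactor, feed, 0.584, viable_fraction=vf)
        assert fit.m_S_hat == pytest.approx(0.0031, rel=5e-5)
        assert fit.k_d_hat == pytest.approx(6e-5, rel=1e-3)

    def test_constant_biomass_identifies_maintenance_ratio(self, reactor):
        """At the zero-growth fixed point, m_S = supply rate / biomass."""
        flat = MixingVesselFeed(V_S=1.2, phi_V=0.035, C_S_MC=6.0, C_S_MR=6.0)
        D = reactor.dilution_rate
        m_true = 0.004
        C_fix = D * 6.0 / m_true  # q_S = m_S at mu = 0
        t = np.linspace(0, 600, 9)
        fit = fit_retentostat(t, np.full_like(t, C_fix), reactor, flat, 0.584, k_d=0.0)
        assert fit.m_S_hat == pytest.approx(m_true, rel=1e-6)

    def test_scale_equivariance_under_unit_change(self, reactor, feed):
        """Rescaling all concentrations (unit change) leaves m_S_hat unchanged."""
        t, cx, _ = make_series(reactor, feed, m_S=0.0031, noise_cv=0.03, seed=3)
        fit1 = fit_retentostat(t, cx, reactor, feed, 0.584, k_d=0.0)
        c = 1000.0  # g/L -> mg/L
        feed_scaled = MixingVesselFeed(feed.V_S, feed.phi_V, feed.C_S_MC * c, feed.C_S_MR * c)
        fit2 = fit_retentostat(t, cx * c, reactor, feed_scaled, 0.584, k_d=0.0)
        assert fit2.m_S_hat == pytest.approx(fit1.m_S_hat, rel=1e-8)

    def test_input_validation(self, reactor, feed):
        with pytest.raises(ValueError, match="4 time points"):
            fit_retentostat([0, 1, 2], [1, 1, 1], reactor, feed, 0.584)
        with pytest.raises(ValueError, match="t=0"):
            fit_retentostat([10, 20, 30, 40], [1, 1, 1, 1], reactor, feed, 0.584)


def test_derive_rates_endpoints(reactor, feed):
    t, cx, vf = make_series(reactor, feed, m_S=0.0031, k_d=6e-5)
    fit = fit_retentostat(t, cx, reactor, feed, 0.584, viable_fraction=vf)
    rates = derive_rates(fit)
    final = rates.iloc[-1]
    assert final["mu_per_h"] < 0.001
    assert final["doubling_time_h"] / 24.0 > 38.0
    # q_S follows the Pirt relation with the fitted m_S
    assert final["qS_g_per_g_h"] == pytest.approx(
        final["mu_per_h"] / 0.584 + fit.m_S_hat, rel=1e-9
    )
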