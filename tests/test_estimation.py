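"""Closed-form estimators: exact inversion of their simplified forward models."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from il27sim.estimation import (DomainError, InsufficientDataError,
                                UnidentifiableError, activation_rate,
                                effective_death_rate, enhanced_production,
                                estimate_all, killing_rate,
                                net_growth_from_series,
                                production_from_two_points, rate_from_halflife)
from il27sim.model import baseline_parameters
from il27sim.synthetic import ObservationDesign, generate_observations


class TestNetGrowth:
    def test_constant_series(self):
        assert net_growth_from_series([1, 2, 3], [5.0, 5.0, 5.0]) == 0.0

    def test_exact_exponential(self):
        t = np.array([11.0, 14.0, 17.0, 20.0])
        v = 3.0 * np.exp(0.2 * t)
        assert net_growth_from_series(t, v) == pytest.approx(0.2, rel=1e-12)

    def test_hand_computed_pairs(self):
        # pairs (1->2) and (2->4): both ln 2 per day
        assert net_growth_from_series([0, 1, 2], [1, 2, 4]) == pytest.approx(np.log(2))

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            net_growth_from_series([1], [2.0])
        with pytest.raises(DomainError):
            net_growth_from_series([1, 2], [1.0, 0.0])


class TestHalflife:
    def test_ln2_halflife_gives_unit_rate(self):
        assert rate_from_halflife(np.log(2)) == pytest.approx(1.0)

    def test_two_day_halflife(self):
        assert rate_from_halflife(2.0) == pytest.approx(np.log(2) / 2, rel=1e-12)

    def test_forward_consistency(self):
        """Decay at the returned rate halves the quantity in one half-life."""
        d = rate_from_halflife(3.7)
        assert np.exp(-d * 3.7) == pytest.approx(0.5, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            rate_from_halflife(0.0)


class TestProductionTwoPoints:
    def test_steady_state_identity(self):
        a, S, d = 3e-5, 2e6, 4.0
        u = a * S / d
        assert production_from_two_points(u, u, 1, 5, S, d) == pytest.approx(a, rel=1e-12)

    def test_roundtrip_forward_ode(self):
        """Forward-simulate du/dt = a*S - d*u with an independent integrator,
        then invert."""
        a, S, d, u0 = 7.7e-6, 4e6, 2.2, 11.0
        sol = solve_ivp(lambda t, u: a * S - d * u, (0, 5), [u0],
                        t_eval=[1.0, 5.0], rtol=1e-12, atol=1e-14)
        u1, u2 = sol.y[0]
        assert production_from_two_points(u1, u2, 1, 5, S, d) == pytest.approx(a, rel=1e-10)

    def test_zero_source_unidentifiable(self):
        with pytest.raises(InsufficientDataError):
            production_from_two_points(1.0, 2.0, 1, 5, 0.0, 1.0)

    def test_bad_times(self):
        with pytest.raises(DomainError):
            production_from_two_points(1.0, 2.0, 5, 1, 1e6, 1.0)


class TestEnhancedProduction:
    def test_roundtrip(self):
        p = baseline_parameters()
        E, I27, u0 = 2e6, 150.0, 5.0
        src = p.lam1 * E + p.lam2 * E * I27 / (p.K_I27_10 + I27)
        sol = solve_ivp(lambda t, u: src - p.d_I10 * u, (0, 5), [u0],
                        t_eval=[1.0, 5.0], rtol=1e-12, atol=1e-14)
        lam2 = enhanced_production(sol.y[0][0], sol.y[0][1], 1, 5, E, I27,
                                   p.K_I27_10, p.lam1, p.d_I10)
        assert lam2 == pytest.approx(p.lam2, rel=1e-10)

    def test_saturation_limit_reduces_to_sum(self):
        """As I27 -> infinity the estimate equals the plain two-point
        inversion with source (lam1 + lam2)*E."""
        lam1, lam2, E, d = 1e-5, 5e-5, 1e6, 4.0
        u = (lam1 + lam2) * E / d  # steady state at full saturation
        got = enhanced_production(u, u, 1, 5, E, 1e12, 30.0, lam1, d)
        assert got == pytest.approx(lam2, rel=1e-6)

    def test_zero_lam2_recovered(self):
        lam1, E, d = 1e-5, 1e6, 4.0
        u = lam1 * E / d
        assert enhanced_production(u, u, 1, 5, E, 80.0, 30.0, lam1, d) == \
            pytest.approx(0.0, abs=1e-10 * lam1)

    def test_no_il27_unidentifiable(self):
        with pytest.raises(UnidentifiableError):
            enhanced_production(1.0, 2.0, 1, 5, 1e6, 0.0, 30.0, 1e-5, 4.0)


class TestActivationRate:
    def test_steady_state_identity(self):
        lamE, K_T, T, d = 3e5, 1e7, 4e7, 1.0
        E = lamE * T / (K_T + T) / d
        assert activation_rate(E, E, T, K_T, d) == pytest.approx(lamE, rel=1e-12)

    def test_roundtrip_both_genotype_arms(self):
        """Recover lamE from forward-simulated CTL counts, with and without
        the IL-27 survival (death-rate) reduction."""
        lamE, K_T, T, d_E = 3e5, 1e7, 3e7, 1.0
        a = lamE * T / (K_T + T)
        for survival_factor in (1.0, 4.0):   # 1: control arm; >1: IL-27 arm
            d_eff = d_E / survival_factor
            sol = solve_ivp(lambda t, E: a - d_eff * E, (0, 5), [2e6],
                            t_eval=[1.0, 5.0], rtol=1e-12, atol=1e-14)
            got = activation_rate(sol.y[0][0], sol.y[0][1], T, K_T, d_eff)
            assert got == pytest.approx(lamE, rel=1e-10)

    def test_effective_death_rate_roundtrip(self):
        a, d_true, E1 = 1.5e5, 0.37, 3e6
        E5 = E1 * np.exp(-d_true * 4) + a / d_true * (1 - np.exp(-d_true * 4))
        assert effective_death_rate(E1, E5, a, 4.0) == pytest.approx(d_true, rel=1e-10)

    def test_no_tumor_unidentifiable(self):
        with pytest.raises(UnidentifiableError):
            activation_rate(1e5, 2e5, 0.0, 1e7, 1.0)


class TestKillingRate:
    def test_no_killing_observed(self):
        g, T1 = 0.2, 1e7
        T2 = T1 * np.exp(g * 4)
        assert killing_rate(T1, T2, 1, 5, g, 50.0, 30.0) == pytest.approx(0.0, abs=1e-12)

    def test_roundtrip(self):
        g, eta, K, u = 0.2, 0.9, 30.0, 45.0
        kill = eta * u / (K + u)
        T1 = 2e7
        T2 = T1 * np.exp((g - kill) * 4)
        assert killing_rate(T1, T2, 1, 5, g, u, K) == pytest.approx(eta, rel=1e-10)

    def test_saturated_limit(self):
        """With the killer far above its half-saturation the estimate equals
        net growth minus observed growth."""
        g, T1 = 0.2, 1e7
        T2 = T1 * np.exp((g - 0.45) * 4)
        assert killing_rate(T1, T2, 1, 5, g, 1e12, 30.0) == pytest.approx(0.45, rel=1e-6)

    def test_zero_killer_unidentifiable(self):
        with pytest.raises(UnidentifiableError):
            killing_rate(1e7, 9e6, 1, 5, 0.2, 0.0, 30.0)


class TestEstimateAll:
    def test_zero_noise_recovery(self):
        """The full cascade on noiseless synthetic observations recovers
        every generated parameter to well below 1%."""
        p = baseline_parameters(mu1_case="large")
        obs = generate_observations(p, ObservationDesign(cv=0.0))
        est = estimate_all(obs)
        errs = est.relative_errors(p)
        assert set(errs) == {"d_T", "lamT", "mu1", "lam1", "lam2", "lamE",
                             "K_E1", "K_E2", "lamG", "eta1", "eta2"}
        assert max(errs.values()) < 1e-2
        assert est.unestimable == {}

    def test_missing_knockout_arms_isolate_killing_rates(self):
        """Dropping the IL-10-knockout arms makes only eta1/eta2 unestimable;
        upstream estimates are unchanged."""
        p = baseline_parameters(mu1_case="large")
        full = generate_observations(p, ObservationDesign(cv=0.0))
        partial_design = ObservationDesign(cv=0.0, arms=("P1CTL", "P1CTL-IL27"))
        part = generate_observations(p, partial_design)
        est_full, est_part = estimate_all(full), estimate_all(part)
        assert "eta2" in est_part.unestimable and "eta1" in est_part.unestimable
        for k in ("mu1", "lam1", "lam2", "lamE", "K_E1", "lamG", "lamT"):
            assert est_part.values[k] == pytest.approx(est_full.values[k], rel=1e-12)

    def test_deterministic_and_records_intermediates(self):
        p = baseline_parameters(mu1_case="large")
        obs = generate_observations(p, ObservationDesign(cv=0.1, seed=5))
        e1, e2 = estimate_all(obs), estimate_all(obs)
        assert e1.values == e2.values
        # the averaged day-1/day-5 intermediates are reproducible from the data
        d, v = obs.series("E", "P1CTL")
        assert e1.intermediates["E_bar[P1CTL]"] == pytest.approx((v[0] + v[-1]) / 2)

    def test_scale_equivariance(self):
        """Rescaling all concentrations (data and matching half-saturations)
        rescales concentration-valued estimates and leaves rates unchanged."""
        p = baseline_parameters(mu1_case="large")
        obs = generate_observations(p, ObservationDesign(cv=0.0))
        c = 3.0
        scaled = obs.table.copy()
        conc = scaled["quantity"].isin(["I27", "I10", "G"])
        scaled.loc[conc, "value"] *= c
        from il27sim.estimation import FIXED_CONSTANTS_DEFAULT, ObservationSet
        fixed = dict(FIXED_CONSTANTS_DEFAULT)
        for k in ("K_I27_10", "K_kill10", "K_killG"):
            fixed[k] *= c
        est0 = estimate_all(obs)
        est1 = estimate_all(ObservationSet(scaled), fixed=fixed)
        assert est1["mu1"] == pytest.approx(c * est0["mu1"], rel=1e-10)
        assert est1["lam1"] == pytest.approx(c * est0["lam1"], rel=1e-10)
        assert est1["K_E1"] == pytest.approx(c * est0["K_E1"], rel=1e-10)
        assert est1["eta1"] == pytest.approx(est0["eta1"], rel=1e-10)
        assert est1["lamE"] == pytest.approx(est0["lamE"], rel=1e-10)

    def test_monte_carlo_recovery_under_noise(self):
        """10% per-animal CV, 60 replicates: median relative error stays
        well-behaved for every parameter (the acceptance suite runs the full
        200-replicate study)."""
        p = baseline_parameters(mu1_case="large")
        errs = {}
        for rep in range(60):
            obs = generate_observations(p, ObservationDesign(cv=0.1, seed=rep))
            for k, v in estimate_all(obs).relative_errors(p).items():
                errs.setdefault(k, []).append(v)
        medians = {k: np.median(v) for k, v in errs.items()}
        assert max(medians.values()) < 0.15, medians
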