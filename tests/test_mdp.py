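"""Decision model: utility, perceived risk, backward induction, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epibehave as eb
from epibehave.mdp import (
    PerceivedEnvironment,
    progression_probabilities,
    solve_group_policy,
    terminal_static_values,
    utility,
)

from conftest import random_environment


class TestUtility:
    def test_boundary_zeros(self):
        assert utility(0.0, 48.0, 0.1) == 0.0
        assert utility(48.0, 48.0, 0.1) == 0.0

    def test_midpoint_value(self):
        assert utility(24.0, 48.0, 0.1) == pytest.approx(576.0**0.1, rel=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(nu=st.floats(0.01, 1.0), c=st.floats(0.1, 47.9))
    def test_maximized_at_half_b(self, nu, c):
        assert utility(c, 48.0, nu) <= utility(24.0, 48.0, nu) + 1e-12

    def test_domain_error(self):
        with pytest.raises(ValueError):
            utility(-1.0, 48.0, 0.1)
        with pytest.raises(ValueError):
            utility(48.5, 48.0, 0.1)


class TestPerceivedProbability:
    def env(self, group=1):
        state = eb.EpidemicState(S1=0.9, I=0.1)
        return PerceivedEnvironment(state, eb.ContactProfile.uniform(24.0), group)

    def test_no_infectious_gives_zero(self, dparams):
        env = PerceivedEnvironment(
            eb.EpidemicState(S1=1.0), eb.ContactProfile.uniform(24.0), 1
        )
        assert eb.perceived_infection_probability(24.0, env, dparams, 1.0) == 0.0

    def test_zero_reporting_nulls_risk(self, dparams):
        assert eb.perceived_infection_probability(24.0, self.env(), dparams, 0.0) == 0.0

    def test_direct_arithmetic(self, dparams):
        got = eb.perceived_infection_probability(24.0, self.env(), dparams, 1.0)
        assert got == pytest.approx(1.0 - math.exp(-0.01324 * 24.0 * 0.1), rel=1e-12)
        assert got == pytest.approx(0.03128, abs=5e-5)

    def test_risk_evader_scaled_by_epsilon(self, dparams):
        p1 = eb.perceived_infection_probability(24.0, self.env(1), dparams, 1.0)
        p2 = eb.perceived_infection_probability(24.0, self.env(2), dparams, 1.0)
        assert p2 < p1
        assert math.log1p(-p2) == pytest.approx(dparams.epsilon * math.log1p(-p1), rel=1e-9)


def test_progression_probabilities(dparams):
    p_e, p_ar, p_ir = progression_probabilities(dparams)
    assert p_e == pytest.approx(1.0 - math.exp(-0.2), rel=1e-12)
    assert p_ar == p_ir == pytest.approx(1.0 - math.exp(-1.0 / 9.0), rel=1e-12)
    assert progression_probabilities(eb.DiseaseParams(kappa=1e-12))[0] == pytest.approx(0.0, abs=1e-9)


class TestTerminalStaticValues:
    def test_last_step_recovered_value(self, dparams, bparams):
        v_i, v_r = terminal_static_values(14, bparams, dparams)
        u_star = utility(24.0, 48.0, bparams.nu1)
        assert v_r[14] == pytest.approx(u_star + bparams.delta * 0.0, rel=1e-12)

    def test_undiscounted_full_utility_sum(self, dparams):
        bp = eb.BehaviorParams(delta=1.0, symptomatic_utility="full")
        tau = 10
        v_i, v_r = terminal_static_values(tau, bp, dparams)
        u_star = utility(24.0, 48.0, bp.nu1)
        assert v_r[0] == pytest.approx((tau + 1) * u_star, rel=1e-12)
        assert v_i[0] <= v_r[0] + 1e-12

    def test_symptomatic_value_matches_chain_enumeration(self, dparams, bparams):
        """Forward enumeration of the two-state (I -> R) absorbing chain."""
        tau = 14
        v_i, v_r = terminal_static_values(tau, bparams, dparams)
        _, _, p_ir = progression_probabilities(dparams)
        u_star = utility(24.0, 48.0, bparams.nu1)
        prob_i = 1.0
        expected = 0.0
        for k in range(tau + 1):
            # still symptomatic: utility 0; recovered: u(C*)
            expected += bparams.delta**k * (1.0 - prob_i) * u_star
            prob_i *= 1.0 - p_ir
        assert v_i[0] == pytest.approx(expected, rel=1e-12)

    def test_recovered_closed_form(self, dparams, bparams):
        tau = 14
        _, v_r = terminal_static_values(tau, bparams, dparams)
        u_star = utility(24.0, 48.0, bparams.nu1)
        for k in (0, 7, tau):
            geom = sum(bparams.delta**j for j in range(tau - k + 1))
            assert v_r[k] == pytest.approx(geom * u_star, rel=1e-12)


def brute_force_policy(env, dp, bp, n_grid=2000):
    """Independent oracle: plain dense-grid backward induction."""
    from epibehave.kernel import _mixing_arrays

    g = env.group
    nu, tau, b, d = bp.nu(g), bp.tau(g), bp.b, bp.delta
    mix = _mixing_arrays(env.state.as_array(), env.contacts.as_array(), dp)
    beta_i = dp.beta if g == 1 else dp.epsilon * dp.beta
    hazard = beta_i * bp.phi * mix
    p_e, p_ar, _ = progression_probabilities(dp)
    v_i, v_r = terminal_static_values(tau, bp, dp, group=g)
    grid = np.linspace(b / 2 / n_grid, b / 2, n_grid)
    u_grid = (grid * (b - grid)) ** nu
    p_grid = -np.expm1(-hazard * grid)
    v_s = v_e = v_a = bp.terminal_value
    c0 = b / 2
    for k in range(tau, -1, -1):
        obj = u_grid + d * ((1 - p_grid) * v_s + p_grid * v_e)
        i = len(obj) - 1 - int(np.argmax(obj[::-1]))
        c0, u_c, p_se = grid[i], u_grid[i], p_grid[i]
        v_s_new = obj[i]
        v_e_new = u_c + d * ((1 - p_e) * v_e + p_e * (dp.sigma * v_a + (1 - dp.sigma) * v_i[k + 1]))
        v_a_new = u_c + d * ((1 - p_ar) * v_a + p_ar * v_r[k + 1])
        v_s, v_e, v_a = v_s_new, v_e_new, v_a_new
    return c0


class TestSolveGroupPolicy:
    def test_zero_prevalence_gives_disease_free_optimum(self, dparams, bparams):
        env = PerceivedEnvironment(
            eb.EpidemicState(S1=0.6, S2=0.4), eb.ContactProfile.uniform(24.0), 1
        )
        c0, table = solve_group_policy(env, dparams, bparams)
        assert c0 == 24.0
        assert np.all(table.C_hat == 24.0)

    def test_zero_horizon_ignores_prevalence(self, dparams):
        bp = eb.BehaviorParams(tau1=0, tau2=0)
        env = PerceivedEnvironment(
            eb.EpidemicState(S1=0.5, I=0.5), eb.ContactProfile.uniform(24.0), 1
        )
        c0, _ = solve_group_policy(env, dparams, bp)
        assert c0 == 24.0

    def test_matches_grid_oracle_on_randomized_environments(self, dparams, bparams):
        rng = np.random.default_rng(20260926)
        spacing = bparams.b / 2 / 2000
        for i in range(100):
            env = random_environment(rng, group=1 + i % 2)
            c_impl, _ = solve_group_policy(env, dparams, bparams)
            c_oracle = brute_force_policy(env, dparams, bparams)
            assert abs(c_impl - c_oracle) <= spacing + 1e-6, f"env {i}"

    def test_contact_choice_monotone_in_prevalence(self, dparams, bparams):
        prev = None
        for m in (0.0, 0.02, 0.05, 0.1, 0.2, 0.4):
            state = eb.EpidemicState(
                S1=(1 - m) * 0.5, S2=(1 - m) * 0.5,
                E1=m / 3, A1=m / 3, I=m / 3,
            )
            env = PerceivedEnvironment(state, eb.ContactProfile.uniform(24.0), 1)
            c0, _ = solve_group_policy(env, dparams, bparams)
            if prev is not None:
                assert c0 <= prev + 1e-9
            prev = c0

    def test_contact_choice_monotone_in_reporting(self, dparams):
        state = eb.EpidemicState(S1=0.4, S2=0.3, E1=0.1, A1=0.1, I=0.1)
        env = PerceivedEnvironment(state, eb.ContactProfile.uniform(24.0), 1)
        prev = None
        for phi in (0.0, 0.25, 0.5, 0.75, 1.0):
            bp = eb.BehaviorParams(phi=phi)
            c0, _ = solve_group_policy(env, dparams, bp)
            if phi == 0.0:
                assert c0 == 24.0
            if prev is not None:
                assert c0 <= prev + 1e-9
            prev = c0

    def test_risk_evader_keeps_more_contacts_at_equal_shape(self, dparams):
        """epsilon < 1 lowers perceived risk, so group 2 sacrifices less."""
        bp = eb.BehaviorParams(nu1=0.1, nu2=0.1)
        state = eb.EpidemicState(S1=0.4, S2=0.3, E1=0.1, A1=0.1, I=0.1)
        contacts = eb.ContactProfile.uniform(24.0)
        c1, _ = solve_group_policy(PerceivedEnvironment(state, contacts, 1), dparams, bp)
        c2, _ = solve_group_policy(PerceivedEnvironment(state, contacts, 2), dparams, bp)
        assert c2 >= c1

    def test_value_ordering_infection_never_beneficial(self, dparams, bparams):
        state = eb.EpidemicState(S1=0.4, S2=0.3, E1=0.1, A1=0.1, I=0.1)
        env = PerceivedEnvironment(state, eb.ContactProfile.uniform(20.0), 1)
        _, table = solve_group_policy(env, dparams, bparams)
        tau = len(table.C_hat) - 1
        for k in range(tau + 1):
            assert table.V_S[k] >= table.V_E[k] - 1e-12
            assert table.V_E[k] >= table.V_I[k] - 1e-12

    def test_value_table_frame_shape(self, dparams, bparams):
        env = PerceivedEnvironment(
            eb.EpidemicState(S1=0.9, I=0.1), eb.ContactProfile.uniform(24.0), 2
        )
        _, table = solve_group_policy(env, dparams, bparams)
        df = table.to_frame()
        assert list(df.columns) == ["k", "V_S", "V_E", "V_A", "V_I", "V_R", "C_hat"]
        assert len(df) == bparams.tau2 + 1
        assert (df["C_hat"] > 0).all() and (df["C_hat"] <= 24.0).all()


class TestDiscount:
    def test_zero_rate(self):
        assert eb.annual_to_daily_discount(0.0) == 1.0

    def test_five_percent_annual(self):
        assert round(eb.annual_to_daily_discount(0.05), 5) == 0.99986

    def test_round_trip(self):
        delta = eb.annual_to_daily_discount(0.05)
        assert delta**365 == pytest.approx(0.95, abs=1e-12)

    def test_rate_domain(self):
        with pytest.raises(ValueError):
            eb.annual_to_daily_discount(1.0)
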