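"""Core dynamics: response laws, fluxes, Euler stepping, growth phases."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from medexsim.model_core import (CommunityParameters, CommunityState,
                                 grow_until, mediator_fluxes,
                                 per_capita_growth_rates, read_network_csv,
                                 simulate_trajectory, step, write_network_csv)

from conftest import build_community, mutualist_pair


def single_influence(rho, inhibition_law="linear", facilitation_law="monod",
                     r0=0.1, K=1.0e4, **kwargs):
    """One species, one mediator, one influence link."""
    return build_community(1, 1, [r0], influences=[(0, 0, rho)],
                           inhibition_law=inhibition_law,
                           facilitation_law=facilitation_law, **kwargs)


class TestGrowthRates:
    def test_zero_concentration_gives_basal_rates(self):
        params = mutualist_pair()
        rates = per_capita_growth_rates(params, np.zeros(2))
        np.testing.assert_allclose(rates, params.r0)

    def test_monod_half_saturation(self):
        params = single_influence(0.2)
        params.K[0, 0] = 5.0e3
        rate = per_capita_growth_rates(params, np.array([5.0e3]))
        assert rate[0] == pytest.approx(0.1 + 0.1)

    def test_linear_inhibition_hand_value(self):
        # r0 = 0.1, rho- = 0.2, K = 1e4, C = 5e3 -> 0.1 - 0.2 * 0.5 = 0
        params = single_influence(-0.2)
        rate = per_capita_growth_rates(params, np.array([5.0e3]))
        assert rate[0] == pytest.approx(0.0, abs=1e-14)

    def test_linear_inhibition_can_go_negative(self):
        params = single_influence(-0.2)
        rate = per_capita_growth_rates(params, np.array([1.0e5]))
        assert rate[0] == pytest.approx(0.1 - 0.2 * 10.0)

    @pytest.mark.parametrize("c,expected", [
        (1.0e3, 0.1),                                # below threshold
        (6.0e3, 0.1 - 0.2 * (6.0e3 - 2.0e3) / 1e4),  # above threshold
    ])
    def test_threshold_law(self, c, expected):
        params = single_influence(-0.2, inhibition_law="threshold", c_th=2.0e3)
        rate = per_capita_growth_rates(params, np.array([c]))
        assert rate[0] == pytest.approx(expected)

    def test_threshold_with_zero_cth_equals_linear(self):
        linear = single_influence(-0.15)
        thresh = single_influence(-0.15, inhibition_law="threshold", c_th=0.0)
        for c in (0.0, 1.0e3, 2.0e4):
            assert (per_capita_growth_rates(thresh, [c])[0]
                    == pytest.approx(per_capita_growth_rates(linear, [c])[0]))

    def test_growth_inhibition_law_hand_value(self):
        # r(C) = r0 - r_inh / (1 + K/(C - C_th)) above threshold
        params = single_influence(-0.2, inhibition_law="growth_inhibition",
                                  c_th=1.0e3)
        c = 6.0e3
        expected = 0.1 - 0.2 / (1.0 + 1.0e4 / (c - 1.0e3))
        assert per_capita_growth_rates(params, [c])[0] == pytest.approx(expected)

    def test_moser_n1_equals_monod(self):
        monod = single_influence(0.2)
        moser = single_influence(0.2, facilitation_law="moser", moser_n=1.0)
        for c in (0.0, 3.0e3, 5.0e4):
            assert (per_capita_growth_rates(moser, [c])[0]
                    == pytest.approx(per_capita_growth_rates(monod, [c])[0]))

    def test_moser_steeper_at_n2(self):
        moser = single_influence(0.2, facilitation_law="moser", moser_n=2.0)
        k = moser.K[0, 0]
        below = per_capita_growth_rates(moser, [0.3 * k])[0]
        at_k = per_capita_growth_rates(moser, [k])[0]
        assert at_k == pytest.approx(0.1 + 0.1)  # half-saturation at K for any n
        assert below < 0.1 + 0.1 * 0.3 / 1.3     # steeper than Monod below K

    def test_additivity_across_mediators(self):
        # community with two links on one species: contribution sums exactly
        both = build_community(1, 2, [0.1],
                               influences=[(0, 0, 0.2), (0, 1, -0.1)])
        only_a = build_community(1, 2, [0.1], influences=[(0, 0, 0.2)])
        only_b = build_community(1, 2, [0.1], influences=[(0, 1, -0.1)])
        only_b.K[:] = both.K[:] = only_a.K[:] = 1.0e4
        c = np.array([4.0e3, 7.0e3])
        r_both = per_capita_growth_rates(both, c)[0]
        r_a = per_capita_growth_rates(only_a, c)[0]
        r_b = per_capita_growth_rates(only_b, c)[0]
        assert r_both == pytest.approx(r_a + r_b - 0.1)

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            per_capita_growth_rates(mutualist_pair(), np.array([-1.0, 0.0]))

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError):
            per_capita_growth_rates(mutualist_pair(), np.zeros(3))


class TestMediatorFluxes:
    def test_no_cells_no_flux(self):
        params = mutualist_pair()
        state = CommunityState(np.zeros(2), np.array([1.0e3, 2.0e3]))
        np.testing.assert_allclose(mediator_fluxes(params, state), 0.0)

    def test_decay_acts_without_cells(self):
        params = mutualist_pair()
        params.decay = np.array([0.1, 0.0])
        state = CommunityState(np.zeros(2), np.array([1.0e3, 2.0e3]))
        np.testing.assert_allclose(mediator_fluxes(params, state),
                                   [-100.0, 0.0])

    def test_single_producer_flux(self):
        # beta = 0.1 fmol/h/cell at S = 1e4/ml -> 1e3 fmol/ml/h
        params = build_community(1, 1, [0.1], productions=[(0, 0, 0.1)])
        state = CommunityState(np.array([1.0e4]), np.zeros(1))
        assert mediator_fluxes(params, state)[0] == pytest.approx(1.0e3)

    def test_reusable_mediator_is_never_consumed(self):
        params = mutualist_pair(depletable=False)
        state = CommunityState(np.array([1.0e6, 1.0e6]),
                               np.array([5.0e3, 5.0e3]))
        flux = mediator_fluxes(params, state)
        assert np.all(flux > 0)  # production only

    def test_monod_uptake_hand_value(self):
        # per-capita Monod uptake (equation-as-printed kinetics)
        params = mutualist_pair(depletable=True)
        params = CommunityParameters(
            r0=params.r0, rho=params.rho, K=params.K, alpha=params.alpha,
            beta=params.beta, depletable=params.depletable,
            consumption="monod")
        S = np.array([1.0e5, 1.0e5])
        C = np.array([1.0e4, 0.0])
        flux = mediator_fluxes(params, CommunityState(S, C))
        # production 0.1*1e5; consumption by species 1: 1.0 * C/(C+K) * S
        expected = 0.1 * 1.0e5 - 1.0 * (1.0e4 / (1.0e4 + params.K[1, 0])) * 1.0e5
        assert flux[0] == pytest.approx(expected)

    def test_growth_coupled_uptake_scales_with_rate(self):
        params = mutualist_pair(depletable=True)
        S = np.array([1.0e5, 1.0e5])
        C = np.array([1.0e4, 0.0])
        rates = per_capita_growth_rates(params, C)
        flux = mediator_fluxes(params, CommunityState(S, C))
        expected = 0.1 * 1.0e5 - 1.0 * rates[1] * (
            1.0e4 / (1.0e4 + params.K[1, 0])) * 1.0e5
        assert flux[0] == pytest.approx(expected)


class TestStep:
    def test_zero_rates_leave_state_unchanged(self):
        params = build_community(1, 1, [0.0])
        state = CommunityState(np.array([1.0e4]), np.array([2.0e3]))
        out = step(params, state, 0.01)
        np.testing.assert_allclose(out.S, state.S)
        np.testing.assert_allclose(out.C, state.C)
        assert out.t == pytest.approx(0.01)

    def test_euler_update_arithmetic(self):
        params = build_community(1, 0, [0.1])
        out = step(params, CommunityState(np.array([1.0e4]), np.zeros(0)), 0.01)
        assert out.S[0] == pytest.approx(1.0e4 * 1.001)

    def test_concentration_clamped_at_zero(self):
        params = build_community(1, 1, [0.1], decay=np.array([100.0]))
        out = step(params, CommunityState(np.array([0.0]), np.array([1.0])), 0.01)
        assert out.C[0] == 0.0

    def test_density_floored_at_zero(self):
        params = single_influence(-50.0)  # inhibition overwhelms within a step
        out = step(params, CommunityState(np.array([100.0]), np.array([1.0e6])),
                   0.5)
        assert out.S[0] == 0.0

    def test_kernel_matches_numpy_reference(self):
        """Compiled growth loop reproduces repeated step() exactly."""
        rng = np.random.default_rng(42)
        n, m = 4, 3
        params = CommunityParameters(
            r0=rng.uniform(0.08, 0.12, n),
            rho=np.where(rng.random((n, m)) < 0.5,
                         rng.uniform(-0.2, 0.2, (n, m)), 0.0),
            K=rng.uniform(5.0e3, 1.5e4, (n, m)),
            alpha=np.zeros((m, n)), beta=rng.uniform(0.0, 0.15, (m, n)),
            depletable=np.zeros((m, n), dtype=bool))
        # add one depletable link on an existing influence
        ii, ll = np.nonzero(params.rho)
        params.depletable[ll[0], ii[0]] = True
        params.alpha[ll[0], ii[0]] = 1.0
        state = CommunityState(np.full(n, 2.5e3), np.zeros(m))
        ref = state.copy()
        for _ in range(500):
            ref = step(params, ref, 0.01)
        out, reached = grow_until(params, state, 1.0e30, t_max=500 * 0.01,
                                  dt=0.01)
        assert not reached
        np.testing.assert_allclose(out.S, ref.S, rtol=1e-9)
        np.testing.assert_allclose(out.C, ref.C, rtol=1e-9)


class TestGrowUntil:
    def test_exponential_crossing_time(self):
        # single species, r0 = 0.1: 1e4 -> 1e10 in ln(1e6)/ln(1.001) steps
        params = build_community(1, 0, [0.1])
        state = CommunityState(np.array([1.0e4]), np.zeros(0))
        out, reached = grow_until(params, state, 1.0e10, t_max=1.0e3, dt=0.01)
        assert reached
        euler_steps = int(np.ceil(np.log(1.0e6) / np.log(1.001)))
        assert out.t == pytest.approx(euler_steps * 0.01, abs=0.011)
        assert out.t == pytest.approx(np.log(1.0e6) / 0.1, rel=0.01)

    def test_stall_without_growth(self):
        params = build_community(2, 0, [0.0, 0.0])
        state = CommunityState(np.full(2, 5.0e3), np.zeros(0))
        out, reached = grow_until(params, state, 1.0e10, t_max=50.0)
        assert not reached
        assert out.t == pytest.approx(50.0, abs=0.011)

    def test_faster_competitor_gains_frequency(self):
        params = build_community(2, 0, [0.12, 0.08])
        state = CommunityState(np.full(2, 5.0e3), np.zeros(0))
        out, reached = grow_until(params, state, 1.0e10, t_max=1.0e4)
        assert reached
        f_fast = out.S[0] / out.S.sum()
        assert f_fast > 0.5

    def test_extinction_threshold_zeroes_species(self):
        params = build_community(2, 1, [0.1, -0.5],  # second species dies off
                                 influences=[], productions=[])
        state = CommunityState(np.array([5.0e3, 1.0]), np.zeros(1))
        out, _ = grow_until(params, state, 1.0e10, t_max=1.0e3,
                            extinction_threshold=0.1)
        assert out.S[1] == 0.0

    def test_requires_threshold_above_current_density(self):
        params = build_community(1, 0, [0.1])
        state = CommunityState(np.array([1.0e4]), np.zeros(0))
        with pytest.raises(ValueError):
            grow_until(params, state, 1.0e3, t_max=10.0)


class TestInvariants:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_state_stays_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 3, 3
        params = CommunityParameters(
            r0=rng.uniform(-0.05, 0.15, n),
            rho=np.where(rng.random((n, m)) < 0.6,
                         rng.uniform(-0.5, 0.5, (n, m)), 0.0),
            K=rng.uniform(1.0e3, 2.0e4, (n, m)),
            alpha=np.zeros((m, n)),
            beta=rng.uniform(0.0, 0.2, (m, n)),
            depletable=np.zeros((m, n), dtype=bool))
        state = CommunityState(rng.uniform(0, 1.0e4, n), rng.uniform(0, 1.0e4, m))
        for _ in range(50):
            state = step(params, state, 0.01)
            assert np.all(state.S >= 0)
            assert np.all(state.C >= 0)

    def test_zero_interactions_reduce_to_exponential(self):
        params = build_community(3, 2, [0.08, 0.1, 0.12])
        state = CommunityState(np.full(3, 1.0e3), np.zeros(2))
        out, _ = grow_until(params, state, 1.0e30, t_max=10.0, dt=0.01)
        steps = round(out.t / 0.01)
        np.testing.assert_allclose(
            out.S, 1.0e3 * (1 + params.r0 * 0.01) ** steps, rtol=1e-9)

    def test_step_refinement_converges(self, quick_config):
        """Halving dt changes the end state by O(dt) on a mutualist pair."""
        params = mutualist_pair()
        finals = {}
        for dt in (0.01, 0.005):
            state = CommunityState(np.full(2, 5.0e3), np.zeros(2))
            out, reached = grow_until(params, state, 1.0e8, t_max=1.0e3, dt=dt)
            assert reached
            finals[dt] = out.S / out.S.sum()
        assert np.max(np.abs(finals[0.01] - finals[0.005])) < 0.01


class TestSerialization:
    def test_network_csv_round_trip(self):
        params = mutualist_pair()
        params.rho[0, 0] = -0.05  # add a self-restraint link for coverage
        params = CommunityParameters(
            r0=params.r0, rho=params.rho, K=params.K, alpha=params.alpha,
            beta=params.beta, depletable=params.depletable,
            inhibition_law="threshold", c_th=123.0, moser_n=2.0,
            facilitation_law="moser")
        buf = io.StringIO()
        write_network_csv(params, buf)
        buf.seek(0)
        back = read_network_csv(buf)
        np.testing.assert_allclose(back.r0, params.r0)
        np.testing.assert_allclose(back.rho, params.rho)
        np.testing.assert_allclose(back.beta, params.beta)
        np.testing.assert_allclose(back.alpha, params.alpha)
        assert np.array_equal(back.depletable, params.depletable)
        mask = params.rho != 0
        np.testing.assert_allclose(back.K[mask], params.K[mask])
        assert back.inhibition_law == "threshold"
        assert back.facilitation_law == "moser"
        assert back.c_th == 123.0
        assert back.moser_n == 2.0
        assert back.consumption == params.consumption

    def test_trajectory_long_format(self):
        params = mutualist_pair()
        state = CommunityState(np.full(2, 5.0e3), np.zeros(2))
        df = simulate_trajectory(params, state, t_end=1.0, dt=0.01,
                                 sample_every=50)
        assert set(df.columns) == {"t", "entity_type", "entity_id", "value"}
        assert set(df.entity_type) == {"species", "mediator"}
        # one row per entity per snapshot
        n_snapshots = df.t.nunique()
        assert len(df) == n_snapshots * 4
        assert df.t.max() == pytest.approx(1.0, abs=0.011)
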