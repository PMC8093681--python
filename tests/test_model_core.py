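"""Unit and property tests for the colonization model core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from radlabel.model_core import (CommunitySpec, ContinuousEquilibrium,
                                 DomainError, NoViableSpeciesError,
                                 ParameterError, StateError, TradeOff,
                                 continuous_density, critical_inferiority,
                                 dynamics_rhs, evaluate_tradeoff, gap_variant,
                                 integrate_to_steady_state, interval_frequency,
                                 make_positions, solve_equilibrium)
from conftest import spec_with_fecundities, tradeoff_through


class TestTradeOff:
    def test_linear_closed_form(self):
        assert evaluate_tradeoff(TradeOff.linear(1, 1, 2.5), 0.5) == pytest.approx(1.5)

    @pytest.mark.parametrize("tof,intercept", [
        (TradeOff.linear(1.3, 0.7), 1.3),
        (TradeOff.saturating(0.8, 2.0, 1.5), 0.8),
        (TradeOff.convex(1.1, 1.0, 2.0), 1.1),
    ])
    def test_intercept_at_zero(self, tof, intercept):
        assert tof(0.0) == pytest.approx(intercept)

    def test_saturating_approaches_asymptote(self):
        tof = TradeOff.saturating(a=1.0, c=2.0, k=8.0, x_hat=2.5)
        assert abs(tof(2.5) - 3.0) < 1e-6

    def test_domain_error(self):
        with pytest.raises(DomainError):
            TradeOff.linear()(3.0)

    def test_monotonicity_enforced(self):
        with pytest.raises(ParameterError):
            TradeOff.from_callable(lambda x: 2.0 - x, x_hat=2.5)
        with pytest.raises(ParameterError):
            TradeOff.from_callable(lambda x: x - 1.0, x_hat=2.5)  # not positive

    def test_finite_difference_matches_closed_form(self):
        closed = TradeOff.saturating(1.0, 2.0, 1.5)
        numeric = TradeOff.from_callable(
            lambda x: 1.0 + 2.0 * (1.0 - np.exp(-1.5 * x)), x_hat=2.5)
        x = np.linspace(0.05, 2.45, 7)
        assert np.allclose(numeric.derivative(x), closed.derivative(x), atol=1e-5)


class TestMakePositions:
    def test_even_intervals(self):
        pos = make_positions(5, 2.5)
        assert np.allclose(np.diff(pos), 0.5)

    def test_single_species(self):
        assert make_positions(1, 2.5) == pytest.approx([0.0])

    def test_relative_shift_moves_grid(self):
        h = 2.5 / 5
        assert np.allclose(make_positions(5, 2.5, relative_shift=0.4),
                           make_positions(5, 2.5) + 0.4 * h)

    def test_jitter_stays_within_half_interval(self):
        n, x_hat = 30, 2.5
        h = x_hat / n
        base = make_positions(n, x_hat)
        pos = make_positions(n, x_hat, perturbation="jitter_half_interval", seed=3)
        assert np.all(np.sort(np.abs(np.sort(pos) - base)) <= h + 1e-12)
        assert np.all(np.diff(pos) > 0)
        assert pos.min() >= 0 and pos.max() <= x_hat

    def test_uniform_random_sorted_in_domain(self):
        pos = make_positions(40, 2.5, perturbation="uniform_random", seed=9)
        assert np.all(np.diff(pos) > 0)
        assert pos.min() >= 0 and pos.max() <= 2.5

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            make_positions(5, 2.5, relative_shift=1.5)
        with pytest.raises(ParameterError):
            make_positions(0, 2.5)
        with pytest.raises(ParameterError):
            make_positions(5, 2.5, perturbation="wobble")


class TestEquilibrium:
    def test_single_species(self):
        spec = spec_with_fecundities([2.0])
        assert solve_equilibrium(spec).frequencies == pytest.approx([0.5])

    def test_all_below_threshold_extinct(self):
        spec = spec_with_fecundities([0.3, 0.5, 0.8])
        eq = solve_equilibrium(spec)
        assert np.all(eq.frequencies == 0)
        assert eq.empty_fraction == pytest.approx(1.0)

    def test_quasi_exclusion_example(self, quasi_exclusion_spec):
        eq = solve_equilibrium(quasi_exclusion_spec)
        assert eq.frequencies == pytest.approx([0.5, 0.1, 0.0])

    def test_serrated_example(self, serrated_spec):
        eq = solve_equilibrium(serrated_spec)
        assert eq.frequencies == pytest.approx([0.5, 0.0, 1.0 / 6.0])

    def test_first_survivor_clears_mq_threshold(self):
        spec = spec_with_fecundities([0.5, 0.9, 1.4, 2.0])
        eq = solve_equilibrium(spec)
        first = int(np.flatnonzero(eq.survivors)[0])
        assert spec.fecundities[first] > spec.m / spec.q
        assert np.all(spec.fecundities[:first] <= spec.m / spec.q)

    @given(st.lists(st.floats(min_value=0.05, max_value=3.0),
                    min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_recursion_is_fixed_point(self, increments):
        f = 0.4 + np.cumsum(increments)
        spec = spec_with_fecundities(
            f, positions=0.1 + 2.3 * np.arange(f.size) / f.size)
        eq = solve_equilibrium(spec)
        assert np.all(eq.frequencies >= 0)
        assert eq.frequencies.sum() <= 1 + 1e-12
        assert np.max(np.abs(dynamics_rhs(spec, eq.frequencies))) < 1e-9


class TestDynamics:
    def test_extinction_absorbing(self, quasi_exclusion_spec):
        rhs = dynamics_rhs(quasi_exclusion_spec, np.zeros(3))
        assert np.all(rhs == 0)

    def test_equilibrium_is_fixed_point(self, quasi_exclusion_spec):
        rhs = dynamics_rhs(quasi_exclusion_spec, np.array([0.5, 0.1, 0.0]))
        assert np.max(np.abs(rhs)) < 1e-12

    def test_state_validation(self, quasi_exclusion_spec):
        with pytest.raises(StateError):
            dynamics_rhs(quasi_exclusion_spec, np.array([-0.1, 0.1, 0.0]))
        with pytest.raises(StateError):
            dynamics_rhs(quasi_exclusion_spec, np.array([0.6, 0.5, 0.2]))


class TestSteadyState:
    def test_single_species_logistic(self):
        spec = spec_with_fecundities([2.0])
        eq = integrate_to_steady_state(spec, p0=np.array([1e-3]))
        assert eq.converged
        assert eq.frequencies == pytest.approx([0.5], abs=1e-8)

    def test_matches_recursion(self, quasi_exclusion_spec):
        ode = integrate_to_steady_state(quasi_exclusion_spec)
        assert np.allclose(ode.frequencies, [0.5, 0.1, 0.0], atol=1e-6)

    def test_m_zero_top_competitor_takes_all(self, linear_tradeoff):
        spec = CommunitySpec(make_positions(8, 2.5), m=0.0, q=1.0,
                             trade_off=linear_tradeoff)
        rec = solve_equilibrium(spec)
        assert int(rec.survivors.sum()) == 1
        ode = integrate_to_steady_state(spec, t_max=1e6)
        for eq in (rec, ode):
            assert int(np.sum(eq.frequencies > 1e-9)) == 1
            assert eq.frequencies[0] == pytest.approx(1.0, abs=1e-6)
            assert eq.empty_fraction == pytest.approx(0.0, abs=1e-6)

    def test_random_specs_agree_with_recursion(self):
        rng = np.random.default_rng(20210316)
        for _ in range(15):
            n = int(rng.integers(2, 12))
            f = 0.5 + np.cumsum(rng.uniform(0.05, 1.0, size=n))
            spec = spec_with_fecundities(
                f, m=rng.uniform(0.2, 1.5),
                positions=np.sort(rng.uniform(0.05, 2.45, size=n)))
            ode = integrate_to_steady_state(spec)
            assert ode.converged
            assert np.allclose(ode.frequencies,
                               solve_equilibrium(spec).frequencies, atol=1e-6)


class TestContinuousSolution:
    def test_critical_inferiority_linear_root(self, linear_tradeoff):
        assert critical_inferiority(linear_tradeoff, 1.5, 1.0) == \
            pytest.approx(0.5, abs=1e-9)

    def test_critical_inferiority_clamped(self, linear_tradeoff):
        assert critical_inferiority(linear_tradeoff, 0.5, 1.0) == 0.0

    def test_no_viable_species(self, linear_tradeoff):
        with pytest.raises(NoViableSpeciesError):
            critical_inferiority(linear_tradeoff, 4.0, 1.0)

    def test_density_linear_closed_form(self, linear_tradeoff):
        ce = ContinuousEquilibrium(linear_tradeoff, 1.0, 1.0)
        assert continuous_density(ce, 0.0) == pytest.approx(0.5)
        x = 1.2
        assert continuous_density(ce, x) == pytest.approx(0.5 * (1 + x) ** -1.5)

    def test_zero_width_interval(self, linear_tradeoff):
        ce = ContinuousEquilibrium(linear_tradeoff, 1.0, 1.0)
        assert interval_frequency(ce, 0.7, 0.0) == 0.0

    def test_full_interval_closed_form(self, strong_saturating_tradeoff):
        ce = ContinuousEquilibrium(strong_saturating_tradeoff, 1.0, 1.0)
        full = interval_frequency(ce, ce.x_c, ce.trade_off.x_hat - ce.x_c)
        assert full == pytest.approx(ce.total_frequency, abs=1e-10)

    def test_interval_example_arithmetic(self, linear_tradeoff):
        ce = ContinuousEquilibrium(linear_tradeoff, 1.5, 1.0)  # x_c = 0.5
        expected = (1.5 ** -0.5 - 3.5 ** -0.5) * np.sqrt(1.5)
        assert interval_frequency(ce, 0.5, 2.0) == pytest.approx(expected)

    @pytest.mark.parametrize("tof", [
        TradeOff.linear(1, 1, 2.5),
        TradeOff.saturating(1, 2.5, 3, 2.5),
        TradeOff.sigmoid(1, 3, 4, 1.25, 2.5),
    ], ids=["linear", "concave", "sigmoid"])
    def test_density_integrates_to_interval_frequency(self, tof):
        ce = ContinuousEquilibrium(tof, 1.0, 1.0)
        rng = np.random.default_rng(5)
        for _ in range(25):
            a, b = np.sort(rng.uniform(ce.x_c, tof.x_hat, size=2))
            num = quad(lambda x: continuous_density(ce, x), a, b,
                       epsabs=1e-12, epsrel=1e-12)[0]
            assert num == pytest.approx(interval_frequency(ce, a, b - a),
                                        abs=1e-8)

    def test_domain_errors(self, linear_tradeoff):
        ce = ContinuousEquilibrium(linear_tradeoff, 1.5, 1.0)  # x_c = 0.5
        with pytest.raises(DomainError):
            continuous_density(ce, 0.2)
        with pytest.raises(DomainError):
            interval_frequency(ce, 0.6, 3.0)


class TestGapVariant:
    def test_identity_at_unit_rate(self, quasi_exclusion_spec):
        assert gap_variant(quasi_exclusion_spec, 1.0).q == quasi_exclusion_spec.q

    def test_equivalent_to_rescaled_encounter_rate(self, quasi_exclusion_spec):
        g = 0.7
        gap = gap_variant(quasi_exclusion_spec, g)
        direct = CommunitySpec(quasi_exclusion_spec.positions,
                               quasi_exclusion_spec.m,
                               quasi_exclusion_spec.q * g,
                               quasi_exclusion_spec.trade_off)
        assert np.allclose(solve_equilibrium(gap).frequencies,
                           solve_equilibrium(direct).frequencies)

    def test_single_species_hand_value(self):
        spec = spec_with_fecundities([2.0], m=1.0, q=2.0)
        eq = solve_equilibrium(gap_variant(spec, 0.5))
        assert eq.frequencies == pytest.approx([0.5])  # 1 - m/(q g f)

    def test_invalid_rate(self, quasi_exclusion_spec):
        with pytest.raises(ParameterError):
            gap_variant(quasi_exclusion_spec, 0.0)
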