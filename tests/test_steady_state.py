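"""Steady-state solver vs oracles, activation curves, Hill fitting."""

import numpy as np
import pytest

import thinfil as tf
from thinfil.exceptions import FitDomainError, ParameterError

from conftest import equilibrium_oracle


class TestSolveSteadyState:
    def test_rest_state_matches_quadratic_closed_form(self, constants):
        # with K0'=0 and ca=0 only B1 is populated and K1*C*T1 = B1 with
        # C = T1 = 1 - B1 gives the quadratic 800*(1-B1)^2 = B1
        k = tf.with_condition_k0p(constants, 0.0)
        state = tf.solve_steady_state(k, 0.0)
        b1_closed = 1.0 - (-1.0 + np.sqrt(1.0 + 4.0 * constants.K1)) / (2 * constants.K1)
        assert state.B1 == pytest.approx(b1_closed, abs=1e-8)
        assert state.B1 == pytest.approx(0.9653, abs=2e-4)
        assert state.C == pytest.approx(state.T1, abs=1e-8)
        for name in ("B2", "B3", "T2", "T3", "M"):
            assert getattr(state, name) == pytest.approx(0.0, abs=1e-8)

    def test_rigor_thirds_at_reciprocal_affinity(self, constants):
        # K0' = 1e6 drives C ~ 0, decoupling Tn into the two-step chain;
        # at ca = 1/K2 all three T states are equally populated
        k = tf.with_condition_k0p(constants, 1e6)
        state = tf.solve_steady_state(k, 1.0 / constants.K2)
        assert state.T1 == pytest.approx(1.0 / 3.0, abs=1e-4)
        assert state.T2 == pytest.approx(1.0 / 3.0, abs=1e-4)
        assert state.T3 == pytest.approx(1.0 / 3.0, abs=1e-4)
        assert state.ca_bound_tn == pytest.approx(2.0 / 3.0, abs=1e-4)

    def test_saturating_ca_fills_t_states(self, constants):
        # at saturating Ca2+ essentially all Tn is Ca2+-bound; the doubly
        # bound states dominate, split between B3 and T3 according to the
        # residual coupling K5 (B3/T3 = K1*(K4/K2)^2*C = 8*C, closed by
        # Tm conservation: 8*C^2 + C = 1)
        import numpy as np
        k = tf.with_condition_k0p(constants, 0.0)
        state = tf.solve_steady_state(k, 1e3)
        assert state.ca_bound_tn > 0.99
        c_closed = (-1.0 + np.sqrt(33.0)) / 16.0
        assert state.C == pytest.approx(c_closed, abs=1e-3)
        assert state.B_total == pytest.approx(1.0 - c_closed, abs=1e-3)

    @pytest.mark.parametrize("k0p", [0.0, 1.0, 1e6])
    def test_relaxation_matches_brute_force_oracle(self, constants, k0p):
        k = tf.with_condition_k0p(constants, k0p)
        for ca in (0.0, 0.3, 2.0, 30.0):
            relaxed = tf.solve_steady_state(k, ca)
            oracle = equilibrium_oracle(constants, ca, k0p)
            for name in ("B1", "B2", "B3", "T2", "T3", "M"):
                assert getattr(relaxed, name) == pytest.approx(
                    getattr(oracle, name), abs=1e-8
                ), f"{name} mismatch at ca={ca}, K0p={k0p}"

    @pytest.mark.parametrize("k0p", [0.0, 1.0, 1e6])
    def test_relaxation_matches_algebraic_fixed_point(self, constants, k0p):
        k = tf.with_condition_k0p(constants, k0p)
        for ca in np.logspace(-2, 2, 20):
            relaxed = tf.solve_steady_state(k, float(ca)).to_array()
            roots = tf.equilibrium_roots(k, float(ca))
            assert roots, f"no algebraic root at ca={ca}"
            best = min(
                np.max(np.abs(r.to_array() - relaxed)) for r in roots
            )
            assert best < 1e-6

    def test_negative_ca_rejected(self, constants):
        with pytest.raises(ParameterError):
            tf.solve_steady_state(constants, -1.0)


class TestComputeCurve:
    def test_binding_curve_monotone_without_crossbridges(self, constants):
        k = tf.with_condition_k0p(constants, 0.0)
        curve = tf.compute_curve(k, quantity="ca_bound_tn")
        assert np.all(np.diff(curve.values) >= -1e-10)

    def test_activation_curve_monotone_standard_conditions(self, constants):
        curve = tf.compute_curve(constants, quantity="M")
        assert np.all(np.diff(curve.values) >= -1e-10)

    def test_rigor_curve_equals_chain_closed_form(self, constants):
        k = tf.with_condition_k0p(constants, 1e6)
        curve = tf.compute_curve(k, quantity="ca_bound_tn")
        closed = tf.chain_binding_closed_form(constants, curve.ca_grid)
        assert np.max(np.abs(curve.values - closed)) < 1e-4

    def test_cycling_curve_steeper_than_equilibrium_curve(self, constants):
        """Cycling crossbridges make binding a cooperative function of Ca2+."""
        cyc = tf.hill_fit(tf.compute_curve(constants, quantity="ca_bound_tn"))
        equ = tf.hill_fit(
            tf.compute_curve(tf.with_condition_k0p(constants, 0.0),
                             quantity="ca_bound_tn")
        )
        assert cyc.n_hill > 1.0
        assert cyc.n_hill > equ.n_hill + 0.3


class TestHillFit:
    def test_exact_hill_one_input(self):
        grid = np.logspace(-2, 2, 60)
        curve = tf.ActivationCurve(grid, grid / (0.5 + grid), "synthetic")
        fit = tf.hill_fit(curve)
        assert fit.converged
        assert fit.n_hill == pytest.approx(1.0, abs=0.01)
        assert fit.k_half == pytest.approx(0.5, rel=0.01)

    def test_exact_hill_two_input(self):
        grid = np.logspace(-2, 2, 60)
        curve = tf.ActivationCurve(grid, grid ** 2 / (0.25 + grid ** 2), "synthetic")
        fit = tf.hill_fit(curve)
        assert fit.n_hill == pytest.approx(2.0, abs=0.01)
        assert fit.k_half == pytest.approx(0.5, rel=0.01)

    def test_curve_not_spanning_transition_rejected(self):
        grid = np.logspace(1, 2, 20)  # far above k_half: no transition sampled
        curve = tf.ActivationCurve(grid, grid / (0.5 + grid), "synthetic")
        with pytest.raises(FitDomainError):
            tf.hill_fit(curve)

    def test_noncooperative_limits_fit_well_below_cycling(self, constants):
        """The no-crossbridge and rigor curves are near-mass-action.

        Both are two-step chains with equal stepwise constants; their fitted
        Hill coefficients sit near the theoretical 4/3 of such a chain, far
        below the steeply cooperative cycling curve.
        """
        fits = {}
        for label, k0p in (("none", 0.0), ("rigor", 1e6)):
            k = tf.with_condition_k0p(constants, k0p)
            fits[label] = tf.hill_fit(tf.compute_curve(k, quantity="ca_bound_tn"))
        cycling = tf.hill_fit(tf.compute_curve(constants, quantity="ca_bound_tn"))
        assert 1.0 < fits["none"].n_hill < 1.5
        assert 1.0 < fits["rigor"].n_hill < 1.5
        assert cycling.n_hill > 1.9
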