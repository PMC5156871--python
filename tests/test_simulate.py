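"""Integration accuracy, stability classification, equilibria, and the scan."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from spherocycle import simulate
from spherocycle.model_core import (
    ModelDomainError,
    MonolayerParams,
    MonolayerState,
    SpheroidState,
)

rates = st.floats(0.01, 5.0)


class TestIntegrate:
    def test_zero_initial_state_stays_zero(self, printed_rates, spheroid_params):
        traj = simulate.integrate("monolayer", printed_rates, [0, 0, 0],
                                  (0, 1), t_eval=[0, 1])
        assert traj.states.max() == 0.0
        traj = simulate.integrate("spheroid", spheroid_params, [0, 0, 0, 0, 0],
                                  (0, 5), t_eval=[5])
        assert traj.states.max() == 0.0

    def test_matches_matrix_exponential(self, printed_rates, mono_init):
        # the linear model has a closed-form solution; the adaptive solver
        # must agree with it to its requested tolerance
        traj = simulate.integrate("monolayer", printed_rates, mono_init,
                                  (0, 1), t_eval=[1.0])
        exact = simulate.propagate_monolayer(printed_rates, mono_init, 1.0)
        assert traj.states[-1] == pytest.approx(exact.as_array(), rel=1e-6)

    def test_tolerance_halving_invariance(self, spheroid_params, spheroid_init):
        t1 = simulate.integrate("spheroid", spheroid_params, spheroid_init,
                                (0, 29), t_eval=[29])
        t2 = simulate.integrate("spheroid", spheroid_params, spheroid_init,
                                (0, 29), t_eval=[29], rtol=5e-9, atol=5e-11)
        assert t2.states[-1] == pytest.approx(t1.states[-1], rel=1e-4)

    def test_scheme_invariance(self, spheroid_params, spheroid_init):
        lsoda = simulate.integrate("spheroid", spheroid_params, spheroid_init,
                                   (0, 29), t_eval=[29])
        radau = simulate.integrate("spheroid", spheroid_params, spheroid_init,
                                   (0, 29), t_eval=[29], method="Radau")
        assert radau.states[-1] == pytest.approx(lsoda.states[-1], rel=1e-4)

    def test_nonnegativity_preserved(self, spheroid_params, spheroid_init):
        traj = simulate.integrate("spheroid", spheroid_params, spheroid_init,
                                  (0, 100), t_eval=np.linspace(0, 100, 201))
        assert traj.states.min() >= 0.0

    def test_boundedness_below_twice_equilibrium(
        self, spheroid_params, spheroid_init, control_equilibrium
    ):
        """Spheroid growth saturates: T(t) stays below 2 T* for all t."""
        traj = simulate.integrate("spheroid", spheroid_params, spheroid_init,
                                  (0, 400), t_eval=np.linspace(0, 400, 401))
        assert traj.totals().max() < 2 * control_equilibrium.state.T

    def test_negative_init_rejected(self, printed_rates):
        with pytest.raises(ModelDomainError):
            simulate.integrate("monolayer", printed_rates, [-1, 0, 0], (0, 1))

    def test_empty_span_rejected(self, printed_rates):
        with pytest.raises(ModelDomainError):
            simulate.integrate("monolayer", printed_rates, [1, 1, 1], (1, 1))


class TestMonolayerSummary:
    def test_phase_percents_sum_to_100(self, printed_rates, mono_init):
        traj = simulate.integrate("monolayer", printed_rates, mono_init,
                                  (0, 1), t_eval=[0, 1])
        s = simulate.monolayer_summary(traj, 1.0)
        assert s["pct_g1"] + s["pct_s"] + s["pct_g2"] == pytest.approx(100.0, abs=1e-9)

    @pytest.mark.parametrize("convention", simulate.MORTALITY_CONVENTIONS)
    def test_control_mortality_is_zero(self, printed_rates, mono_init, convention):
        traj = simulate.integrate("monolayer", printed_rates, mono_init,
                                  (0, 1), t_eval=[1.0])
        assert simulate.monolayer_summary(traj, 1.0, convention)["mortality"] == 0.0

    def test_time_outside_range_rejected(self, printed_rates, mono_init):
        traj = simulate.integrate("monolayer", printed_rates, mono_init,
                                  (0, 1), t_eval=[0, 1])
        with pytest.raises(ModelDomainError):
            simulate.monolayer_summary(traj, 0.5)

    def test_unknown_convention_rejected(self, printed_rates, mono_init):
        traj = simulate.integrate("monolayer", printed_rates, mono_init,
                                  (0, 1), t_eval=[1.0])
        with pytest.raises(ModelDomainError):
            simulate.monolayer_summary(traj, 1.0, "bogus")


class TestStability:
    def test_control_persists(self, printed_rates):
        rep = simulate.classify_monolayer_stability(printed_rates)
        assert rep.verdict == "persists"
        assert rep.dominant_eigenvalue > 0

    def test_threshold_is_critical(self):
        rep = simulate.classify_monolayer_stability(MonolayerParams(1.0, 2.0, 1.5, 1.5))
        assert rep.verdict == "critical"
        assert rep.dominant_eigenvalue == pytest.approx(0.0, abs=1e-9)

    def test_overwhelming_apoptosis_dies_out(self):
        rep = simulate.classify_monolayer_stability(MonolayerParams(0.85, 1.59, 0.5, 1.3))
        assert rep.verdict == "dies_out"
        assert rep.dominant_eigenvalue < 0

    @given(c1=rates, cS=rates, c2=rates, da=st.floats(0.0, 5.0))
    def test_verdict_matches_eigenvalue_sign(self, c1, cS, c2, da):
        """The algebraic threshold agrees with the spectral one."""
        rep = simulate.classify_monolayer_stability(MonolayerParams(c1, cS, c2, da))
        if rep.verdict == "persists":
            assert rep.dominant_eigenvalue > -1e-9
        elif rep.verdict == "dies_out":
            assert rep.dominant_eigenvalue < 1e-9
        else:
            assert rep.dominant_eigenvalue == pytest.approx(0.0, abs=1e-9)

    def test_coefficient_signs(self, printed_rates):
        rep = simulate.classify_monolayer_stability(printed_rates)
        assert rep.a0 < 0  # persistence means a0 = c1 cS (da - c2) < 0
        assert rep.a1 > 0 and rep.a2 > 0


class TestEquilibrium:
    def test_two_method_agreement(self, spheroid_params, spheroid_init,
                                  control_equilibrium):
        by_integration = simulate.equilibrium_by_integration(
            spheroid_params, spheroid_init)
        assert control_equilibrium.state.as_array() == pytest.approx(
            by_integration.as_array(), rel=1e-3
        )

    def test_residual_below_tolerance(self, control_equilibrium):
        assert control_equilibrium.converged
        assert control_equilibrium.residual_norm < 1e-8

    def test_origin_stays_at_origin(self, spheroid_params):
        eq = simulate.solve_equilibrium(spheroid_params,
                                        guess=SpheroidState(0, 0, 0, 0, 0))
        assert eq.state.T == 0.0
        assert eq.converged

    def test_mass_balance_relation_holds(self, spheroid_params, control_equilibrium):
        resid = simulate.check_equilibrium_relation(control_equilibrium,
                                                    spheroid_params)
        assert resid < 1e-8

    def test_closed_form_relation_at_no_treatment(self, spheroid_params,
                                                  control_equilibrium):
        # da = 0: G2* = (m/c2) N* (sn + N*) / (sn - N*)
        s = control_equilibrium.state
        p = spheroid_params
        expected = (p.m / p.cycle.c2) * s.N * (p.sn + s.N) / (p.sn - s.N)
        assert s.G2 == pytest.approx(expected, rel=1e-8)

    def test_perturbed_state_has_residual(self, spheroid_params, control_equilibrium):
        from spherocycle.simulate import EquilibriumResult

        s = control_equilibrium.state
        shifted = EquilibriumResult(
            SpheroidState(s.G1, s.S, s.G2, s.Q, s.N + 1.0), 0.0, True)
        assert simulate.check_equilibrium_relation(shifted, spheroid_params) > 1e-3

    def test_singular_relation_rejected(self, spheroid_params):
        from spherocycle.simulate import EquilibriumResult

        eq = EquilibriumResult(SpheroidState(1, 1, 1, 1, spheroid_params.sn), 0.0, True)
        with pytest.raises(ModelDomainError):
            simulate.check_equilibrium_relation(eq, spheroid_params)


class TestBifurcationScan:
    def test_scan_structure_and_monotonicity(self, spheroid_params,
                                             control_equilibrium):
        curves = simulate.bifurcation_scan(
            spheroid_params, c2_scales=(1.0, 0.47),
            da_grids={1.0: np.linspace(0, 3.0, 16),
                      0.47: np.linspace(0, 1.5, 16)},
        )
        assert [c.c2_scale for c in curves] == [1.0, 0.47]
        for curve in curves:
            assert len(curve.equilibria) == len(curve.da_values)
            assert all(eq.converged for eq in curve.equilibria)
            n_values = np.array([eq.state.N for eq in curve.equilibria])
            assert np.all(np.diff(n_values) <= 1e-6)
        # the untreated point of the control curve is the control equilibrium
        assert curves[0].equilibria[0].state.as_array() == pytest.approx(
            control_equilibrium.state.as_array(), rel=1e-6, abs=1e-8
        )

    def test_critical_da_marked(self, spheroid_params):
        curves = simulate.bifurcation_scan(
            spheroid_params, c2_scales=(0.47,), da_grids={0.47: [0.0, 0.5]})
        assert curves[0].critical_da == pytest.approx(0.47 * 3.85)

    def test_empty_scales_rejected(self, spheroid_params):
        with pytest.raises(ModelDomainError):
            simulate.bifurcation_scan(spheroid_params, c2_scales=())
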