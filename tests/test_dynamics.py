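"""Time integration: phases, quasi-linearization, and oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from campfem.analytic import compartmental_timecourse
from campfem.dynamics import (
    Phase,
    SignalingParameters,
    SimulationConfig,
    advance_time_step,
    build_system,
    michaelis_menten_rate,
    phase_of,
    quasi_linearize,
    simulate,
)

from conftest import C_O, E_AC, K_M, V_MAX


def norm_sup_error(series: np.ndarray, reference: np.ndarray) -> float:
    """Sup-norm discrepancy normalized by the reference curve's maximum."""
    return float(np.abs(series - reference).max() / np.abs(reference).max())


class TestKinetics:
    def test_rate_at_km_is_half_maximal(self):
        assert michaelis_menten_rate(2.0, 0.295, 2.0) == pytest.approx(0.1475)

    def test_rate_zero_at_zero(self):
        assert michaelis_menten_rate(0.0, V_MAX, K_M) == 0.0

    def test_rate_saturates(self):
        assert michaelis_menten_rate(1e9, V_MAX, K_M) == pytest.approx(V_MAX, rel=1e-6)
        c = np.linspace(0, 20, 50)
        rates = michaelis_menten_rate(c, V_MAX, K_M)
        assert (np.diff(rates) > 0).all()
        assert (rates <= V_MAX).all()

    def test_negative_concentration_warns(self):
        with pytest.warns(UserWarning):
            michaelis_menten_rate(-0.1, V_MAX, K_M)

    def test_linearization_at_zero(self):
        a, b = quasi_linearize(0.0, V_MAX, K_M, E_AC)
        assert a == pytest.approx(V_MAX / K_M)
        assert b == pytest.approx(E_AC)

    def test_linearization_printed_values(self):
        a, b = quasi_linearize(2.0, 0.295, 2.0, 0.0)
        assert a == pytest.approx(0.036875)
        assert b == pytest.approx(-0.07375)

    @given(c1=st.floats(0.0, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_linearization_exact_at_expansion_point(self, c1):
        """a·C1 + (E_AC − b) equals M(C1): tangent-line consistency."""
        a, b = quasi_linearize(c1, V_MAX, K_M, E_AC)
        assert a * c1 + (E_AC - b) == pytest.approx(
            michaelis_menten_rate(c1, V_MAX, K_M), abs=1e-12
        )


class TestPhases:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (5.0, Phase.DIFFUSION_ONLY),
            (10.0, Phase.SYNTHESIS),  # closed on the left
            (15.0, Phase.SYNTHESIS),
            (20.0, Phase.SYNTHESIS_AND_DEGRADATION),
            (100.0, Phase.SYNTHESIS_AND_DEGRADATION),
        ],
    )
    def test_three_branches(self, t, expected):
        assert phase_of(t, 10.0, 20.0) is expected

    def test_simultaneous_start(self):
        assert phase_of(0.0, 0.0, 0.0) is Phase.SYNTHESIS_AND_DEGRADATION

    def test_degradation_before_synthesis_rejected(self):
        with pytest.raises(ValueError):
            SignalingParameters(D=1.0, t_s=20.0, t_d=10.0)

    def test_off_grid_switch_times_rejected(self):
        params = SignalingParameters(D=1.0, t_s=2.5, t_d=2.5)
        with pytest.raises(ValueError):
            SimulationConfig(dt=2.0, t_end=10.0).validate_phase_times(params)


class TestAdvanceStep:
    def test_uniform_state_without_loads_is_stationary(self, coarse_sphere_mesh):
        params = SignalingParameters(D=3.0)
        config = SimulationConfig(dt=1.0, t_end=1.0)
        system = build_system(coarse_sphere_mesh, params)
        c0 = np.full(coarse_sphere_mesh.n_nodes, C_O)
        c1, n_inner = advance_time_step(c0, system, params, config, 0.0)
        assert np.abs(c1 - c0).max() < 1e-14

    def test_degradation_steps_match_ode_at_first_order(self, coarse_sphere_mesh):
        """Stepping a uniform state tracks the well-mixed decay with O(Δt) error.

        The γ = 2/3 member of the implicit family is first-order accurate, so
        refining Δt by 4 must shrink the one-second error roughly fourfold.
        """
        params = SignalingParameters(D=3.0, V_max=V_MAX, K_M=K_M, C_o=C_O)
        system = build_system(coarse_sphere_mesh, params)
        ode = solve_ivp(
            lambda t, c: [-V_MAX * c[0] / (K_M + c[0])], (0, 1.0), [C_O],
            rtol=1e-12, atol=1e-14, method="Radau",
        ).y[0, -1]
        errors = {}
        for dt in (1.0, 0.25):
            config = SimulationConfig(dt=dt, t_end=1.0)
            c = np.full(coarse_sphere_mesh.n_nodes, C_O)
            for step in range(int(round(1.0 / dt))):
                c, _ = advance_time_step(c, system, params, config, step * dt)
            errors[dt] = np.abs(c - ode).max() / ode
        assert errors[1.0] < 5e-3
        assert errors[0.25] < 0.35 * errors[1.0]

    def test_no_degradation_converges_in_one_iteration(self, coarse_sphere_mesh):
        params = SignalingParameters(D=3.0, E_AC=E_AC, V_max=0.0)
        config = SimulationConfig(dt=1.0, t_end=1.0)
        system = build_system(coarse_sphere_mesh, params)
        c0 = np.full(coarse_sphere_mesh.n_nodes, C_O)
        _, n_inner = advance_time_step(c0, system, params, config, 0.0)
        assert n_inner == 1


class TestSimulate:
    def test_all_activity_off_stays_at_initial_level(self, coarse_sphere_mesh):
        params = SignalingParameters(D=30.0, C_o=C_O)
        course = simulate(
            coarse_sphere_mesh, params,
            SimulationConfig(dt=5.0, t_end=50.0, probe_node_ids=[0, 5]),
        )
        assert course.times[0] == 0.0
        for series in course.probes.values():
            assert np.allclose(series, C_O, atol=1e-13)

    def test_pure_synthesis_exactly_linear(self, coarse_sphere_mesh):
        params = SignalingParameters(D=30.0, E_AC=E_AC, V_max=0.0, C_o=C_O)
        course = simulate(
            coarse_sphere_mesh, params,
            SimulationConfig(dt=1.0, t_end=50.0, probe_node_ids=[0]),
        )
        expected = C_O + E_AC * course.times
        assert np.abs(course.probes[0] - expected).max() < 1e-9

    def test_compartmental_runs_stay_spatially_uniform(self, coarse_sphere_mesh):
        params = SignalingParameters(D=0.3, E_AC=E_AC, V_max=V_MAX, K_M=K_M, C_o=C_O)
        course = simulate(
            coarse_sphere_mesh, params, SimulationConfig(dt=2.0, t_end=100.0)
        )
        final = course.final_state
        assert final.max() - final.min() < 1e-9 * final.max()

    @pytest.mark.parametrize("diffusivity", [0.3, 300.0])
    def test_compartmental_independent_of_diffusivity_and_geometry(
        self, coarse_sphere_mesh, blob_mesh, diffusivity
    ):
        """Well-mixed response identical across D values and geometries."""
        config = SimulationConfig(dt=2.0, t_end=120.0, probe_node_ids=[0])
        results = []
        for mesh in (coarse_sphere_mesh, blob_mesh):
            params = SignalingParameters(
                D=diffusivity, E_AC=E_AC, V_max=V_MAX, K_M=K_M, C_o=C_O
            )
            course = simulate(mesh, params, config)
            results.append(course.probes[0])
        assert np.abs(results[0] - results[1]).max() < 1e-6 * np.abs(results[0]).max()

    def test_compartmental_matches_analytic_oracle(self, coarse_sphere_mesh):
        params = SignalingParameters(D=30.0, E_AC=E_AC, V_max=V_MAX, K_M=K_M, C_o=C_O)
        course = simulate(
            coarse_sphere_mesh, params,
            SimulationConfig(dt=1.0, t_end=300.0, probe_node_ids=[3]),
        )
        exact = compartmental_timecourse(course.times, E_AC, V_MAX, K_M, C_O)
        assert norm_sup_error(course.probes[3], exact) < 0.01

    def test_error_decreases_under_time_refinement(self, coarse_sphere_mesh):
        errors = []
        for dt in (10.0, 5.0, 1.0):
            params = SignalingParameters(D=30.0, E_AC=E_AC, V_max=V_MAX,
                                         K_M=K_M, C_o=C_O)
            course = simulate(
                coarse_sphere_mesh, params,
                SimulationConfig(dt=dt, t_end=300.0, probe_node_ids=[3]),
            )
            exact = compartmental_timecourse(course.times, E_AC, V_MAX, K_M, C_O)
            errors.append(norm_sup_error(course.probes[3], exact))
        assert errors[0] > errors[1] > errors[2]

    def test_mass_conserved_without_sources(self, coarse_sphere_mesh):
        params = SignalingParameters(D=30.0, C_o=C_O)
        system = build_system(coarse_sphere_mesh, params)
        rng = np.random.default_rng(3)
        c = C_O * (1.0 + 0.5 * rng.uniform(-1, 1, coarse_sphere_mesh.n_nodes))
        config = SimulationConfig(dt=2.0, t_end=2.0)
        total0 = float(system.K1 @ c @ np.ones(len(c)))
        for step in range(30):
            c, _ = advance_time_step(c, system, params, config, 2.0 * step)
        total = float(system.K1 @ c @ np.ones(len(c)))
        assert abs(total - total0) / abs(total0) < 1e-10

    def test_unconditional_stability_and_common_steady_state(self, coarse_sphere_mesh):
        finals = []
        for dt in (1.0, 5.0, 10.0):
            params = SignalingParameters(D=30.0, E_AC=E_AC, V_max=V_MAX,
                                         K_M=K_M, C_o=C_O)
            course = simulate(
                coarse_sphere_mesh, params,
                SimulationConfig(dt=dt, t_end=600.0, probe_node_ids=[0]),
            )
            series = course.probes[0]
            assert np.isfinite(series).all()
            assert series.max() < 10.0  # bounded well below divergence
            finals.append(series[-1])
        assert np.ptp(finals) < 1e-4 * finals[0]

    def test_first_order_limit_of_quasi_linearization(self, coarse_sphere_mesh):
        """K_M ≫ C reduces the saturating kinetics to linear decay e^{-t·V_max/K_M}."""
        k_m, v_max = 1e3, 59.0  # V_max/K_M = 0.059 1/s
        params = SignalingParameters(D=30.0, V_max=v_max, K_M=k_m, C_o=C_O)
        course = simulate(
            coarse_sphere_mesh, params,
            SimulationConfig(dt=0.1, t_end=60.0, probe_node_ids=[0]),
        )
        expected = C_O * np.exp(-0.059 * course.times)
        assert norm_sup_error(course.probes[0], expected) < 0.005

    def test_gamma_below_half_refused(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt=1.0, t_end=10.0, gamma=0.3)

    def test_delayed_start_flat_then_linear(self, coarse_sphere_mesh):
        params = SignalingParameters(
            D=10.0, V_max=V_MAX, K_M=K_M, C_o=C_O, t_s=10.0, t_d=20.0,
            face_fluxes={"plasma_membrane": 2.0},
        )
        course = simulate(
            coarse_sphere_mesh, params,
            SimulationConfig(dt=1.0, t_end=40.0, probe_node_ids=[0, 1, 2]),
        )
        for series in course.probes.values():
            pre = course.times < 10.0
            assert np.abs(series[pre] - C_O).max() < 1e-10
            # slope drops once degradation switches on at t_d
            slope = np.diff(series)
            synth_slope = slope[(course.times[1:] > 12) & (course.times[1:] <= 20)]
            late_slope = slope[course.times[1:] > 25]
            assert late_slope.mean() < synth_slope.mean()

    def test_membrane_source_orders_probes_by_distance(self, sphere_mesh):
        """Nodes nearer the membrane source hold higher steady concentrations."""
        radii = np.linalg.norm(sphere_mesh.nodes, axis=1)
        # one node per region: membrane, mid-cytosol, perinuclear
        idx = [
            int(np.argmin(np.abs(radii - target))) for target in (9.34, 7.3, 5.26)
        ]
        assert len(set(idx)) == 3
        params = SignalingParameters(
            D=3.0, V_max=V_MAX, K_M=K_M, C_o=C_O,
            face_fluxes={"plasma_membrane": 0.3611},
        )
        course = simulate(
            sphere_mesh, params,
            SimulationConfig(dt=2.0, t_end=400.0, probe_node_ids=idx),
        )
        outer, mid, inner = (course.probes[i][-1] for i in idx)
        assert outer > mid > inner
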