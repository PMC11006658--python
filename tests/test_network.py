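"""Matrix assembly, constraint projection, integration and steady states."""

import numpy as np
import pytest
from scipy.linalg import expm

from cranioflow.errors import ConfigurationError, ConstraintError
from cranioflow.network import (
    CompartmentalModel,
    ConstantPrescription,
    build_constraint_basis,
    starling_landis_flow,
)
from cranioflow.parameters import StarlingParams


class TestStarlingLandis:
    def test_baseline_filtration_matches_printed_flow(self):
        params = StarlingParams(k_cb=0.066, sigma_cb=1.0, pi_capillary=21.5, pi_brain=0.0)
        flow = starling_landis_flow(34.64, 11.2, params)
        assert flow == pytest.approx(0.12804, abs=1e-12)
        assert round(flow, 2) == 0.13

    def test_pure_hydraulic_flow_without_osmosis(self):
        params = StarlingParams(k_cb=0.5, sigma_cb=0.0, pi_capillary=21.5, pi_brain=0.0)
        assert starling_landis_flow(12.0, 10.0, params) == pytest.approx(1.0)

    def test_zero_at_the_filtration_balance_point(self):
        params = StarlingParams()
        assert starling_landis_flow(11.2 + 21.5, 11.2, params) == pytest.approx(0.0)

    def test_reabsorption_is_negative(self):
        params = StarlingParams()
        assert starling_landis_flow(20.0, 11.2, params) < 0.0


class TestMatrixAssembly:
    def test_two_compartment_fluidity_matrix(self, toy2_config):
        model = CompartmentalModel(toy2_config)
        z = model.assemble_fluidity_matrix()
        assert np.allclose(z, [[-2.0, 2.0], [2.0, -2.0]])

    def test_fluidity_rows_sum_to_zero_full_network(self, baseline_config):
        model = CompartmentalModel(baseline_config)
        z = model.assemble_fluidity_matrix()
        assert np.max(np.abs(z.sum(axis=1))) < 1e-12
        assert np.max(np.abs(z - z.T)) < 1e-12

    def test_two_compartment_compliance_matrix_with_self_term(self, toy2_config):
        model = CompartmentalModel(toy2_config)
        c = model.assemble_compliance_matrix(np.array([10.0, 5.0]))
        # pair C=3 contributes the Laplacian block; self C=1 adds to A's diagonal
        assert np.allclose(c, [[4.0, -3.0], [-3.0, 3.0]])

    def test_baseline_compliance_matrix_offdiagonals_are_edge_values(
        self, baseline_config
    ):
        model = CompartmentalModel(baseline_config)
        c = model.assemble_compliance_matrix(baseline_config.baseline_pressures())
        assert np.max(np.abs(c - c.T)) < 1e-12
        for edge in baseline_config.compliances:
            if edge.is_self:
                continue
            i, j = baseline_config.index(edge.a), baseline_config.index(edge.b)
            assert -c[i, j] == pytest.approx(edge.baseline_compliance, abs=1e-9)

    def test_net_inflow_vanishes_at_baseline(self, baseline_config):
        model = CompartmentalModel(baseline_config)
        inflow = model.net_inflow(0.0, baseline_config.baseline_pressures())
        interior = [
            i for i, name in enumerate(baseline_config.names)
            if name not in ("Central Arteries", "Central Veins", "Thoracic")
        ]
        assert np.max(np.abs(inflow[interior])) < 1e-6


class TestConstraintBasis:
    def test_single_row_null_direction(self):
        cs = build_constraint_basis(np.array([[1.0, 1.0]]))
        q = cs.Q
        assert q.shape == (2, 1)
        assert abs(abs(q[0, 0]) - 1 / np.sqrt(2)) < 1e-12
        assert np.allclose(cs.A @ q, 0.0, atol=1e-12)

    def test_identity_row_block_frees_remaining_coordinates(self):
        a = np.zeros((2, 5))
        a[0, 0] = 1.0
        a[1, 1] = 1.0
        cs = build_constraint_basis(a)
        assert cs.Q.shape == (5, 3)
        assert np.allclose(cs.Q.T @ cs.Q, np.eye(3), atol=1e-12)
        # constrained coordinates do not appear in the basis
        assert np.allclose(cs.Q[:2, :], 0.0)

    def test_rank_deficient_rows_rejected(self):
        a = np.array([[1.0, 1.0, 0.0], [2.0, 2.0, 0.0]])
        with pytest.raises(ConstraintError):
            build_constraint_basis(a)

    def test_cranial_volume_constraint_basis_is_orthonormal(self, baseline_config):
        model = CompartmentalModel(
            baseline_config, prescribed={"Thoracic": ConstantPrescription(-6.0)}
        )
        cs = model.constraints
        assert cs.A.shape[0] == 1
        assert np.max(np.abs(cs.Q.T @ cs.Q - np.eye(cs.Q.shape[1]))) <= 1e-12
        assert np.max(np.abs(cs.A @ cs.Q)) <= 1e-12
        assert cs.Q.shape[1] == model.n_state - 1

    def test_prescribing_a_constrained_compartment_is_rejected(self, baseline_config):
        with pytest.raises(ConfigurationError, match="ambiguous"):
            CompartmentalModel(
                baseline_config,
                prescribed={"Brain": ConstantPrescription(11.2)},
            )


class TestIntegration:
    def test_matrix_exponential_oracle_three_compartments(self, toy3_config):
        """Constant-coefficient linear network against the closed form."""
        model = CompartmentalModel(toy3_config, constrained=False)
        state = model.baseline_state()
        p0 = state.pressures.copy()
        c_inv = np.diag(1.0 / np.array([1.0, 2.0, 1.5]))
        a = c_inv @ model.assemble_fluidity_matrix()
        t_end = 2.0
        expected = expm(a * t_end) @ p0
        traj = model.integrate(state, (0.0, t_end), t_eval=[0.0, t_end],
                               rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(traj.pressures[-1] - expected)) < 1e-8

    def test_constraint_inactive_on_an_invariant_manifold(
        self, toy3_config, toy3_constrained_config
    ):
        """Total volume is conserved by the free dynamics, so adding the
        total-volume constraint row must not change the trajectory."""
        free = CompartmentalModel(toy3_config, constrained=False)
        constrained = CompartmentalModel(toy3_constrained_config, constrained=True)
        assert constrained.constraints.A.shape[0] == 1
        t_eval = np.linspace(0.0, 2.0, 21)
        kw = dict(t_eval=t_eval, rtol=1e-10, atol=1e-12)
        traj_free = free.integrate(free.baseline_state(), (0.0, 2.0), **kw)
        traj_con = constrained.integrate(constrained.baseline_state(), (0.0, 2.0), **kw)
        assert np.max(np.abs(traj_free.pressures - traj_con.pressures)) < 1e-8
        assert np.max(np.abs(traj_free.compartment_volumes
                             - traj_con.compartment_volumes)) < 1e-8
        assert np.max(traj_con.constraint_residual) <= 1e-10

    def test_closed_subnetwork_conserves_volume(self, toy3_config):
        """No forced flows: the interface/compartment volume derivatives sum
        to zero, so total stored volume stays at its initial value."""
        model = CompartmentalModel(toy3_config, constrained=False)
        state = model.baseline_state()
        traj = model.integrate(state, (0.0, 3.0), t_eval=np.linspace(0, 3, 13))
        totals = traj.compartment_volumes.sum(axis=1)
        assert np.max(np.abs(totals)) < 1e-9

    def test_interface_volumes_track_compliance_times_pressure_difference(
        self, toy2_config
    ):
        model = CompartmentalModel(toy2_config, constrained=False)
        state = model.baseline_state()
        traj = model.integrate(state, (0.0, 2.0), t_eval=[0.0, 2.0])
        d_pair = (traj.pressures[-1, 0] - traj.pressures[-1, 1]) - (
            traj.pressures[0, 0] - traj.pressures[0, 1]
        )
        # constant compliance: V_ab = C_ab * d(P_a - P_b)
        assert traj.interface_volumes[-1, 0] == pytest.approx(3.0 * d_pair, abs=1e-8)
        assert traj.interface_volumes[-1, 1] == pytest.approx(
            1.0 * (traj.pressures[-1, 0] - traj.pressures[0, 0]), abs=1e-8
        )

    def test_baseline_steady_state_persists_for_an_hour(self, baseline_config):
        model = CompartmentalModel(
            baseline_config,
            prescribed={
                "Thoracic": ConstantPrescription(-6.0),
                "Central Arteries": ConstantPrescription(92.0),
                "Central Veins": ConstantPrescription(5.0),
            },
        )
        s0 = model.baseline_state()
        traj = model.integrate(s0, (0.0, 60.0), t_eval=np.linspace(0, 60, 61))
        assert np.max(np.abs(traj.pressures - s0.pressures[None, :])) < 1e-6

    def test_halving_tolerances_leaves_icp_trace_unchanged(self, baseline_config):
        """Integration convergence self-test on the ramp transient."""
        from cranioflow.experiments import ThoracicProfile

        profile = ThoracicProfile()
        model = CompartmentalModel(
            baseline_config,
            prescribed={
                "Thoracic": profile,
                "Central Arteries": ConstantPrescription(92.0),
                "Central Veins": ConstantPrescription(5.0),
            },
        )
        t_eval = np.linspace(0.0, 1.0, 101)
        icp = {}
        for rtol, atol in [(1e-8, 1e-8), (5e-9, 5e-9)]:
            s0 = model.baseline_state()
            a = model.integrate(s0, (0.0, 1.0), t_eval=t_eval, rtol=rtol, atol=atol)
            b = model.integrate(a.final_state(), (1.0, 5.0),
                                t_eval=np.linspace(1, 5, 81), rtol=rtol, atol=atol)
            icp[rtol] = np.concatenate(
                [a.pressure("Ventricular CSF"), b.pressure("Ventricular CSF")]
            )
        assert np.max(np.abs(icp[1e-8] - icp[5e-9])) < 1e-4


class TestSteadyState:
    def test_baseline_boundary_conditions_recover_printed_pressures(
        self, baseline_config
    ):
        model = CompartmentalModel(baseline_config)
        ss = model.find_steady_state(
            boundary_conditions={
                "Central Arteries": 92.0,
                "Central Veins": 5.0,
                "Thoracic": -6.0,
            },
            method="root",
        )
        assert np.max(np.abs(ss.pressures - baseline_config.baseline_pressures())) < 1e-4

    def test_root_and_integration_methods_agree(self, baseline_config):
        model = CompartmentalModel(baseline_config)
        ss = model.find_steady_state(
            boundary_conditions={
                "Central Arteries": 92.0,
                "Central Veins": 5.0,
                "Thoracic": -6.0,
            },
            method="both",
        )
        assert np.max(np.abs(ss.pressures - baseline_config.baseline_pressures())) < 1e-4

    def test_sweep_corner_has_a_steady_state(self, baseline_config):
        model = CompartmentalModel(baseline_config)
        ss = model.find_steady_state(
            boundary_conditions={
                "Central Arteries": 98.0,
                "Central Veins": 8.0,
                "Thoracic": -6.0,
            },
            method="root",
        )
        assert np.all(np.isfinite(ss.pressures))
        icp = ss.pressures[baseline_config.index("Ventricular CSF")]
        assert 5.0 < icp < 20.0

    def test_steady_state_independent_of_initial_perturbation(self, baseline_config):
        model = CompartmentalModel(baseline_config)
        bc = {"Central Arteries": 92.0, "Central Veins": 5.0, "Thoracic": -6.0}
        reference = model.find_steady_state(boundary_conditions=bc, method="root")
        rng = np.random.default_rng(42)
        guess = model.baseline_state()
        interior = [
            i for i, name in enumerate(baseline_config.names) if name not in bc
        ]
        guess.pressures[interior] += rng.uniform(-1.0, 1.0, size=len(interior))
        perturbed = model.find_steady_state(
            boundary_conditions=bc, initial_guess=guess, method="root"
        )
        assert np.max(np.abs(perturbed.pressures - reference.pressures)) < 1e-6
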