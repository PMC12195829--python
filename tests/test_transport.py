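"""Transient coupled transport solver."""

import numpy as np
import pytest

from conftest import single_tet_model, straight_network, unit_box_mesh
from vasctrans.compounds import builtin_compound_table
from vasctrans.flow import FlowParameters, solve_flow
from vasctrans.geometry import GeometryRecipe, generate_geometry, generate_tissue_mesh
from vasctrans.model import BrainTransportModel
from vasctrans.transport import (
    BolusProfile,
    TimeSettings,
    TransportParameters,
    assemble_transport_operators,
    run_transport,
    steady_diffusion_solve,
    wellmixed_reduction,
)


def _lumped_system(rv=0.5, k_w=0.2, k_e=0.1):
    """Single-tet continuum-only system: a well-mixed two-compartment unit."""
    model = single_tet_model(rv=rv)
    params = TransportParameters(
        D_capillary=1.0, D_tissue=1.0, wall_permeability=k_w, clearance_rate=k_e
    )
    ops = assemble_transport_operators(model, None, None, params)
    return model, params, ops


class TestOperators:
    def test_single_element_matrices_match_hand_integration(self):
        """P1 operators on the reference tet equal the hand-integrated forms."""
        from vasctrans.fem import shape_gradients
        from vasctrans.transport import _continuum_operators

        model = single_tet_model(rv=None)
        grads, vols = shape_gradients(model.points, model.cells)
        mass, K, _ = _continuum_operators(
            model, np.ones(1), 2.5, None, grads, vols, floor=False
        )
        V = 1.0 / 6.0
        # grad N: N0 = 1-x-y-z, N1 = x, N2 = y, N3 = z
        G = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        K_hand = 2.5 * V * G @ G.T
        np.testing.assert_allclose(K.toarray(), K_hand, atol=1e-14)
        np.testing.assert_allclose(mass, np.full(4, V / 4.0), atol=1e-16)

    def test_uniform_field_stationary(self):
        """Uniform concentrations: zero diffusive flux, zero exchange, so the
        closed system stays exactly constant in time."""
        model, _, ops = _lumped_system(k_w=5.0, k_e=0.0)
        c0 = np.full(ops.size, 3.0)  # c_cap = c_tissue = 3 everywhere
        sol = run_transport(ops, BolusProfile(amplitude=0.0),
                            TimeSettings(total_time=10.0, n_steps=10), initial=c0)
        np.testing.assert_allclose(sol.c_cap, 3.0, atol=1e-12)
        np.testing.assert_allclose(sol.c_tissue, 3.0, atol=1e-12)

    def test_geometry_mismatch_rejected(self, small_geometry):
        net, model = small_geometry
        flow = solve_flow(net, model, FlowParameters())
        other = generate_tissue_mesh(
            GeometryRecipe(domain_shape="box", dimensions=(1, 1, 1), target_3d_elements=48)
        )
        other.rv_field = np.zeros(other.n_cells)
        from vasctrans.flow import ConfigurationError

        with pytest.raises(ConfigurationError, match="match"):
            assemble_transport_operators(other, net, flow, TransportParameters())


class TestTimeStepping:
    def test_zero_bolus_stays_zero(self, small_geometry):
        net, model = small_geometry
        flow = solve_flow(net, model, FlowParameters())
        ops = assemble_transport_operators(model, net, flow, TransportParameters())
        sol = run_transport(ops, BolusProfile(amplitude=0.0),
                            TimeSettings(total_time=100.0, n_steps=10))
        assert np.max(np.abs(sol.c_vessel)) == 0.0
        assert np.max(np.abs(sol.c_tissue)) == 0.0

    def test_closed_system_mass_conservation(self):
        """No boundaries, no clearance: total mass constant to < 1e-8 over 40
        steps despite diffusion and wall exchange."""
        model = unit_box_mesh(3)
        rng = np.random.default_rng(4)
        model.rv_field = rng.uniform(0.01, 0.2, model.n_cells)
        params = TransportParameters(
            D_capillary=0.5, D_tissue=0.05, wall_permeability=0.3, clearance_rate=0.0
        )
        ops = assemble_transport_operators(model, None, None, params)
        c0 = rng.uniform(0.0, 1.0, ops.size)
        sol = run_transport(ops, BolusProfile(amplitude=0.0),
                            TimeSettings(total_time=400.0, n_steps=40), initial=c0)
        mass = [float(ops.M @ np.concatenate([sol.c_cap[i], sol.c_tissue[i]]))
                for i in range(len(sol.times))]
        assert np.max(np.abs(np.asarray(mass) - mass[0])) / mass[0] < 1e-8

    def test_mass_ledger_identity(self, small_geometry):
        """Per-step budget closes: storage = in - out - clearance - adv loss."""
        net, model = small_geometry
        flow = solve_flow(net, model, FlowParameters())
        params = TransportParameters.for_compound(builtin_compound_table()[0])
        ops = assemble_transport_operators(model, net, flow, params)
        sol = run_transport(ops, BolusProfile(), TimeSettings())
        led = sol.mass_ledger
        scale = max(led["inflow"].abs().max(), led["storage_change"].abs().max())
        assert (led["residual"].abs() / scale).max() < 1e-8

    def test_boundedness(self, small_geometry):
        """Rectangular bolus of amplitude A keeps every nodal value within
        [-eps, A + eps], eps = 1e-6 A."""
        net, model = small_geometry
        flow = solve_flow(net, model, FlowParameters())
        params = TransportParameters.for_compound(builtin_compound_table()[1])
        ops = assemble_transport_operators(model, net, flow, params)
        A = 20.0
        sol = run_transport(ops, BolusProfile(amplitude=A), TimeSettings())
        eps = 1e-6 * A
        for field in (sol.c_vessel, sol.c_cap, sol.c_tissue):
            assert field.min() >= -eps
            assert field.max() <= A + eps


class TestTwoCompartmentOracle:
    def test_lumped_fe_matches_ode_oracle(self):
        """The single-tet FE configuration reproduces the independent RK4
        two-compartment integration to < 1e-4 relative."""
        rv, k_w, k_e = 0.5, 0.2, 0.1
        model, params, ops = _lumped_system(rv=rv, k_w=k_w, k_e=k_e)
        times = TimeSettings(total_time=20.0, n_steps=4000, theta=0.5)
        source = lambda t: 0.8 * np.exp(-0.2 * t)  # noqa: E731
        c0 = np.concatenate([np.full(4, 1.0), np.zeros(4)])
        sol = run_transport(ops, BolusProfile(amplitude=0.0), times,
                            initial=c0, capillary_source=source)
        t, c_cap_ref, c_tis_ref = wellmixed_reduction(
            params, BolusProfile(amplitude=0.0), times, phi_cap=rv,
            initial=(1.0, 0.0), source=source, n_substeps=40000,
        )
        scale = max(c_cap_ref.max(), 1e-12)
        assert np.max(np.abs(sol.c_cap[:, 0] - c_cap_ref)) / scale < 1e-4
        assert np.max(np.abs(sol.c_tissue[:, 0] - c_tis_ref)) / scale < 1e-4

    def test_equilibration_conserves_mass(self):
        """No clearance, no forcing: compartments equilibrate and the
        phi-weighted total is conserved."""
        params = TransportParameters(wall_permeability=0.5, clearance_rate=0.0)
        times = TimeSettings(total_time=100.0, n_steps=100)
        phi = 0.3
        t, c_cap, c_tis = wellmixed_reduction(
            params, BolusProfile(amplitude=0.0), times, phi_cap=phi, initial=(1.0, 0.0),
            source=lambda _: 0.0,
        )
        assert c_cap[-1] == pytest.approx(c_tis[-1], rel=1e-6)
        total = phi * c_cap + (1 - phi) * c_tis
        np.testing.assert_allclose(total, total[0], rtol=1e-9)

    def test_pure_clearance_exponential(self):
        """k_x = 0 decouples the tissue: c_t(t) = exp(-k_e t)."""
        params = TransportParameters(wall_permeability=0.0, clearance_rate=0.05)
        times = TimeSettings(total_time=50.0, n_steps=25)
        t, _, c_tis = wellmixed_reduction(
            params, BolusProfile(amplitude=0.0), times, initial=(0.0, 1.0),
            source=lambda _: 0.0,
        )
        np.testing.assert_allclose(c_tis, np.exp(-0.05 * t), rtol=1e-8)

    def test_doubling_clearance_lowers_auc(self):
        times = TimeSettings(total_time=100.0, n_steps=100)
        aucs = []
        for k_e in (0.02, 0.04):
            params = TransportParameters(wall_permeability=0.5, clearance_rate=k_e)
            t, _, c_tis = wellmixed_reduction(
                params, BolusProfile(amplitude=0.0), times, initial=(1.0, 0.0),
                source=lambda _: 0.0,
            )
            aucs.append(np.trapezoid(c_tis, t))
        assert aucs[1] < aucs[0]


class TestConvergence:
    def test_spatial_order_two(self):
        """Manufactured steady diffusion solution: L2 order >= 1.9 under
        mesh halving."""
        D = 0.7
        exact = lambda p: np.sin(np.pi * p[:, 0]) * np.sin(np.pi * p[:, 1]) * np.sin(np.pi * p[:, 2])  # noqa: E731
        forcing = lambda p: 3.0 * np.pi**2 * D * exact(p)  # noqa: E731
        errors = []
        for n in (4, 8):
            model = unit_box_mesh(n)
            pts = model.points
            boundary = np.nonzero(
                (np.min(pts, axis=1) < 1e-12) | (np.max(pts, axis=1) > 1 - 1e-12)
            )[0]
            u = steady_diffusion_solve(model, D, boundary, np.zeros(len(boundary)), forcing)
            from vasctrans.fem import lumped_node_volumes

            w = lumped_node_volumes(model.points, model.cells)
            errors.append(np.sqrt(np.sum(w * (u - exact(pts)) ** 2)))
        order = np.log2(errors[0] / errors[1])
        assert order >= 1.9

    def test_temporal_order_one_backward_euler(self):
        """Pure-decay configuration: backward Euler error halves with dt."""
        k_e = 0.2
        model, params, ops = _lumped_system(rv=0.5, k_w=0.0, k_e=k_e)
        errs = []
        for n in (20, 40, 80):
            c0 = np.concatenate([np.zeros(4), np.ones(4)])
            sol = run_transport(ops, BolusProfile(amplitude=0.0),
                                TimeSettings(total_time=10.0, n_steps=n), initial=c0)
            errs.append(abs(sol.c_tissue[-1, 0] - np.exp(-k_e * 10.0)))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders >= 0.9)


class TestCompoundRuns:
    def test_auc_strictly_decreasing_in_clearance(self, small_geometry):
        """Across the three built-in compounds at fixed geometry, tissue AUC
        reverses the clearance ordering."""
        net, model = small_geometry
        bm = BrainTransportModel(network=net, tissue=model)
        results = {c.name: bm.solve(c) for c in builtin_compound_table()}
        auc = {k: r.auc("tissue") for k, r in results.items()}
        # clearance: Galantamine < Ph3SnL2 < Ph3SnL1
        assert auc["Galantamine"] > auc["Ph3SnL2"] > auc["Ph3SnL1"]

    def test_qualitative_bolus_response(self, small_geometry):
        """Tissue mean rises during the bolus, peaks early, then decays
        toward zero by the end of the protocol."""
        net, model = small_geometry
        bm = BrainTransportModel(network=net, tissue=model)
        res = bm.solve(builtin_compound_table()[2])
        mt = res.mean_tissue
        peak_t = res.concentration.peak_time["tissue"]
        assert mt[0] == 0.0
        assert 0.0 < peak_t <= 100.0
        assert mt[-1] < 0.05 * res.concentration.peak_value["tissue"]


class TestProfiles:
    def test_bolus_values(self):
        b = BolusProfile(amplitude=20.0, duration=40.0)
        assert b.value(0.0) == 20.0
        assert b.value(40.0) == 20.0  # inclusive end
        assert b.value(40.1) == 0.0
        tri = BolusProfile(amplitude=10.0, duration=40.0, shape="triangular")
        assert tri.value(0.0) == 10.0
        assert tri.value(20.0) == pytest.approx(5.0)
        assert tri.value(41.0) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            BolusProfile(amplitude=-1.0)
        with pytest.raises(ValueError):
            BolusProfile(shape="gaussian")
        with pytest.raises(ValueError):
            TimeSettings(total_time=0.0)
        with pytest.raises(ValueError):
            TimeSettings(theta=0.3)
        with pytest.raises(ValueError):
            TransportParameters(D_tissue=0.0)
        assert TimeSettings().dt == pytest.approx(10.0)
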