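"""Steady coupled pressure solver."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from conftest import single_tet_model, straight_network, unit_box_mesh
from vasctrans.flow import (
    ConfigurationError,
    FlowParameters,
    assemble_darcy_system,
    assemble_pipe_system,
    segment_conductances,
    solve_flow,
)
from vasctrans.geometry import (
    GeometryError,
    GeometryRecipe,
    VesselNetwork,
    build_connectivity,
    compute_rv_field,
    generate_geometry,
    generate_tissue_mesh,
)
from vasctrans.units import mmhg_to_pa


def _boundary_fluxes(net, model, params, sol):
    """Boundary flux at each Dirichlet vessel node from the unconstrained rows."""
    g = segment_conductances(net, params.blood_viscosity)
    g_conn = params.connectivity_conductivity * model.conn_coeff
    flux = {}
    for d in np.concatenate([net.inlet_nodes, net.outlet_nodes]):
        f = 0.0
        for (a, b), gi in zip(net.segments, g):
            if a == d:
                f += gi * (sol.p_vessel[d] - sol.p_vessel[b])
            elif b == d:
                f += gi * (sol.p_vessel[d] - sol.p_vessel[a])
        for v, t, gc in zip(model.conn_vessel, model.conn_tissue, g_conn):
            if v == d:
                f += gc * (sol.p_vessel[d] - sol.p_cap[t])
        flux[int(d)] = f
    return flux


class TestPipeSystem:
    def test_poiseuille_closed_form(self):
        """Single segment flow matches q = pi r^4 dp / (8 mu L)."""
        net = straight_network([0.0, 0.0, 0.0], [1.0, 0.0, 0.0], radius=0.01)
        params = FlowParameters(
            blood_viscosity=1.0e-3,
            inlet_pressure=mmhg_to_pa(10.0),
            outlet_pressure=0.0,
        )
        A, b = assemble_pipe_system(net, params)
        p = spla.spsolve(A.tocsc(), b)
        g = segment_conductances(net, params.blood_viscosity)[0]
        q = g * (p[0] - p[1])
        expected = np.pi * 0.01**4 * 1333.22 / (8.0 * 1.0e-3 * 1.0)
        assert q == pytest.approx(expected, rel=1e-12)
        assert q == pytest.approx(5.236e-3, rel=1e-3)

    def test_uniform_pressure_no_flow(self):
        net = straight_network([0, 0, 0], [1, 0, 0])
        params = FlowParameters(inlet_pressure=500.0, outlet_pressure=500.0)
        A, b = assemble_pipe_system(net, params)
        p = spla.spsolve(A.tocsc(), b)
        assert np.allclose(p, 500.0)

    def test_series_conductance_halves(self):
        """Two identical segments in series carry half the single-segment flow."""
        one = straight_network([0, 0, 0], [1, 0, 0], radius=0.01)
        two = VesselNetwork(
            nodes=np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]),
            segments=np.array([[0, 1], [1, 2]]),
            radii=np.array([0.01, 0.01]),
            kinds=np.array(["capillary", "capillary"]),
            inlet_nodes=np.array([0]),
            outlet_nodes=np.array([2]),
        )
        params = FlowParameters(inlet_pressure=1000.0, outlet_pressure=0.0)
        flows = []
        for net in (one, two):
            A, b = assemble_pipe_system(net, params)
            p = spla.spsolve(A.tocsc(), b)
            g = segment_conductances(net, params.blood_viscosity)
            flows.append(g[0] * (p[net.segments[0, 0]] - p[net.segments[0, 1]]))
        assert flows[1] == pytest.approx(flows[0] / 2.0, rel=1e-12)

    def test_zero_length_segment_rejected(self):
        net = straight_network([0, 0, 0], [0, 0, 0])
        with pytest.raises(GeometryError, match="zero-length"):
            assemble_pipe_system(net, FlowParameters())


class TestDarcySystem:
    def test_1d_column_linear_profile(self):
        """Fixed end pressures on a bar give the linear Laplace solution."""
        recipe = GeometryRecipe(domain_shape="box", dimensions=(4.0, 0.5, 0.5),
                                target_3d_elements=200)
        model = generate_tissue_mesh(recipe)
        params = FlowParameters(darcy_mobility=1.0e-13)
        K = assemble_darcy_system(model, params, np.ones(model.n_cells)).tolil()
        x = model.points[:, 0]
        left, right = np.nonzero(x < 1e-9)[0], np.nonzero(x > 4.0 - 1e-9)[0]
        b = np.zeros(model.n_points)
        for d, val in [(left, 100.0), (right, 0.0)]:
            for n in d:
                K.rows[n] = [int(n)]
                K.data[n] = [1.0]
                b[n] = val
        p = spla.spsolve(K.tocsc(), b)
        expected = 100.0 * (1.0 - x / 4.0)
        assert np.max(np.abs(p - expected)) / 100.0 < 1e-10
        # discrete maximum principle: interior values inside the boundary range
        assert p.min() >= -1e-10 and p.max() <= 100.0 + 1e-10

    def test_zero_mobility_zero_matrix(self):
        model = unit_box_mesh(1)
        K = assemble_darcy_system(model, FlowParameters(darcy_mobility=0.0),
                                  np.ones(model.n_cells))
        assert K.nnz == 0 or np.all(K.data == 0)

    def test_constant_field_in_null_space(self):
        model = unit_box_mesh(2)
        K = assemble_darcy_system(model, FlowParameters(), np.ones(model.n_cells))
        assert np.max(np.abs(K @ np.full(model.n_points, 7.0))) < 1e-18


class TestCoupledSolve:
    def test_decoupling_limit_matches_pipe_solve(self, small_geometry):
        """leakage = 0 and zero connectivity reduce the vessel block to the
        standalone pipe network solve."""
        net, model = small_geometry
        params = FlowParameters(leakage_coefficient=0.0, connectivity_conductivity=0.0)
        sol = solve_flow(net, model, params)
        A, b = assemble_pipe_system(net, params)
        p_ref = spla.spsolve(A.tocsc(), b)
        np.testing.assert_allclose(sol.p_vessel, p_ref, rtol=1e-10, atol=1e-8)
        assert np.allclose(sol.p_cap, params.outlet_pressure)
        assert np.allclose(sol.p_tissue, params.outlet_pressure)

    def test_equal_boundary_pressures_constant_fields(self, small_geometry):
        net, model = small_geometry
        params = FlowParameters(inlet_pressure=1500.0, outlet_pressure=1500.0)
        sol = solve_flow(net, model, params)
        assert np.allclose(sol.p_vessel, 1500.0, atol=1e-8)
        assert np.allclose(sol.p_cap, 1500.0, atol=1e-8)
        assert np.allclose(sol.p_tissue, 1500.0, atol=1e-8)
        assert np.allclose(sol.q_segment, 0.0, atol=1e-12)

    def test_lumped_closed_form(self):
        """With kappa = 0 each mesh node solves a hand-computable balance:
        p_tissue = p_cap and p_cap is the conductance-weighted mean of the
        vessel pressures it couples to."""
        model = single_tet_model(rv=0.1)
        net = straight_network([0.1, 0.1, 0.1], [0.6, 0.1, 0.1], radius=0.02)
        build_connectivity(net, model, search_radius=10.0)  # couple to all nodes
        params = FlowParameters(darcy_mobility=0.0, inlet_pressure=2000.0,
                                outlet_pressure=1000.0)
        sol = solve_flow(net, model, params)
        g_conn = params.connectivity_conductivity * model.conn_coeff
        for tn in range(model.n_points):
            mask = model.conn_tissue == tn
            g = g_conn[mask]
            pv = sol.p_vessel[model.conn_vessel[mask]]
            expected = float(np.sum(g * pv) / np.sum(g))
            assert sol.p_cap[tn] == pytest.approx(expected, rel=1e-12)
            assert sol.p_tissue[tn] == pytest.approx(expected, rel=1e-12)

    def test_global_mass_balance(self, small_geometry):
        """Inlet inflow equals outlet outflow plus net transmural storage
        (zero at steady state) to < 1e-8 relative."""
        net, model = small_geometry
        params = FlowParameters()
        sol = solve_flow(net, model, params)
        flux = _boundary_fluxes(net, model, params, sol)
        inflow = sum(flux[int(d)] for d in net.inlet_nodes)
        outflow = -sum(flux[int(d)] for d in net.outlet_nodes)
        net_leak = float(sol.q_leak_node.sum())
        assert inflow > 0
        assert abs(inflow - outflow - net_leak) / inflow < 1e-8
        # net transmural exchange vanishes at steady state (closed tissue)
        assert abs(net_leak) / inflow < 1e-8

    def test_interior_pressures_within_bounds(self, small_geometry):
        net, model = small_geometry
        params = FlowParameters()
        sol = solve_flow(net, model, params)
        lo, hi = params.outlet_pressure, params.inlet_pressure
        for field in (sol.p_vessel, sol.p_cap, sol.p_tissue):
            assert field.min() >= lo - 1e-6
            assert field.max() <= hi + 1e-6

    def test_mirror_symmetry(self):
        """Symmetric mesh + symmetric BCs -> node-wise mirror-symmetric field."""
        from scipy.spatial import cKDTree

        from vasctrans.geometry import TissueModel

        # build an exactly y-mirror-symmetric mesh by reflecting a half box
        recipe = GeometryRecipe(domain_shape="box", dimensions=(2.0, 0.5, 1.0),
                                target_3d_elements=48)
        half = generate_tissue_mesh(recipe)
        pts = half.points
        refl = pts.copy()
        refl[:, 1] = 1.0 - refl[:, 1]
        on_plane = np.abs(pts[:, 1] - 0.5) < 1e-12
        remap = np.arange(len(pts))
        new_idx = []
        extra = []
        for i, p in enumerate(refl):
            if on_plane[i]:
                new_idx.append(i)
            else:
                new_idx.append(len(pts) + len(extra))
                extra.append(p)
        new_idx = np.asarray(new_idx)
        points = np.vstack([pts, np.asarray(extra)])
        mirrored_cells = new_idx[half.cells][:, [0, 2, 1, 3]]  # restore orientation
        model = TissueModel(points=points, cells=np.vstack([half.cells, mirrored_cells]))
        assert np.all(model.cell_volumes() > 0)
        model.rv_field = np.full(model.n_cells, 0.02)
        net = straight_network([0.2, 0.5, 0.5], [1.8, 0.5, 0.5], radius=0.02)
        build_connectivity(net, model, search_radius=10.0)
        sol = solve_flow(net, model, FlowParameters())
        mirror_pts = model.points.copy()
        mirror_pts[:, 1] = 1.0 - mirror_pts[:, 1]
        idx = cKDTree(model.points).query(mirror_pts)[1]
        scale = FlowParameters().inlet_pressure - FlowParameters().outlet_pressure
        assert np.max(np.abs(sol.p_tissue - sol.p_tissue[idx])) / scale < 1e-8
        assert np.max(np.abs(sol.p_cap - sol.p_cap[idx])) / scale < 1e-8

    def test_leakage_monotonicity(self, small_geometry):
        """Raising the leakage coefficient increases total transmural flow."""
        net, model = small_geometry
        totals = []
        for leak in (1e-12, 1e-11, 1e-10):
            sol = solve_flow(net, model, FlowParameters(leakage_coefficient=leak))
            totals.append(sol.total_transmural_flow)
        assert totals[0] < totals[1] < totals[2]

    def test_missing_dirichlet_rejected(self, small_geometry):
        net, model = small_geometry
        bad = VesselNetwork(
            nodes=net.nodes, segments=net.segments, radii=net.radii, kinds=net.kinds,
            inlet_nodes=np.empty(0, dtype=int), outlet_nodes=np.empty(0, dtype=int),
        )
        with pytest.raises(ConfigurationError, match="inlet"):
            solve_flow(bad, model, FlowParameters())

    def test_requires_rv_field(self, small_geometry):
        net, model = small_geometry
        from vasctrans.geometry import TissueModel

        bare = TissueModel(points=model.points, cells=model.cells)
        with pytest.raises(ConfigurationError, match="r_V"):
            solve_flow(net, bare, FlowParameters())
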