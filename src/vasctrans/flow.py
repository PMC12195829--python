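"""Steady coupled pressure problem.

Three pressure fields are solved simultaneously:

* ``p_vessel`` on the 1D network (Hagen-Poiseuille conductances
  ``g = pi r^4 / (8 mu L)`` per segment, Dirichlet values at inlets/outlets),
* ``p_cap`` — the smeared capillary continuum field (Darcy, weighted by the
  element capillary fraction ``r_V``), coupled to vessel nodes through the
  connectivity pairs,
* ``p_tissue`` — the interstitial field (Darcy, weighted by ``1 - r_V``),
  coupled to ``p_cap`` by a lumped transmural leakage conductance per unit
  tissue volume.

The printed whole-organ parameters are under-determined in units; here the
Darcy coefficient is a lumped mobility kappa in ``v = -kappa grad p``
(mm s^-1 per Pa mm^-1) and the leakage coefficient a volumetric transmural
conductance per unit volume (s^-1 Pa^-1).  Both are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import units
from .fem import lumped_node_volumes, shape_gradients
from .geometry import CAPILLARY, GeometryError, TissueModel, VesselNetwork

logger = logging.getLogger(__name__)

__all__ = ["FlowParameters", "PressureSolution", "assemble_pipe_system",
           "assemble_darcy_system", "solve_flow"]

#: floor applied to domain fractions during assembly so decoupled rows stay
#: invertible; physically inert at this magnitude
RV_FLOOR = 1.0e-6


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class FlowParameters:
    """Parameters of the steady flow problem (canonical mm / s / Pa units)."""

    blood_viscosity: float = 1.0e-3  # Pa*s, taken equal to water
    darcy_mobility: float = 1.0e-13  # mm^2 s^-1 Pa^-1, lumped mobility in v = -kappa grad p
    leakage_coefficient: float = 1.0e-11  # s^-1 Pa^-1, transmural conductance per volume
    inlet_pressure: float = units.mmhg_to_pa(20.0)  # Pa
    outlet_pressure: float = units.mmhg_to_pa(10.0)  # Pa
    connectivity_conductivity: float = 1.0e-8  # mm s^-1 Pa^-1 per unit coupling area

    def __post_init__(self) -> None:
        if self.blood_viscosity <= 0:
            raise ValueError("blood_viscosity must be > 0")
        if self.darcy_mobility < 0 or self.leakage_coefficient < 0:
            raise ValueError("darcy_mobility and leakage_coefficient must be >= 0")
        if self.connectivity_conductivity < 0:
            raise ValueError("connectivity_conductivity must be >= 0")


@dataclass
class PressureSolution:
    """Solved pressure fields plus derived fluxes."""

    p_vessel: np.ndarray  # Pa, per network node
    p_cap: np.ndarray  # Pa, per mesh node
    p_tissue: np.ndarray  # Pa, per mesh node
    q_segment: np.ndarray  # mm^3/s per segment, positive a -> b
    v_tissue: np.ndarray  # mm/s Darcy velocity per element
    v_cap: np.ndarray  # mm/s smeared capillary Darcy velocity per element
    q_leak_node: np.ndarray  # mm^3/s transmural flow per mesh node (cap -> tissue > 0)
    q_conn: np.ndarray  # mm^3/s per connectivity pair (vessel -> cap > 0)

    @property
    def total_transmural_flow(self) -> float:
        return float(np.sum(np.abs(self.q_leak_node)) / 2.0)


def segment_conductances(network: VesselNetwork, viscosity: float) -> np.ndarray:
    """Hagen-Poiseuille conductance per segment, mm^3 s^-1 Pa^-1."""
    lengths = network.segment_lengths()
    if np.any(lengths <= 0):
        raise GeometryError("zero-length vessel segment")
    return np.pi * network.radii**4 / (8.0 * viscosity * lengths)


def assemble_pipe_system(
    network: VesselNetwork, params: FlowParameters
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Nodal balance system for the 1D network with Dirichlet inlet/outlet rows.

    Returns ``(A, b)`` with ``A p = b``; interior rows are Kirchhoff balances,
    inlet/outlet rows fix the prescribed pressures.
    """
    n = network.n_nodes
    g = segment_conductances(network, params.blood_viscosity)
    a_idx, b_idx = network.segments[:, 0], network.segments[:, 1]
    rows = np.concatenate([a_idx, b_idx, a_idx, b_idx])
    cols = np.concatenate([a_idx, b_idx, b_idx, a_idx])
    vals = np.concatenate([g, g, -g, -g])
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    b = np.zeros(n)
    A, b = _apply_dirichlet(
        A.tolil(), b,
        np.concatenate([network.inlet_nodes, network.outlet_nodes]),
        np.concatenate([
            np.full(len(network.inlet_nodes), params.inlet_pressure),
            np.full(len(network.outlet_nodes), params.outlet_pressure),
        ]),
    )
    return A.tocsr(), b


def _apply_dirichlet(A_lil, b, nodes, values):
    for node, val in zip(nodes, values):
        A_lil.rows[node] = [int(node)]
        A_lil.data[node] = [1.0]
        b[node] = val
    return A_lil, b


def assemble_darcy_system(
    model: TissueModel, params: FlowParameters, fraction: np.ndarray
) -> sp.csr_matrix:
    """Galerkin stiffness of ``-div(kappa grad p)`` weighted by a domain fraction.

    ``fraction`` is the per-element volume fraction of the field's domain
    (``r_V`` for the capillary field, ``1 - r_V`` for tissue).  A constant
    field lies in the null space; boundary conditions arrive through the
    coupling terms or Dirichlet rows added by the caller.
    """
    grads, vols = shape_gradients(model.points, model.cells)
    bad = np.nonzero(vols <= 0)[0]
    if bad.size:
        raise GeometryError(f"degenerate element Jacobian in element(s) {bad[:5].tolist()}")
    kappa = params.darcy_mobility
    w = kappa * np.maximum(fraction, RV_FLOOR if kappa > 0 else 0.0) * vols
    # element stiffness: w_e * grad N_i . grad N_j
    ke = np.einsum("e,eik,ejk->eij", w, grads, grads)
    rows = np.repeat(model.cells, 4, axis=1).ravel()
    cols = np.tile(model.cells, (1, 4)).ravel()
    n = model.n_points
    return sp.csr_matrix((ke.ravel(), (rows, cols)), shape=(n, n))


def solve_flow(
    network: VesselNetwork, model: TissueModel, params: FlowParameters
) -> PressureSolution:
    """Solve the coupled vessel / capillary / tissue pressure block system."""
    if model.rv_field is None:
        raise ConfigurationError("r_V field not computed; run compute_rv_field first")
    if len(network.inlet_nodes) == 0 or len(network.outlet_nodes) == 0:
        raise ConfigurationError(
            "no Dirichlet pressure nodes: set inlet and outlet nodes on the network"
        )
    nv, nm = network.n_nodes, model.n_points
    rv = model.rv_field

    g = segment_conductances(network, params.blood_viscosity)
    a_idx, b_idx = network.segments[:, 0], network.segments[:, 1]
    A_vv = sp.csr_matrix(
        (
            np.concatenate([g, g, -g, -g]),
            (np.concatenate([a_idx, b_idx, a_idx, b_idx]),
             np.concatenate([a_idx, b_idx, b_idx, a_idx])),
        ),
        shape=(nv, nv),
    )
    K_cap = assemble_darcy_system(model, params, rv)
    K_tis = assemble_darcy_system(model, params, 1.0 - rv)

    # vessel <-> capillary connectivity conductances (per pair)
    g_conn = params.connectivity_conductivity * model.conn_coeff
    C_vc = sp.csr_matrix((g_conn, (model.conn_vessel, model.conn_tissue)), shape=(nv, nm))
    D_v = sp.diags(np.asarray(C_vc.sum(axis=1)).ravel())
    D_c = sp.diags(np.asarray(C_vc.sum(axis=0)).ravel())

    # capillary <-> tissue leakage, lumped per mesh node
    w_node = lumped_node_volumes(model.points, model.cells)
    g_leak = params.leakage_coefficient * w_node
    L = sp.diags(g_leak)

    cap_coupled = g_conn.sum() > 0 or params.leakage_coefficient > 0
    tis_coupled = params.leakage_coefficient > 0

    A = sp.bmat(
        [
            [A_vv + D_v, -C_vc, None],
            [-C_vc.T, K_cap + D_c + L, -L],
            [None, -L, K_tis + L],
        ],
        format="lil",
    )
    b = np.zeros(nv + 2 * nm)
    dir_nodes = np.concatenate([network.inlet_nodes, network.outlet_nodes])
    dir_vals = np.concatenate([
        np.full(len(network.inlet_nodes), params.inlet_pressure),
        np.full(len(network.outlet_nodes), params.outlet_pressure),
    ])
    A, b = _apply_dirichlet(A, b, dir_nodes, dir_vals)
    # decoupled continuum fields carry no flow: pin them to the outlet pressure
    if not cap_coupled:
        A, b = _apply_dirichlet(A, b, nv + np.arange(nm), np.full(nm, params.outlet_pressure))
    if not tis_coupled:
        A, b = _apply_dirichlet(A, b, nv + nm + np.arange(nm), np.full(nm, params.outlet_pressure))

    A = A.tocsc()
    p = spla.spsolve(A, b)
    res = np.linalg.norm(A @ p - b) / max(np.linalg.norm(b), 1.0)
    if res > 1.0e-10:
        logger.warning("flow solve residual %.3e above 1e-10", res)

    p_vessel = p[:nv]
    p_cap = p[nv: nv + nm]
    p_tissue = p[nv + nm:]

    q_segment = g * (p_vessel[a_idx] - p_vessel[b_idx])
    grads, vols = shape_gradients(model.points, model.cells)
    grad_pt = np.einsum("eik,ei->ek", grads, p_tissue[model.cells])
    grad_pc = np.einsum("eik,ei->ek", grads, p_cap[model.cells])
    v_tissue = -params.darcy_mobility * grad_pt
    v_cap = -params.darcy_mobility * grad_pc
    q_leak_node = g_leak * (p_cap - p_tissue)
    q_conn = g_conn * (p_vessel[model.conn_vessel] - p_cap[model.conn_tissue])
    logger.info(
        "flow solved: residual %.2e, net transmural flow %.3e mm^3/s",
        res,
        float(q_leak_node.sum()),
    )
    return PressureSolution(
        p_vessel=p_vessel,
        p_cap=p_cap,
        p_tissue=p_tissue,
        q_segment=q_segment,
        v_tissue=v_tissue,
        v_cap=v_cap,
        q_leak_node=q_leak_node,
        q_conn=q_conn,
    )
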