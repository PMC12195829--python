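"""Transient coupled concentration problem.

Solves convection-diffusion for three concentration fields — the 1D vessel
network, the smeared capillary continuum and the tissue continuum — coupled
by diffusive wall exchange (rate ``wall_permeability`` per unit volume),
convective transmural leakage (upwinded by the sign of the local pressure
difference), vessel-continuum connectivity exchange, and a first-order
clearance sink on the tissue field.  Time integration is a theta scheme
(backward Euler by default) over the inlet bolus protocol.

Spatial discretisation is P1 Galerkin with row-sum mass lumping and
finite-volume upwinding of the network advection; on the structured
(non-obtuse) tet meshes produced by :mod:`vasctrans.geometry` this keeps the
discrete solution within the physical concentration bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import units
from .compounds import CompoundRecord
from .fem import lumped_node_volumes, shape_gradients
from .flow import RV_FLOOR, ConfigurationError, PressureSolution
from .geometry import GeometryError, TissueModel, VesselNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TransportParameters",
    "BolusProfile",
    "TimeSettings",
    "FieldSolution",
    "TransportOperators",
    "assemble_transport_operators",
    "run_transport",
    "wellmixed_reduction",
    "steady_diffusion_solve",
]


@dataclass(frozen=True)
class TransportParameters:
    """Solute transport parameters (canonical mm / s / mol/L units).

    ``wall_permeability`` is a lumped volumetric exchange rate (s^-1) scaling
    ``(c_cap - c_tissue)``; ``clearance_rate`` the first-order tissue sink
    (s^-1).  Defaults mirror the whole-organ protocol: very fast intravascular
    diffusion, slow tissue diffusion.
    """

    D_capillary: float = 1.0e4  # mm^2/s
    D_tissue: float = 0.2  # mm^2/s
    wall_permeability: float = 100.0  # s^-1
    clearance_rate: float = 0.0  # s^-1
    leakage_coefficient: float = 1.0e-11  # s^-1 Pa^-1 (must match the flow solve)
    connectivity_permeability: float = 0.1  # mm/s, vessel<->capillary exchange per coupling area

    def __post_init__(self) -> None:
        if self.D_capillary <= 0 or self.D_tissue <= 0:
            raise ValueError("diffusivities must be > 0")
        if min(self.wall_permeability, self.clearance_rate,
               self.connectivity_permeability) < 0:
            raise ValueError("rates must be >= 0")

    @classmethod
    def for_compound(
        cls,
        compound: CompoundRecord,
        tissue_density_kg_per_l: float = 1.0,
        **overrides,
    ) -> "TransportParameters":
        """Parameters for one compound: its diffusivity becomes the tissue-domain
        diffusivity and its clearance coefficient the first-order sink rate."""
        k_e = units.clearance_to_rate(compound.clearance_coefficient, tissue_density_kg_per_l)
        logger.info(
            "%s: D_tissue = %.3e mm^2/s, clearance %.3f mL/s/kg -> k_e = %.3e 1/s "
            "(tissue density %.2f kg/L)",
            compound.name, compound.diffusion_coefficient,
            compound.clearance_coefficient, k_e, tissue_density_kg_per_l,
        )
        kwargs = dict(D_tissue=compound.diffusion_coefficient, clearance_rate=k_e)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class BolusProfile:
    """Inlet concentration pulse.

    The whole-organ protocol names a bolus but not its shape; the default is
    a rectangular pulse of amplitude 20 mol/L lasting 40 s (one tenth of the
    simulated 400 s), with zero concentration prescribed at vein outlets.
    """

    amplitude: float = 20.0  # mol/L
    duration: float = 40.0  # s
    shape: str = "rectangular"  # or "triangular"
    outlet_concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.duration < 0:
            raise ValueError("amplitude and duration must be >= 0")
        if self.shape not in ("rectangular", "triangular"):
            raise ValueError(f"unknown bolus shape {self.shape!r}")

    def value(self, t: float) -> float:
        """Inlet concentration at time t (inclusive of t == duration)."""
        if self.duration == 0 or t > self.duration:
            return 0.0
        if self.shape == "rectangular":
            return self.amplitude
        return self.amplitude * max(0.0, 1.0 - t / self.duration)


@dataclass(frozen=True)
class TimeSettings:
    """Time integration protocol: default 400 s in 40 equal implicit steps."""

    total_time: float = 400.0
    n_steps: int = 40
    theta: float = 1.0  # 1 = backward Euler, 0.5 = Crank-Nicolson

    def __post_init__(self) -> None:
        if self.total_time <= 0 or self.n_steps < 1:
            raise ValueError("total_time must be > 0 and n_steps >= 1")
        if not 0.5 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0.5, 1]")

    @property
    def dt(self) -> float:
        return self.total_time / self.n_steps


@dataclass
class FieldSolution:
    """Time series of the three concentration fields plus the mass ledger."""

    times: np.ndarray  # (nt,)
    c_vessel: np.ndarray  # (nt, n_vessel_nodes)
    c_cap: np.ndarray  # (nt, n_mesh_nodes)
    c_tissue: np.ndarray  # (nt, n_mesh_nodes)
    mass_ledger: pd.DataFrame  # per-step budget in mol (concentration * mm^3 / 1e6... see note)

    def field(self, domain: str) -> np.ndarray:
        try:
            return {"vessel": self.c_vessel, "capillary": self.c_cap,
                    "tissue": self.c_tissue}[domain]
        except KeyError:
            raise ValueError(f"unknown domain {domain!r}") from None


@dataclass
class TransportOperators:
    """Assembled operator bundle for the theta stepper.

    ``K`` collects every non-transient term; ``K_clear`` (clearance sink) and
    ``K_adv_galerkin`` (continuum Galerkin advection, whose column sums are
    boundary fluxes) are also kept separately for the mass ledger.
    """

    M: np.ndarray  # lumped mass diagonal, length N
    K: sp.csr_matrix
    K_clear: sp.csr_matrix
    K_adv_galerkin: sp.csr_matrix
    n_vessel: int
    n_mesh: int
    inlet_nodes: np.ndarray  # global indices (vessel block), bolus Dirichlet
    outlet_nodes: np.ndarray  # global indices, zero Dirichlet
    cap_mass: np.ndarray  # capillary-fraction lumped volumes per mesh node (for sources)
    geometry_tag: tuple = field(default=())

    @property
    def size(self) -> int:
        return self.n_vessel + 2 * self.n_mesh


def _mmatrix_fix(K: sp.csr_matrix) -> sp.csr_matrix:
    """Move positive off-diagonal stiffness entries onto the diagonal.

    Distorted (obtuse) tets break the M-matrix property of the P1 stiffness
    and with it the discrete maximum principle.  This symmetric, row-sum
    preserving correction (the standard low-order artificial-diffusion
    operator) restores it at the cost of locally first-order accuracy.
    """
    off = K - sp.diags(K.diagonal())
    pos = off.maximum(0.0)
    if pos.nnz == 0:
        return K
    return (K - pos + sp.diags(np.asarray(pos.sum(axis=1)).ravel())).tocsr()


def _continuum_operators(model, fraction, diffusivity, velocity, grads, vols, floor=True):
    """Lumped mass diagonal, stiffness and Galerkin advection for one field."""
    frac = np.maximum(fraction, RV_FLOOR) if floor else fraction
    n = model.n_points
    mass = lumped_node_volumes(model.points, model.cells, element_weights=frac)
    w = diffusivity * frac * vols
    ke = np.einsum("e,eik,ejk->eij", w, grads, grads)
    rows = np.repeat(model.cells, 4, axis=1).ravel()
    cols = np.tile(model.cells, (1, 4)).ravel()
    K = _mmatrix_fix(sp.csr_matrix((ke.ravel(), (rows, cols)), shape=(n, n)))
    if velocity is not None and np.any(velocity):
        # int phi N_i (v . grad N_j): row-constant per element, weight V/4
        conv = np.einsum("e,ek,ejk->ej", frac * vols / 4.0, velocity, grads)  # (m, 4)
        ae = np.repeat(conv[:, None, :], 4, axis=1)
        A = sp.csr_matrix((ae.ravel(), (rows, cols)), shape=(n, n))
    else:
        A = sp.csr_matrix((n, n))
    return mass, K, A


def assemble_transport_operators(
    model: TissueModel,
    network: VesselNetwork | None,
    flow: PressureSolution | None,
    params: TransportParameters,
) -> TransportOperators:
    """Assemble mass and transport operators on the solved flow field.

    ``network``/``flow`` may be ``None`` for continuum-only configurations
    (e.g. the lumped two-compartment verification case); advection vanishes
    and no Dirichlet nodes exist.
    """
    if model.rv_field is None:
        raise ConfigurationError("r_V field not computed")
    if flow is not None and network is not None:
        if len(flow.p_vessel) != network.n_nodes or len(flow.p_cap) != model.n_points:
            raise ConfigurationError("flow solution does not match the geometry")
    grads, vols = shape_gradients(model.points, model.cells)
    if np.any(vols <= 0):
        raise GeometryError("mesh has degenerate elements")
    rv = model.rv_field
    nm = model.n_points
    nv = network.n_nodes if network is not None else 0
    N = nv + 2 * nm
    s_cap, s_tis = nv, nv + nm  # block offsets

    v_cap = flow.v_cap if flow is not None else None
    v_tis = flow.v_tissue if flow is not None else None
    m_cap, K_cap, A_cap = _continuum_operators(
        model, rv, params.D_capillary, v_cap, grads, vols
    )
    m_tis, K_tis, A_tis = _continuum_operators(
        model, 1.0 - rv, params.D_tissue, v_tis, grads, vols
    )

    rows, cols, vals = [], [], []
    arows, acols, avals = [], [], []  # Galerkin advection bookkeeping

    def add(r, c, v, acc=(rows, cols, vals)):
        acc[0].append(np.asarray(r)); acc[1].append(np.asarray(c)); acc[2].append(np.asarray(v))

    def add_coo(mat, roff, coff, acc=(rows, cols, vals)):
        coo = mat.tocoo()
        add(coo.row + roff, coo.col + coff, coo.data, acc)

    add_coo(K_cap + A_cap, s_cap, s_cap)
    add_coo(K_tis + A_tis, s_tis, s_tis)
    add_coo(A_cap, s_cap, s_cap, (arows, acols, avals))
    add_coo(A_tis, s_tis, s_tis, (arows, acols, avals))

    # diffusive wall exchange, lumped per node on the full element volume
    w_node = lumped_node_volumes(model.points, model.cells)
    ex = params.wall_permeability * w_node
    idx = np.arange(nm)
    add(s_cap + idx, s_cap + idx, ex)
    add(s_cap + idx, s_tis + idx, -ex)
    add(s_tis + idx, s_tis + idx, ex)
    add(s_tis + idx, s_cap + idx, -ex)

    # convective transmural leakage, upwinded by the pressure difference sign
    if flow is not None:
        q = flow.q_leak_node  # > 0: capillary -> tissue
        pos, neg = q > 0, q < 0
        add(s_cap + idx[pos], s_cap + idx[pos], q[pos])
        add(s_tis + idx[pos], s_cap + idx[pos], -q[pos])
        add(s_tis + idx[neg], s_tis + idx[neg], -q[neg])
        add(s_cap + idx[neg], s_tis + idx[neg], q[neg])

    # clearance sink on the tissue field
    kc_rows = s_tis + idx
    K_clear = sp.csr_matrix(
        (params.clearance_rate * m_tis, (kc_rows, kc_rows)), shape=(N, N)
    )

    M = np.zeros(N)
    M[s_cap + idx] = m_cap
    M[s_tis + idx] = m_tis

    inlet_glob = np.empty(0, dtype=int)
    outlet_glob = np.empty(0, dtype=int)
    if network is not None:
        a_idx, b_idx = network.segments[:, 0], network.segments[:, 1]
        lengths = network.segment_lengths()
        areas = np.pi * network.radii**2
        np.add.at(M, a_idx, areas * lengths / 2.0)
        np.add.at(M, b_idx, areas * lengths / 2.0)
        gd = areas * params.D_capillary / lengths
        add(a_idx, a_idx, gd); add(b_idx, b_idx, gd)
        add(a_idx, b_idx, -gd); add(b_idx, a_idx, -gd)
        if flow is not None:
            qs = flow.q_segment
            pos = qs >= 0
            up = np.where(pos, a_idx, b_idx)
            dn = np.where(pos, b_idx, a_idx)
            qa = np.abs(qs)
            add(up, up, qa)
            add(dn, up, -qa)
        # vessel <-> smeared capillary connectivity exchange
        h = params.connectivity_permeability * model.conn_coeff
        cv, ct = model.conn_vessel, model.conn_tissue
        add(cv, cv, h)
        add(cv, s_cap + ct, -h)
        add(s_cap + ct, s_cap + ct, h)
        add(s_cap + ct, cv, -h)
        if flow is not None and len(flow.q_conn):
            qc = flow.q_conn  # > 0: vessel -> capillary field
            posc = qc > 0
            add(cv[posc], cv[posc], qc[posc])
            add(s_cap + ct[posc], cv[posc], -qc[posc])
            negc = qc < 0
            add(s_cap + ct[negc], s_cap + ct[negc], -qc[negc])
            add(cv[negc], s_cap + ct[negc], qc[negc])
        inlet_glob = network.inlet_nodes.astype(int)
        outlet_glob = network.outlet_nodes.astype(int)

    K = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(N, N)
    ) + K_clear
    K_advG = sp.csr_matrix(
        (np.concatenate(avals), (np.concatenate(arows), np.concatenate(acols))), shape=(N, N)
    ) if avals else sp.csr_matrix((N, N))
    return TransportOperators(
        M=M, K=K, K_clear=K_clear, K_adv_galerkin=K_advG,
        n_vessel=nv, n_mesh=nm,
        inlet_nodes=inlet_glob, outlet_nodes=outlet_glob,
        cap_mass=m_cap,
    )


def run_transport(
    operators: TransportOperators,
    bolus: BolusProfile,
    times: TimeSettings,
    initial: np.ndarray | None = None,
    capillary_source: Callable[[float], float] | None = None,
) -> FieldSolution:
    """Theta-scheme time integration of the assembled transport system.

    Inlet vessel nodes carry the bolus concentration evaluated at the end of
    each step; outlet nodes carry ``bolus.outlet_concentration``.
    ``capillary_source`` optionally adds a spatially uniform volumetric source
    (mol L^-1 s^-1 per unit capillary volume) to the smeared capillary field.
    The per-step mass ledger is an exact discrete budget: storage change =
    boundary influx - outflux - clearance - advective boundary loss.
    """
    N = operators.size
    dt, theta = times.dt, times.theta
    c = np.zeros(N) if initial is None else np.array(initial, dtype=float)
    if c.shape != (N,):
        raise ValueError(f"initial condition has shape {c.shape}, expected ({N},)")

    M = sp.diags(operators.M)
    K = operators.K
    lhs = (M / dt + theta * K).tolil()
    dir_nodes = np.concatenate([operators.inlet_nodes, operators.outlet_nodes]).astype(int)
    for d in dir_nodes:
        lhs.rows[d] = [int(d)]
        lhs.data[d] = [1.0]
    solver = spla.factorized(lhs.tocsc())

    s_cap = operators.n_vessel
    cap_idx = s_cap + np.arange(operators.n_mesh)

    nt = times.n_steps + 1
    out_t = np.linspace(0.0, times.total_time, nt)
    c_hist = np.empty((nt, N))
    c_hist[0] = c
    ledger_rows = []
    for step in range(times.n_steps):
        t1 = out_t[step + 1]
        f = np.zeros(N)
        if capillary_source is not None:
            # theta-weighted source, mass-consistent with the lumped capillary volume
            s_theta = theta * capillary_source(t1) + (1 - theta) * capillary_source(out_t[step])
            f[cap_idx] = operators.cap_mass * s_theta
        rhs = (M / dt) @ c - (1 - theta) * (K @ c) + f
        rhs[operators.inlet_nodes] = bolus.value(t1)
        rhs[operators.outlet_nodes] = bolus.outlet_concentration
        c_new = solver(rhs)
        if not np.all(np.isfinite(c_new)):
            raise RuntimeError(f"transport solve diverged at step {step + 1}")
        c_theta = theta * c_new + (1 - theta) * c
        resid = operators.M * (c_new - c) / dt + K @ c_theta - f
        storage = float(operators.M @ (c_new - c))
        source = float(f.sum()) * dt
        boundary = resid[dir_nodes] * dt
        inflow = float(boundary[boundary > 0].sum())
        outflow = float(-boundary[boundary < 0].sum())
        clearance = float((operators.K_clear @ c_theta).sum()) * dt
        adv_loss = float((operators.K_adv_galerkin @ c_theta).sum()) * dt
        ledger_rows.append(
            {
                "time": t1,
                "storage_change": storage,
                "inflow": inflow + source,
                "outflow": outflow,
                "clearance": clearance,
                "advective_loss": adv_loss,
                "residual": storage - (inflow + source - outflow - clearance - adv_loss),
            }
        )
        c = c_new
        c_hist[step + 1] = c

    ledger = pd.DataFrame(ledger_rows)
    nv, nm = operators.n_vessel, operators.n_mesh
    return FieldSolution(
        times=out_t,
        c_vessel=c_hist[:, :nv],
        c_cap=c_hist[:, nv: nv + nm],
        c_tissue=c_hist[:, nv + nm:],
        mass_ledger=ledger,
    )


def wellmixed_reduction(
    params: TransportParameters,
    bolus: BolusProfile,
    times: TimeSettings,
    phi_cap: float = 0.03,
    initial: tuple[float, float] = (0.0, 0.0),
    source: Callable[[float], float] | None = None,
    n_substeps: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Independent two-compartment reference for the exchange-clearance kinetics.

    Integrates, with fixed-step RK4 at ``n_substeps`` (>= 1e4) steps,

        dc_cap/dt = -k_x (c_cap - c_t) + s(t)
        dc_t/dt   =  k_x' (c_cap - c_t) - k_e c_t

    with ``k_x = wall_permeability / phi_cap`` and
    ``k_x' = wall_permeability / (1 - phi_cap)`` (volume-fraction weighting of
    the shared exchange flux), ``k_e = clearance_rate``, and forcing ``s``
    (default: the bolus profile acting as a volumetric source).  Returns
    ``(t, c_cap, c_tissue)`` sampled at the coarse output times.
    """
    if not 0 < phi_cap < 1:
        raise ValueError("phi_cap must lie in (0, 1)")
    n_substeps = max(int(n_substeps), 10_000)
    k_x = params.wall_permeability / phi_cap
    k_xp = params.wall_permeability / (1.0 - phi_cap)
    k_e = params.clearance_rate
    s = source if source is not None else bolus.value

    def rhs(t, y):
        d = y[0] - y[1]
        return np.array([-k_x * d + s(t), k_xp * d - k_e * y[1]])

    dt = times.total_time / n_substeps
    y = np.array(initial, dtype=float)
    out_t = np.linspace(0.0, times.total_time, times.n_steps + 1)
    out = np.empty((times.n_steps + 1, 2))
    out[0] = y
    nxt = 1
    for i in range(n_substeps):
        t = i * dt
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t_new = (i + 1) * dt
        while nxt <= times.n_steps and t_new >= out_t[nxt] - 1e-12:
            out[nxt] = y
            nxt += 1
    return out_t, out[:, 0], out[:, 1]


def steady_diffusion_solve(
    model: TissueModel,
    diffusivity: float,
    dirichlet_nodes: np.ndarray,
    dirichlet_values: np.ndarray,
    forcing: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Single-field steady diffusion solve ``-D lap u = f`` on the tissue mesh.

    Verification utility (manufactured-solution studies): P1 stiffness with a
    mass-lumped load vector and Dirichlet rows by replacement.
    """
    grads, vols = shape_gradients(model.points, model.cells)
    w = diffusivity * vols
    ke = np.einsum("e,eik,ejk->eij", w, grads, grads)
    rows = np.repeat(model.cells, 4, axis=1).ravel()
    cols = np.tile(model.cells, (1, 4)).ravel()
    n = model.n_points
    K = sp.csr_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tolil()
    b = np.zeros(n)
    if forcing is not None:
        b = lumped_node_volumes(model.points, model.cells) * forcing(model.points)
    for d, v in zip(dirichlet_nodes, dirichlet_values):
        K.rows[d] = [int(d)]
        K.data[d] = [1.0]
        b[d] = v
    return spla.spsolve(K.tocsc(), b)
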