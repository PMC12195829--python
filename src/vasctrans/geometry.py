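"""Synthetic vascularized-tissue geometry.

A real cerebral micro-CT reconstruction couples three element classes: 1D
elements for the larger vessels, 3D continuum elements for the surrounding
tissue in a smeared (composite) description, and connectivity elements tying
vessel nodes to nearby continuum nodes.  This module generates a reduced-scale
stand-in with the same structure: a tetrahedral tissue mesh (box or
ellipsoid), a seeded branching capillary tree drained by a vein tree, the
per-element capillary volume fraction ``r_V`` and the vessel-to-tissue
connectivity set.  Everything is deterministic under the recipe seed.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import vtkio
from .fem import TetLocator, tet_volumes

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryRecipe",
    "VesselNetwork",
    "TissueModel",
    "generate_tissue_mesh",
    "generate_vessel_tree",
    "compute_rv_field",
    "build_connectivity",
    "generate_geometry",
]

CAPILLARY = "capillary"
VEIN = "vein"


class GeometryError(ValueError):
    """Raised for infeasible recipes or degenerate geometry."""


@dataclass(frozen=True)
class GeometryRecipe:
    """Parameters of the synthetic geometry generator.

    The defaults emulate a small brain-like domain: a 6 x 5 x 4 mm ellipsoid
    holding ~5,000 tissue tets and a 200-segment vascular network, i.e. the
    whole-organ element-class structure (1D vessels << 3D continuum, plus a
    connectivity set) at desk scale.
    """

    domain_shape: str = "ellipsoid"  # "box" or "ellipsoid"
    dimensions: tuple[float, float, float] = (6.0, 5.0, 4.0)  # mm; ellipsoid axes = full extents
    target_3d_elements: int = 5000
    n_vessel_segments: int = 200
    capillary_fraction: float = 0.75  # share of segments that are capillaries
    bifurcation_probability: float = 0.35
    root_radius_capillary: float = 0.03  # mm
    root_radius_vein: float = 0.05  # mm
    radius_decay: float = 0.85  # child radius = parent radius * decay at a bifurcation
    min_radius: float = 0.004  # mm, lower clamp
    step_length: tuple[float, float] = (0.35, 0.8)  # mm, segment length range
    rv_mode: str = "derived"  # "derived" from vessel density, or "uniform"
    uniform_rv: float = 0.03  # used when rv_mode == "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.domain_shape not in ("box", "ellipsoid"):
            raise GeometryError(f"unknown domain shape {self.domain_shape!r}")
        if min(self.dimensions) <= 0:
            raise GeometryError("domain dimensions must be positive")
        if self.target_3d_elements < 4:
            raise GeometryError("target_3d_elements must be at least 4")
        if self.n_vessel_segments < 1:
            raise GeometryError("n_vessel_segments must be at least 1")
        if not 0 < self.radius_decay <= 1:
            raise GeometryError("radius_decay must be in (0, 1]")
        if not 0 < self.capillary_fraction <= 1:
            raise GeometryError("capillary_fraction must be in (0, 1]")


@dataclass
class VesselNetwork:
    """1D vessel network: nodes, directed segments, radii and kinds.

    Segments are directed along flow: capillaries away from the inlet, veins
    toward the outlet, so every inlet has a directed path to an outlet.
    """

    nodes: np.ndarray  # (n, 3) mm
    segments: np.ndarray  # (m, 2) node indices, a -> b
    radii: np.ndarray  # (m,) mm
    kinds: np.ndarray  # (m,) str, CAPILLARY or VEIN
    inlet_nodes: np.ndarray  # (k,) node indices
    outlet_nodes: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_lengths(self) -> np.ndarray:
        d = self.nodes[self.segments[:, 1]] - self.nodes[self.segments[:, 0]]
        return np.linalg.norm(d, axis=1)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        for i, (a, b) in enumerate(self.segments):
            g.add_edge(int(a), int(b), radius=float(self.radii[i]), kind=str(self.kinds[i]))
        return g

    def validate(self) -> None:
        if np.any(self.radii <= 0):
            raise GeometryError("all segment radii must be positive")
        if np.any(self.segment_lengths() <= 0):
            raise GeometryError("zero-length vessel segment")
        g = self.to_digraph()
        for inlet in self.inlet_nodes:
            reach = nx.descendants(g, int(inlet)) | {int(inlet)}
            if not reach.intersection(set(int(o) for o in self.outlet_nodes)):
                raise GeometryError(f"inlet node {inlet} has no directed path to an outlet")
        kinds_by_node: dict[int, set[str]] = {}
        for (a, b), k in zip(self.segments, self.kinds):
            kinds_by_node.setdefault(int(a), set()).add(str(k))
            kinds_by_node.setdefault(int(b), set()).add(str(k))
        has_veins = bool(np.any(self.kinds == VEIN))
        for inlet in self.inlet_nodes:
            if CAPILLARY not in kinds_by_node.get(int(inlet), set()):
                raise GeometryError(f"inlet node {inlet} is not attached to a capillary")
        if has_veins:
            for outlet in self.outlet_nodes:
                if VEIN not in kinds_by_node.get(int(outlet), set()):
                    raise GeometryError(f"outlet node {outlet} is not attached to a vein")

    # ---------------- I/O ----------------
    def write_csv(self, nodes_path: str | Path, segments_path: str | Path) -> None:
        nd = pd.DataFrame(self.nodes, columns=["x", "y", "z"])
        nd.insert(0, "id", np.arange(self.n_nodes))
        nd["is_inlet"] = np.isin(np.arange(self.n_nodes), self.inlet_nodes).astype(int)
        nd["is_outlet"] = np.isin(np.arange(self.n_nodes), self.outlet_nodes).astype(int)
        nd.to_csv(nodes_path, index=False)
        sd = pd.DataFrame(
            {
                "id": np.arange(self.n_segments),
                "node_a": self.segments[:, 0],
                "node_b": self.segments[:, 1],
                "radius_mm": self.radii,
                "kind": self.kinds,
            }
        )
        sd.to_csv(segments_path, index=False)

    @classmethod
    def read_csv(cls, nodes_path: str | Path, segments_path: str | Path) -> "VesselNetwork":
        nd = pd.read_csv(nodes_path).sort_values("id")
        sd = pd.read_csv(segments_path).sort_values("id")
        return cls(
            nodes=nd[["x", "y", "z"]].to_numpy(float),
            segments=sd[["node_a", "node_b"]].to_numpy(int),
            radii=sd["radius_mm"].to_numpy(float),
            kinds=sd["kind"].to_numpy(str),
            inlet_nodes=nd.loc[nd["is_inlet"] == 1, "id"].to_numpy(int),
            outlet_nodes=nd.loc[nd["is_outlet"] == 1, "id"].to_numpy(int),
        )

    def to_json(self, path: str | Path) -> None:
        doc = {
            "nodes": self.nodes.tolist(),
            "segments": self.segments.tolist(),
            "radii": self.radii.tolist(),
            "kinds": self.kinds.tolist(),
            "inlet_nodes": self.inlet_nodes.tolist(),
            "outlet_nodes": self.outlet_nodes.tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "VesselNetwork":
        doc = json.loads(Path(path).read_text())
        return cls(
            nodes=np.asarray(doc["nodes"], float),
            segments=np.asarray(doc["segments"], int),
            radii=np.asarray(doc["radii"], float),
            kinds=np.asarray(doc["kinds"], str),
            inlet_nodes=np.asarray(doc["inlet_nodes"], int),
            outlet_nodes=np.asarray(doc["outlet_nodes"], int),
        )

    def write_vtk(self, path: str | Path) -> None:
        """Export the network as VTK polylines (one line per segment)."""
        kind_code = np.where(self.kinds == VEIN, 1.0, 0.0)
        vtkio.write_polylines(
            path,
            self.nodes,
            [list(seg) for seg in self.segments],
            cell_data={"radius_mm": self.radii, "kind": kind_code},
        )


@dataclass
class TissueModel:
    """3D tissue continuum: tet mesh, capillary volume fraction, connectivity."""

    points: np.ndarray  # (n, 3) mm
    cells: np.ndarray  # (m, 4)
    rv_field: np.ndarray | None = None  # (m,) capillary volume fraction per element
    conn_vessel: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    conn_tissue: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    conn_coeff: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_volumes(self) -> np.ndarray:
        return tet_volumes(self.points, self.cells)

    @property
    def connectivity(self) -> list[tuple[int, int, float]]:
        return [
            (int(v), int(t), float(c))
            for v, t, c in zip(self.conn_vessel, self.conn_tissue, self.conn_coeff)
        ]

    def validate(self) -> None:
        vols = self.cell_volumes()
        if np.any(vols <= 0):
            raise GeometryError(f"{int((vols <= 0).sum())} mesh elements have non-positive volume")
        if self.rv_field is not None:
            if np.any(self.rv_field < 0) or np.any(self.rv_field >= 1):
                raise GeometryError("r_V must satisfy 0 <= r_V < 1 per element")
        if self.conn_coeff.size:
            if np.any(self.conn_coeff < 0):
                raise GeometryError("connectivity coupling coefficients must be >= 0")
            if self.conn_tissue.max(initial=-1) >= self.n_points:
                raise GeometryError("connectivity references an invalid tissue node")

    def write_vtk(self, path: str | Path, **point_fields: np.ndarray) -> None:
        cell_data = {}
        if self.rv_field is not None:
            cell_data["r_V"] = self.rv_field
        vtkio.write_unstructured_grid(
            path, self.points, self.cells, point_data=point_fields or None, cell_data=cell_data
        )

    @classmethod
    def read_vtk(cls, path: str | Path) -> "TissueModel":
        points, cells, _, cell_data = vtkio.read_unstructured_grid(path)
        return cls(points=points, cells=cells, rv_field=cell_data.get("r_V"))


# --------------------------------------------------------------------------
# Tissue mesh generation
# --------------------------------------------------------------------------

# Kuhn (Freudenthal) subdivision: each cube splits into 6 path-tetrahedra,
# one per permutation of the axes.  Same diagonal in every cube => conforming.
_KUHN_PERMS = list(itertools.permutations(range(3)))


def _structured_box(nx_: int, ny: int, nz: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit box [0,1]^3 meshed with (nx*ny*nz*6) Kuhn tets."""
    xs = np.linspace(0.0, 1.0, nx_ + 1)
    ys = np.linspace(0.0, 1.0, ny + 1)
    zs = np.linspace(0.0, 1.0, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    points = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    cells = []
    unit = np.eye(3, dtype=int)
    for i in range(nx_):
        for j in range(ny):
            for k in range(nz):
                base = np.array([i, j, k])
                for perm in _KUHN_PERMS:
                    v = [base.copy()]
                    cur = base.copy()
                    for ax in perm:
                        cur = cur + unit[ax]
                        v.append(cur.copy())
                    cells.append([nid(*p) for p in (v[0], v[1], v[2], v[3])])
    cells = np.asarray(cells, dtype=int)
    # enforce positive orientation
    vols = tet_volumes(points, cells)
    flip = vols < 0
    cells[flip] = cells[flip][:, [0, 2, 1, 3]]
    return points, cells


def _axis_counts(recipe: GeometryRecipe) -> tuple[int, int, int]:
    """Per-axis cell counts whose 6*nx*ny*nz best approaches the target."""
    dims = np.asarray(recipe.dimensions, float)
    target = recipe.target_3d_elements
    # n_i proportional to L_i with 6 * nx * ny * nz ~ target
    c = (target / (6.0 * float(np.prod(dims)))) ** (1.0 / 3.0)
    base = np.maximum(1, np.round(c * dims)).astype(int)
    # search the +-1 neighbourhood for the closest element count
    best, best_err = None, np.inf
    for d in itertools.product((-1, 0, 1), repeat=3):
        n = np.maximum(1, base + np.array(d))
        err = abs(6 * int(np.prod(n)) - target)
        if err < best_err:
            best, best_err = n, err
    return tuple(int(v) for v in best)


def _map_unit_to_ellipsoid(points: np.ndarray, semi: np.ndarray) -> np.ndarray:
    """Map [0,1]^3 nodes onto an ellipsoid with semi-axes ``semi``.

    Uses the standard cube-to-ball map p -> p * (||p||_inf / ||p||_2), which
    sends concentric cubes to concentric spheres, then scales per axis.
    """
    p = 2.0 * points - 1.0  # [-1, 1]^3
    linf = np.abs(p).max(axis=1)
    l2 = np.linalg.norm(p, axis=1)
    scale = np.divide(linf, l2, out=np.zeros_like(l2), where=l2 > 0)
    return p * scale[:, None] * semi[None, :]


def generate_tissue_mesh(recipe: GeometryRecipe) -> TissueModel:
    """Generate the tissue tet mesh for the recipe (r_V and connectivity unset).

    The element count lands within about +-20 % of ``target_3d_elements``
    (exact for box counts divisible by 6 along near-cubic aspect ratios).
    """
    nx_, ny, nz = _axis_counts(recipe)
    points, cells = _structured_box(nx_, ny, nz)
    dims = np.asarray(recipe.dimensions, float)
    if recipe.domain_shape == "box":
        points = points * dims[None, :]
    else:
        points = _map_unit_to_ellipsoid(points, dims / 2.0)
        vols = tet_volumes(points, cells)
        flip = vols < 0
        cells[flip] = cells[flip][:, [0, 2, 1, 3]]
    model = TissueModel(points=points, cells=cells)
    vols = model.cell_volumes()
    if np.any(vols <= 0):
        raise GeometryError("mesh generation produced degenerate elements")
    n = len(cells)
    if abs(n - recipe.target_3d_elements) > 0.2 * recipe.target_3d_elements:
        logger.warning(
            "mesh has %d elements, more than 20%% from target %d",
            n,
            recipe.target_3d_elements,
        )
    logger.info("tissue mesh: %d nodes, %d tets, volume %.3f mm^3", len(points), n, vols.sum())
    return model


# --------------------------------------------------------------------------
# Vessel tree generation
# --------------------------------------------------------------------------


def _domain_clamp(p: np.ndarray, recipe: GeometryRecipe, margin: float) -> np.ndarray:
    dims = np.asarray(recipe.dimensions, float)
    if recipe.domain_shape == "box":
        return np.clip(p, margin, dims - margin)
    semi = dims / 2.0 - margin
    r = np.sqrt(np.sum((p / semi) ** 2))
    if r > 1.0:
        p = p / r
    return p


def _inlet_outlet_points(recipe: GeometryRecipe, margin: float) -> tuple[np.ndarray, np.ndarray]:
    dims = np.asarray(recipe.dimensions, float)
    if recipe.domain_shape == "box":
        inlet = np.array([margin, dims[1] / 2.0, dims[2] / 2.0])
        outlet = np.array([dims[0] - margin, dims[1] / 2.0, dims[2] / 2.0])
    else:
        semi = dims / 2.0
        inlet = np.array([-(semi[0] - margin), 0.0, 0.0])
        outlet = np.array([semi[0] - margin, 0.0, 0.0])
    return inlet, outlet


class _TreeBuilder:
    """Incremental seeded growth of one branching tree."""

    def __init__(self, recipe: GeometryRecipe, rng: np.random.Generator, root: np.ndarray,
                 root_dir: np.ndarray, root_radius: float, margin: float):
        self.recipe = recipe
        self.rng = rng
        self.margin = margin
        self.nodes = [root.copy()]
        self.segments: list[tuple[int, int]] = []
        self.radii: list[float] = []
        self.depths: list[int] = []
        # active tips: (node index, depth, unit direction)
        self.tips: list[tuple[int, int, np.ndarray]] = [(0, 0, root_dir / np.linalg.norm(root_dir))]
        self.root_radius = root_radius

    def _new_point(self, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
        lo, hi = self.recipe.step_length
        step = self.rng.uniform(lo, hi)
        p = _domain_clamp(origin + step * direction, self.recipe, self.margin)
        tries = 0
        while np.linalg.norm(p - origin) < 1e-6 and tries < 20:
            direction = self._perturb(direction, 1.5)
            p = _domain_clamp(origin + step * direction, self.recipe, self.margin)
            tries += 1
        return p

    def _perturb(self, direction: np.ndarray, spread: float = 0.6) -> np.ndarray:
        d = direction + spread * self.rng.normal(size=3)
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.array([1.0, 0.0, 0.0])

    def grow(self, n_segments: int) -> None:
        while len(self.segments) < n_segments:
            ti = int(self.rng.integers(len(self.tips)))
            node, depth, direction = self.tips.pop(ti)
            branch = (
                self.rng.random() < self.recipe.bifurcation_probability
                and len(self.segments) + 2 <= n_segments
            )
            n_children = 2 if branch else 1
            for _ in range(n_children):
                child_dir = self._perturb(direction, 0.6 if n_children == 1 else 0.9)
                p = self._new_point(self.nodes[node], child_dir)
                child = len(self.nodes)
                self.nodes.append(p)
                child_depth = depth + (1 if n_children == 2 else 0)
                radius = max(
                    self.recipe.min_radius,
                    self.root_radius * self.recipe.radius_decay**child_depth,
                )
                self.segments.append((node, child))
                self.radii.append(radius)
                self.depths.append(child_depth)
                v = self.nodes[child] - self.nodes[node]
                self.tips.append((child, child_depth, v / np.linalg.norm(v)))

    def leaf_nodes(self) -> list[int]:
        parents = {a for a, _ in self.segments}
        children = {b for _, b in self.segments}
        return sorted(children - parents) or [0]


def generate_vessel_tree(recipe: GeometryRecipe, model: TissueModel) -> VesselNetwork:
    """Grow the capillary supply tree and vein drainage tree inside the mesh.

    The capillary tree starts at a single inlet on one side of the domain;
    the vein tree is rooted at a single outlet on the opposite side and built
    in reverse (edges directed toward the outlet).  A few junction segments
    drain capillary tips into the vein tree, so a directed inlet-to-outlet
    path always exists.  Segment count equals ``recipe.n_vessel_segments``.
    """
    dims = np.asarray(recipe.dimensions, float)
    margin = min(0.15 * dims.min(), 0.5)
    if min(recipe.step_length) > dims.min():
        raise GeometryError(
            f"domain too small for the requested tree: limiting dimension {dims.min()} mm "
            f"is below the minimum step length {min(recipe.step_length)} mm"
        )
    inlet_p, outlet_p = _inlet_outlet_points(recipe, margin)
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_vessel_segments

    if n == 1:
        nodes = np.stack([inlet_p, outlet_p])
        net = VesselNetwork(
            nodes=nodes,
            segments=np.array([[0, 1]]),
            radii=np.array([recipe.root_radius_capillary]),
            kinds=np.array([CAPILLARY]),
            inlet_nodes=np.array([0]),
            outlet_nodes=np.array([1]),
        )
        net.validate()
        return net

    n_cap = max(1, int(round(recipe.capillary_fraction * n)))
    n_vein = n - n_cap
    if n_vein == 0:
        n_cap, n_vein = n - 1, 1
    n_join = min(max(1, round(0.05 * n)), n_vein)
    n_vein_tree = n_vein - n_join

    cap = _TreeBuilder(
        recipe, rng, inlet_p, outlet_p - inlet_p, recipe.root_radius_capillary, margin
    )
    cap.grow(n_cap)
    vein = _TreeBuilder(
        recipe, rng, outlet_p, inlet_p - outlet_p, recipe.root_radius_vein, margin
    )
    vein.grow(n_vein_tree)

    cap_nodes = np.asarray(cap.nodes)
    vein_nodes = np.asarray(vein.nodes)
    offset = len(cap_nodes)
    nodes = np.vstack([cap_nodes, vein_nodes])
    segments = list(map(tuple, cap.segments))
    radii = list(cap.radii)
    kinds = [CAPILLARY] * len(cap.segments)
    # vein tree edges reversed: child -> parent, i.e. toward the outlet root
    for (a, b), r in zip(vein.segments, vein.radii):
        segments.append((b + offset, a + offset))
        radii.append(r)
        kinds.append(VEIN)

    # junctions: drain capillary tips into the nearest vein node
    tips = cap.leaf_nodes()
    rng.shuffle(tips)
    vein_tree_kd = cKDTree(vein_nodes)
    joined = 0
    for tip in tips:
        if joined == n_join:
            break
        dist, vn = vein_tree_kd.query(cap_nodes[tip])
        if dist < 1e-6:
            continue
        segments.append((tip, int(vn) + offset))
        radii.append(max(recipe.min_radius, recipe.root_radius_vein * recipe.radius_decay**3))
        kinds.append(VEIN)
        joined += 1
    # guarantee at least one junction even in pathological cases
    if joined == 0:
        dist, vn = vein_tree_kd.query(cap_nodes[tips[0]])
        segments.append((tips[0], int(vn) + offset))
        radii.append(recipe.min_radius)
        kinds.append(VEIN)
        joined = 1
    # top up to the exact requested count with extra capillary twigs
    extra = n - len(segments)
    if extra > 0:
        cap.grow(n_cap + extra)
        new_nodes = np.asarray(cap.nodes[len(cap_nodes):])
        # reindex: new capillary nodes appended after the vein block
        base = len(nodes)
        nodes = np.vstack([nodes, new_nodes])
        for (a, b), r in zip(cap.segments[n_cap:], cap.radii[n_cap:]):
            a2 = a if a < len(cap_nodes) else a - len(cap_nodes) + base
            b2 = b if b < len(cap_nodes) else b - len(cap_nodes) + base
            segments.append((a2, b2))
            radii.append(r)
            kinds.append(CAPILLARY)

    net = VesselNetwork(
        nodes=nodes,
        segments=np.asarray(segments, dtype=int),
        radii=np.asarray(radii, float),
        kinds=np.asarray(kinds, dtype=object).astype(str),
        inlet_nodes=np.array([0]),
        outlet_nodes=np.array([offset]),
    )
    net.validate()
    logger.info(
        "vessel network: %d nodes, %d segments (%d capillary, %d vein)",
        net.n_nodes,
        net.n_segments,
        int(np.sum(net.kinds == CAPILLARY)),
        int(np.sum(net.kinds == VEIN)),
    )
    return net


# --------------------------------------------------------------------------
# Smeared capillary fraction and connectivity
# --------------------------------------------------------------------------


def compute_rv_field(
    network: VesselNetwork,
    model: TissueModel,
    mode: str | None = None,
    uniform_rv: float = 0.03,
    rv_cap: float = 0.95,
) -> TissueModel:
    """Fill the per-element capillary volume fraction ``r_V``.

    In "derived" mode every capillary segment is treated as a cylinder whose
    volume is apportioned to elements by sub-segment sampling: the segment is
    split into short pieces, each piece's volume ``pi r^2 dL`` is charged to
    the element containing its midpoint.  Summed over elements this conserves
    the total capillary volume exactly (up to the ``rv_cap`` clamp).  Vein
    segments are collectors and do not contribute to the smeared fraction.
    """
    mode = mode or "derived"
    vols = model.cell_volumes()
    if np.any(vols <= 0):
        raise GeometryError("mesh has non-positive element volumes")
    if mode == "uniform":
        model.rv_field = np.full(model.n_cells, float(uniform_rv))
        return model
    rv_vol = np.zeros(model.n_cells)
    locator = TetLocator(model.points, model.cells)
    h = float(np.mean(vols) ** (1.0 / 3.0))
    is_cap = network.kinds == CAPILLARY
    for (a, b), r in zip(network.segments[is_cap], network.radii[is_cap]):
        pa, pb = network.nodes[a], network.nodes[b]
        length = float(np.linalg.norm(pb - pa))
        if length == 0:
            continue
        nsub = int(np.clip(np.ceil(length / (0.25 * h)), 4, 64))
        ts = (np.arange(nsub) + 0.5) / nsub
        mids = pa[None, :] + ts[:, None] * (pb - pa)[None, :]
        elems, _ = locator.find(mids, fallback=True)
        np.add.at(rv_vol, elems, np.pi * r * r * length / nsub)
    rv = rv_vol / vols
    n_clamped = int(np.sum(rv > rv_cap))
    if n_clamped:
        logger.warning("r_V clamped below 1 in %d elements", n_clamped)
    model.rv_field = np.minimum(rv, rv_cap)
    return model


def build_connectivity(
    network: VesselNetwork, model: TissueModel, search_radius: float | None = None
) -> TissueModel:
    """Pair each vessel node with nearby tissue nodes (the coupling set).

    Every vessel node gets at least one partner (nearest tissue node as a
    fallback).  The total coupling coefficient of a vessel node equals its
    local lateral surface area ``sum(2 pi r L/2)`` over adjacent segments,
    split evenly across its partners.
    """
    if model.n_points == 0:
        raise GeometryError("empty tissue mesh")
    if search_radius is None:
        search_radius = 1.5 * float(np.mean(model.cell_volumes()) ** (1.0 / 3.0))
    lengths = network.segment_lengths()
    area = np.zeros(network.n_nodes)
    for (a, b), r, ln in zip(network.segments, network.radii, lengths):
        half = 2.0 * np.pi * r * ln / 2.0
        area[a] += half
        area[b] += half
    tree = cKDTree(model.points)
    conn_v, conn_t, conn_c = [], [], []
    neighbours = tree.query_ball_point(network.nodes, search_radius)
    for vn, nbrs in enumerate(neighbours):
        if not nbrs:
            _, nearest = tree.query(network.nodes[vn])
            nbrs = [int(nearest)]
        w = area[vn] / len(nbrs)
        for tn in nbrs:
            conn_v.append(vn)
            conn_t.append(int(tn))
            conn_c.append(w)
    model.conn_vessel = np.asarray(conn_v, dtype=int)
    model.conn_tissue = np.asarray(conn_t, dtype=int)
    model.conn_coeff = np.asarray(conn_c, float)
    logger.info("connectivity: %d vessel-tissue pairs", len(conn_v))
    return model


def generate_geometry(recipe: GeometryRecipe) -> tuple[VesselNetwork, TissueModel]:
    """Run the full geometry chain: mesh, vessel tree, r_V, connectivity."""
    model = generate_tissue_mesh(recipe)
    network = generate_vessel_tree(recipe, model)
    compute_rv_field(network, model, mode=recipe.rv_mode, uniform_rv=recipe.uniform_rv)
    build_connectivity(network, model)
    model.validate()
    return network, model
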