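"""Low-level finite-element utilities on linear tetrahedral meshes.

All meshes are node arrays ``points (n, 3)`` in mm plus connectivity
``cells (m, 4)`` of 0-based node indices.  Shape functions are linear
(P1); gradients are therefore constant per element.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def tet_volumes(points: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Signed volumes of all tetrahedra (positive for right-handed ordering)."""
    a = points[cells[:, 0]]
    b = points[cells[:, 1]] - a
    c = points[cells[:, 2]] - a
    d = points[cells[:, 3]] - a
    return np.einsum("ij,ij->i", np.cross(b, c), d) / 6.0


def shape_gradients(points: np.ndarray, cells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the four P1 shape functions per element.

    Returns
    -------
    grads : (m, 4, 3) array
        ``grads[e, i]`` is the (constant) gradient of shape function i on
        element e, in 1/mm.
    vols : (m,) array
        Signed element volumes in mm^3.
    """
    vols = tet_volumes(points, cells)
    m = cells.shape[0]
    grads = np.empty((m, 4, 3))
    # grad N_i = (opposite face normal) / (3 V); computed via the inverse of
    # the edge matrix for robustness.
    p0 = points[cells[:, 0]]
    edges = np.stack(
        [points[cells[:, i]] - p0 for i in (1, 2, 3)], axis=1
    )  # (m, 3, 3) rows are edge vectors
    inv = np.linalg.inv(edges)  # (m, 3, 3); columns are grad N_1..3
    grads[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    return grads, vols


def lumped_node_volumes(
    points: np.ndarray, cells: np.ndarray, element_weights: np.ndarray | None = None
) -> np.ndarray:
    """Row-sum (lumped) nodal volumes: each element spreads V/4 to its nodes.

    ``element_weights`` optionally scales each element's volume (e.g. by a
    domain volume fraction) before lumping.
    """
    vols = tet_volumes(points, cells)
    if element_weights is not None:
        vols = vols * element_weights
    out = np.zeros(points.shape[0])
    np.add.at(out, cells.ravel(), np.repeat(vols / 4.0, 4))
    return out


def barycentric_coords(points: np.ndarray, cells: np.ndarray, elem: int, x: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of point ``x`` in element ``elem``."""
    tet = points[cells[elem]]
    mat = (tet[1:] - tet[0]).T
    lam = np.linalg.solve(mat, x - tet[0])
    return np.concatenate([[1.0 - lam.sum()], lam])


class TetLocator:
    """Point location in a tet mesh via a centroid KD-tree plus containment test.

    ``find`` returns, per query point, the containing element (or the nearest
    candidate if the point lies marginally outside, when ``fallback`` is on)
    and the clipped barycentric coordinates.
    """

    def __init__(self, points: np.ndarray, cells: np.ndarray, n_candidates: int = 24):
        self.points = points
        self.cells = cells
        self.centroids = points[cells].mean(axis=1)
        self.tree = cKDTree(self.centroids)
        self.k = min(n_candidates, len(cells))
        p0 = points[cells[:, 0]]
        edges = np.stack([points[cells[:, i]] - p0 for i in (1, 2, 3)], axis=1)
        self._inv = np.linalg.inv(edges)
        self._p0 = p0

    def _bary(self, elem: np.ndarray, x: np.ndarray) -> np.ndarray:
        # self._inv holds (M^T)^-1 = (M^-1)^T with edge vectors as rows of M^T,
        # so the barycentric map lam = M^-1 dx contracts over the first axis
        lam = np.einsum("nji,nj->ni", self._inv[elem], x - self._p0[elem])
        return np.concatenate([1.0 - lam.sum(axis=1, keepdims=True), lam], axis=1)

    def find(
        self, x: np.ndarray, tol: float = 1.0e-9, fallback: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """Locate query points ``x (q, 3)``.

        Returns ``(elems (q,), bary (q, 4))``; ``elems[i] = -1`` marks a point
        outside the mesh (only when ``fallback`` is False).
        """
        x = np.atleast_2d(x)
        q = x.shape[0]
        elems = np.full(q, -1, dtype=int)
        bary = np.zeros((q, 4))
        _, cand = self.tree.query(x, k=self.k)
        cand = np.asarray(cand)
        if cand.ndim == 1:  # k == 1 drops the trailing axis
            cand = cand[:, None]
        best_elem = np.full(q, -1, dtype=int)
        best_viol = np.full(q, np.inf)
        unresolved = np.arange(q)
        for j in range(cand.shape[1]):
            if unresolved.size == 0:
                break
            e = cand[unresolved, j]
            lam = self._bary(e, x[unresolved])
            viol = -lam.min(axis=1)
            inside = viol <= tol
            idx = unresolved[inside]
            elems[idx] = e[inside]
            bary[idx] = lam[inside]
            better = viol < best_viol[unresolved]
            bidx = unresolved[better]
            best_viol[bidx] = viol[better]
            best_elem[bidx] = e[better]
            unresolved = unresolved[~inside]
        if fallback and unresolved.size:
            elems[unresolved] = best_elem[unresolved]
            lam = self._bary(best_elem[unresolved], x[unresolved])
            lam = np.clip(lam, 0.0, None)
            lam /= lam.sum(axis=1, keepdims=True)
            bary[unresolved] = lam
        return elems, bary
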