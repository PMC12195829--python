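"""Reduction of field solutions to reported summaries.

Domain means are volume-fraction weighted: the smeared formalism stores both
continuum fields on the same nodes, so a meaningful capillary (tissue) mean
weights each nodal value by the lumped capillary (tissue) volume
``phi_d * V/4`` of its surrounding elements, not by a plain nodal average.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fem import TetLocator, lumped_node_volumes
from .geometry import GeometryError, TissueModel
from .transport import FieldSolution

__all__ = ["ConcentrationSummary", "mean_concentration", "peak_time", "slice_plane",
           "slice_to_csv", "summarize"]


def slice_to_csv(path: str | Path, us: np.ndarray, vs: np.ndarray, vals: np.ndarray) -> None:
    """Write a sampled slice as a CSV matrix (first row/column are the
    in-plane coordinates; empty cells are outside the mesh)."""
    df = pd.DataFrame(vals, index=pd.Index(us, name="u_mm"), columns=vs)
    df.columns.name = "v_mm"
    df.to_csv(path)


@dataclass
class ConcentrationSummary:
    """Mean concentration series per domain with peak location."""

    times: np.ndarray
    mean_capillary: np.ndarray
    mean_tissue: np.ndarray
    peak_value: dict[str, float]
    peak_time: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "mean_capillary": self.mean_capillary,
             "mean_tissue": self.mean_tissue}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _domain_weights(model: TissueModel, domain: str) -> np.ndarray:
    if model.rv_field is None:
        raise GeometryError("r_V field not computed")
    if domain == "capillary":
        frac = model.rv_field
    elif domain == "tissue":
        frac = 1.0 - model.rv_field
    else:
        raise ValueError(f"unknown domain {domain!r}")
    w = lumped_node_volumes(model.points, model.cells, element_weights=frac)
    if w.sum() <= 0:
        raise GeometryError(f"{domain} domain has zero total volume")
    return w


def mean_concentration(solution: FieldSolution, model: TissueModel, domain: str) -> np.ndarray:
    """Volume-weighted mean of the chosen continuum field at each output time."""
    w = _domain_weights(model, domain)
    c = solution.field(domain)
    if c.shape[1] != len(w):
        raise GeometryError("solution and model are geometrically inconsistent")
    return (c @ w) / w.sum()


def peak_time(times: np.ndarray, series: np.ndarray) -> tuple[float, float]:
    """Earliest time attaining the series maximum, with the value."""
    times = np.asarray(times, float)
    series = np.asarray(series, float)
    if series.size == 0:
        raise ValueError("empty series")
    i = int(np.argmax(series))  # argmax returns the first maximal index
    return float(times[i]), float(series[i])


def summarize(solution: FieldSolution, model: TissueModel) -> ConcentrationSummary:
    """Mean-concentration series and peaks for both continuum domains."""
    mc = mean_concentration(solution, model, "capillary")
    mt = mean_concentration(solution, model, "tissue")
    pv, pt = {}, {}
    for name, series in (("capillary", mc), ("tissue", mt)):
        t, v = peak_time(solution.times, series)
        pt[name], pv[name] = t, v
    return ConcentrationSummary(
        times=solution.times, mean_capillary=mc, mean_tissue=mt,
        peak_value=pv, peak_time=pt,
    )


def slice_plane(
    solution: FieldSolution,
    model: TissueModel,
    point: np.ndarray,
    normal: np.ndarray,
    time: float,
    domain: str = "tissue",
    resolution: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample a field on a regular grid in a cutting plane.

    Returns ``(u, v, values)`` where ``u``/``v`` are in-plane coordinates (mm)
    and ``values`` the barycentric interpolation of the nodal field at the
    output time nearest ``time``; grid points outside the mesh are NaN.
    """
    point = np.asarray(point, float)
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    # orthonormal in-plane basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)

    rel = model.points - point
    u_ext = rel @ e1
    v_ext = rel @ e2
    us = np.linspace(u_ext.min(), u_ext.max(), resolution)
    vs = np.linspace(v_ext.min(), v_ext.max(), resolution)
    U, V = np.meshgrid(us, vs, indexing="ij")
    grid = point[None, :] + U.ravel()[:, None] * e1[None, :] + V.ravel()[:, None] * e2[None, :]

    it = int(np.argmin(np.abs(solution.times - time)))
    c = solution.field(domain)[it]
    locator = TetLocator(model.points, model.cells)
    elems, bary = locator.find(grid, fallback=False)
    vals = np.full(grid.shape[0], np.nan)
    inside = elems >= 0
    if not np.any(inside):
        import warnings

        warnings.warn("cutting plane does not intersect the mesh", stacklevel=2)
    else:
        nodes = model.cells[elems[inside]]
        vals[inside] = np.einsum("qi,qi->q", bary[inside], c[nodes])
    return us, vs, vals.reshape(resolution, resolution)
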