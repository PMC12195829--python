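"""Minimal legacy-VTK (ASCII) export/import for tetrahedral grids and polylines.

Covers exactly the subset this package writes: DATASET UNSTRUCTURED_GRID with
tet (type 10) or polyline (type 4) cells, plus scalar POINT_DATA / CELL_DATA.
Files open directly in ParaView.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_VTK_TET = 10
_VTK_POLY_LINE = 4


def _write_data_section(fh, tag: str, n: int, data: dict[str, np.ndarray]) -> None:
    if not data:
        return
    fh.write(f"{tag} {n}\n")
    for name, arr in data.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape[0] != n:
            raise ValueError(f"{tag} array {name!r} has length {arr.shape[0]}, expected {n}")
        if arr.ndim == 1:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for v in arr:
                fh.write(f"{v:.10g}\n")
        elif arr.ndim == 2 and arr.shape[1] == 3:
            fh.write(f"VECTORS {name} double\n")
            for v in arr:
                fh.write(f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n")
        else:
            raise ValueError(f"unsupported array shape {arr.shape} for {name!r}")


def write_unstructured_grid(
    path: str | Path,
    points: np.ndarray,
    cells: np.ndarray,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "vasctrans grid",
) -> None:
    """Write a tetrahedral mesh (cells ``(m, 4)``) as a legacy ASCII .vtk file."""
    points = np.asarray(points, dtype=float)
    cells = np.asarray(cells, dtype=int)
    with open(path, "w") as fh:
        fh.write(f"# vtk DataFile Version 3.0\n{title}\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        fh.write(f"CELLS {len(cells)} {len(cells) * 5}\n")
        for c in cells:
            fh.write(f"4 {c[0]} {c[1]} {c[2]} {c[3]}\n")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        fh.writelines(f"{_VTK_TET}\n" for _ in range(len(cells)))
        _write_data_section(fh, "POINT_DATA", len(points), point_data or {})
        _write_data_section(fh, "CELL_DATA", len(cells), cell_data or {})


def write_polylines(
    path: str | Path,
    points: np.ndarray,
    lines: list[list[int]] | np.ndarray,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "vasctrans network",
) -> None:
    """Write a set of polylines (e.g. vessel segments) as a legacy ASCII .vtk file."""
    points = np.asarray(points, dtype=float)
    lines = [list(map(int, ln)) for ln in lines]
    total = sum(len(ln) + 1 for ln in lines)
    with open(path, "w") as fh:
        fh.write(f"# vtk DataFile Version 3.0\n{title}\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        fh.write(f"CELLS {len(lines)} {total}\n")
        for ln in lines:
            fh.write(" ".join([str(len(ln))] + [str(i) for i in ln]) + "\n")
        fh.write(f"CELL_TYPES {len(lines)}\n")
        fh.writelines(f"{_VTK_POLY_LINE}\n" for _ in range(len(lines)))
        _write_data_section(fh, "POINT_DATA", len(points), point_data or {})
        _write_data_section(fh, "CELL_DATA", len(lines), cell_data or {})


def read_unstructured_grid(
    path: str | Path,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Read back a tet mesh written by :func:`write_unstructured_grid`.

    Returns ``(points, cells, point_data, cell_data)``.
    """
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    # Strip the two header lines and the ASCII/DATASET markers, then tokenise.
    for ln in lines[2:]:
        tokens.extend(ln.split())
    it = iter(tokens)

    def take(n):
        return [next(it) for _ in range(n)]

    points = cells = None
    point_data: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {}
    active: dict[str, np.ndarray] | None = None
    active_n = 0
    while True:
        try:
            tok = next(it)
        except StopIteration:
            break
        key = tok.upper()
        if key == "ASCII":
            continue
        if key == "DATASET":
            next(it)
        elif key == "POINTS":
            n = int(next(it))
            next(it)  # dtype
            vals = np.array(take(3 * n), dtype=float)
            points = vals.reshape(n, 3)
        elif key == "CELLS":
            n = int(next(it))
            total = int(next(it))
            vals = np.array(take(total), dtype=int)
            if total != 5 * n:
                raise ValueError("reader supports tetrahedral cells only")
            cells = vals.reshape(n, 5)[:, 1:]
        elif key == "CELL_TYPES":
            n = int(next(it))
            take(n)
        elif key == "POINT_DATA":
            active_n = int(next(it))
            active = point_data
        elif key == "CELL_DATA":
            active_n = int(next(it))
            active = cell_data
        elif key == "SCALARS":
            name = next(it)
            next(it)  # dtype
            next(it)  # ncomp
            nxt = next(it)  # LOOKUP_TABLE
            next(it)  # table name
            assert nxt.upper() == "LOOKUP_TABLE"
            active[name] = np.array(take(active_n), dtype=float)
        elif key == "VECTORS":
            name = next(it)
            next(it)
            active[name] = np.array(take(3 * active_n), dtype=float).reshape(active_n, 3)
        else:  # pragma: no cover - unknown section
            raise ValueError(f"unsupported VTK section {tok!r}")
    if points is None or cells is None:
        raise ValueError(f"{path} is not a vasctrans unstructured grid")
    return points, cells, point_data, cell_data
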