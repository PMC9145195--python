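"""Mesh and field I/O: legacy-ASCII VTK unstructured grids and PLY.

The VTK writer emits the small legacy-ASCII subset (POINTS / CELLS /
CELL_TYPES plus named CELL_DATA / POINT_DATA scalars and vectors) that every
standard viewer reads; the reader parses the same subset back, which also
serves as the import path for externally segmented templates that follow the
same layout (``cell_label`` and ``wall_type`` cell arrays).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .template import TissueTemplate, TemplateSpec

__all__ = ["write_vtk", "read_vtk", "write_template_vtk",
           "template_from_vtk", "write_template_ply"]


def write_vtk(path, vertices: np.ndarray, triangles: np.ndarray,
              cell_data: dict[str, np.ndarray] | None = None,
              point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a triangle mesh with named data arrays as legacy-ASCII VTK."""
    v = np.asarray(vertices, dtype=float)
    t = np.asarray(triangles, dtype=np.int64)
    lines = ["# vtk DataFile Version 3.0", "cellstretch mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {len(v)} double"]
    lines += [" ".join(f"{x:.9g}" for x in row) for row in v]
    lines.append(f"CELLS {len(t)} {4 * len(t)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in t]
    lines.append(f"CELL_TYPES {len(t)}")
    lines += ["5"] * len(t)

    def emit(block: str, n: int, data: dict[str, np.ndarray]):
        lines.append(f"{block} {n}")
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines.extend(" ".join(f"{x:.9g}" for x in row) for row in arr)
            else:
                kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
                lines.append(f"SCALARS {name} {kind} 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{x:.9g}" if kind == "double" else str(int(x))
                             for x in arr.ravel())

    if cell_data:
        emit("CELL_DATA", len(t), cell_data)
    if point_data:
        emit("POINT_DATA", len(v), point_data)
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path):
    """Read back the legacy-ASCII subset written by :func:`write_vtk`.

    Returns (vertices, triangles, cell_data, point_data).
    """
    tokens = Path(path).read_text().split("\n")
    i = 0
    verts = tris = None
    cell_data: dict[str, np.ndarray] = {}
    point_data: dict[str, np.ndarray] = {}
    target = None
    while i < len(tokens):
        line = tokens[i].strip()
        parts = line.split()
        if not parts:
            i += 1
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n = int(parts[1])
            verts = np.array([tokens[i + 1 + k].split() for k in range(n)],
                             dtype=float)
            i += n + 1
        elif key == "CELLS":
            n = int(parts[1])
            tris = np.array([tokens[i + 1 + k].split()[1:] for k in range(n)],
                            dtype=np.int64)
            i += n + 1
        elif key == "CELL_TYPES":
            i += int(parts[1]) + 1
        elif key == "CELL_DATA":
            target, count = cell_data, int(parts[1])
            i += 1
        elif key == "POINT_DATA":
            target, count = point_data, int(parts[1])
            i += 1
        elif key == "SCALARS":
            name, kind = parts[1], parts[2]
            vals = [tokens[i + 2 + k] for k in range(count)]
            target[name] = np.array(vals, dtype=(np.int64 if kind == "int"
                                                 else float))
            i += count + 2
        elif key == "VECTORS":
            name = parts[1]
            target[name] = np.array(
                [tokens[i + 1 + k].split() for k in range(count)], dtype=float)
            i += count + 1
        else:
            i += 1
    return verts, tris, cell_data, point_data


def write_template_vtk(path, template: TissueTemplate,
                       coords: np.ndarray | None = None,
                       extra_cell_data: dict | None = None,
                       extra_point_data: dict | None = None) -> None:
    """Export a tissue template (optionally deformed) with standard arrays."""
    label2 = np.full(template.n_triangles, -1, dtype=np.int64)
    for c, (tris, signs) in enumerate(zip(template.cells, template.cell_signs)):
        label2[tris[signs < 0]] = c
    cd = {"cell_label": template.tri_cell.astype(np.int64),
          "cell_label2": label2,   # second cell bounded by a shared-band wall
          "wall_type": template.wall_type.astype(np.int64),
          "thickness": template.thickness}
    if extra_cell_data:
        cd.update(extra_cell_data)
    v = template.vertices if coords is None else coords
    pd_ = dict(extra_point_data or {})
    if coords is not None:
        pd_.setdefault("displacement", coords - template.vertices)
    write_vtk(path, v, template.triangles, cell_data=cd, point_data=pd_ or None)


def template_from_vtk(path, spec: TemplateSpec | None = None,
                      wall_thickness: float = 1.1) -> TissueTemplate:
    """Import a (possibly externally segmented) template from the VTK layout.

    Requires ``cell_label`` cell data; ``wall_type`` and ``thickness`` are
    optional.  Per-cell face sets are rebuilt from the labels and validated
    for closedness.
    """
    verts, tris, cell_data, _ = read_vtk(path)
    if "cell_label" not in cell_data:
        raise ValueError("VTK template import requires a cell_label array")
    labels = cell_data["cell_label"].astype(np.int64)
    wall_type = cell_data.get(
        "wall_type", np.full(len(tris), 2, dtype=np.int64)).astype(np.int64)
    thickness = cell_data.get("thickness",
                              np.full(len(tris), wall_thickness))
    labels2 = cell_data.get(
        "cell_label2", np.full(len(tris), -1, dtype=np.int64)).astype(np.int64)
    n_cells = int(labels.max()) + 1
    cells, signs = [], []
    for c in range(n_cells):
        own = np.nonzero(labels == c)[0]
        other = np.nonzero(labels2 == c)[0]
        cells.append(np.concatenate([own, other]))
        signs.append(np.concatenate([np.ones(len(own), dtype=np.int64),
                                     -np.ones(len(other), dtype=np.int64)]))
    tol = 1e-6
    lo, hi = verts.min(axis=0), verts.max(axis=0)
    boundary = {
        "left": np.nonzero(np.abs(verts[:, 0] - lo[0]) < tol)[0],
        "right": np.nonzero(np.abs(verts[:, 0] - hi[0]) < tol)[0],
        "bottom": np.nonzero(np.abs(verts[:, 1] - lo[1]) < tol)[0],
        "top": np.nonzero(np.abs(verts[:, 1] - hi[1]) < tol)[0],
    }
    tpl = TissueTemplate(vertices=verts, triangles=tris, tri_cell=labels,
                         wall_type=wall_type, thickness=np.asarray(thickness),
                         cells=cells, cell_signs=signs, boundary_nodes=boundary,
                         spec=spec, extent=(hi[0] - lo[0], hi[1] - lo[1]))
    tpl.check()
    return tpl


def write_template_ply(path, template: TissueTemplate,
                       coords: np.ndarray | None = None) -> None:
    """Export the template surface as PLY (via trimesh)."""
    import trimesh
    v = template.vertices if coords is None else coords
    trimesh.Trimesh(vertices=v, faces=template.triangles,
                    process=False).export(str(path))
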