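"""Idealized 3D cellular monolayer templates emulating onion epidermal peels.

The tissue is a single layer of rounded-cuboid cells.  Construction follows
three stages:

1. :func:`make_cell_grid` — a 2D brick tiling of ``cell_width x
   (cell_width * aspect_ratio)`` rectangles clipped to the template extent;
   staggered tilings offset alternate cell files by half a cell length.
2. :func:`extrude_template` — each 2D cell is extruded into a closed 3D box
   of triangulated walls (outer/inner periclinal faces plus anticlinal side
   walls split into extrusion segments).  Adjacent cells are fused only
   within a central band of the anticlinal depth (about one third by
   default); outside the band each cell keeps its own wall, so after
   smoothing the cells take the lens-like profile of real epidermal cells.
3. :func:`smooth_template` — damped uniform Laplacian smoothing of all
   vertices except the central extrusion segment, fused (shared-band) nodes
   and nodes on the template border planes, rounding cell sides and ends.

The module also provides :func:`synth_extensometer_trace`, a generator of
noisy synthetic force-displacement traces with a toe region, standing in for
raw microextensometer output in curve-analysis tests, and
:func:`flat_sheet`, a cell-free rectangular membrane used for patch tests.

All lengths are in µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .extensometer import ForceDisplacementCurve

__all__ = [
    "TemplateSpec",
    "SyntheticTraceSpec",
    "CellGrid",
    "TissueTemplate",
    "make_cell_grid",
    "extrude_template",
    "smooth_template",
    "make_template",
    "synth_extensometer_trace",
    "flat_sheet",
]

_WELD_TOL = 1e-6

#: wall-type codes used in ``TissueTemplate.wall_type``
WALL_OUTER_PERICLINAL = 0
WALL_INNER_PERICLINAL = 1
WALL_ANTICLINAL = 2
WALL_SHARED_BAND = 3

WALL_TYPE_NAMES = {
    WALL_OUTER_PERICLINAL: "outer-periclinal",
    WALL_INNER_PERICLINAL: "inner-periclinal",
    WALL_ANTICLINAL: "anticlinal",
    WALL_SHARED_BAND: "shared-band",
}


@dataclass
class TemplateSpec:
    """Parameters of an idealized cell template.

    ``wall_thickness`` is the uniform membrane thickness; its default is
    calibrated so that pressurizing the staggered 5:1 template to 0.5 MPa
    with isotropic E = 100 MPa walls expands the cells by roughly 15 % in
    volume (thickness is the only free overall stiffness scale of the
    model).
    """

    cell_width: float = 20.0
    aspect_ratio: float = 5.0
    staggered: bool = True
    template_extent: tuple[float, float] = (300.0, 300.0)
    vertex_spacing: float = 2.0
    extrusion_segments: int = 5
    segment_length: float = 4.0
    anticlinal_depth: float = 20.0
    connection_band_fraction: float = 1.0 / 3.0
    wall_thickness: float = 1.1
    smoothing_iterations: int = 10
    #: optional lens-shaped rounding of cell sides and ends: cell
    #: cross-sections taper toward the cell axis away from the connection
    #: band, by this fraction at the periclinal rims (0 = Laplacian only)
    rounding_taper: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.aspect_ratio < 1:
            raise ValueError("aspect_ratio must be >= 1")
        if not self.vertex_spacing < self.cell_width:
            raise ValueError("vertex_spacing must be smaller than cell_width")
        if abs(self.extrusion_segments * self.segment_length
               - self.anticlinal_depth) > 1e-9:
            raise ValueError("extrusion_segments * segment_length must equal "
                             "anticlinal_depth")
        if not 0 < self.connection_band_fraction < 1:
            raise ValueError("connection_band_fraction must be in (0, 1)")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")

    @property
    def cell_length(self) -> float:
        return self.cell_width * self.aspect_ratio

    def coarsened(self, factor: float = 2.0) -> "TemplateSpec":
        """Spec with vertex spacing scaled up and extent halved (coarse runs)."""
        w, h = self.template_extent
        return replace(self, vertex_spacing=self.vertex_spacing * factor,
                       template_extent=(w / 2.0, h / 2.0))


@dataclass
class SyntheticTraceSpec:
    """Parameters of a synthetic raw extensometer trace (test fixture).

    Emulates the shape of a raw microextensometer curve: a flat "toe" region
    where the slack sample straightens at near-zero force, followed by a
    linear elastic rise of slope ``apparent_modulus * width * thickness /
    length``, with additive Gaussian force noise.
    """

    length: float = 3600.0
    width: float = 4000.0
    thickness: float = 20.0
    apparent_modulus: float = 10.0      # MPa
    toe_displacement: float = 0.0       # µm
    noise_amplitude: float = 0.0        # µN
    max_strain: float = 0.5
    n_samples: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.thickness) <= 0:
            raise ValueError("all sample dimensions must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")
        if self.toe_displacement < 0:
            raise ValueError("toe displacement must be >= 0")


@dataclass
class CellGrid:
    """2D stage of template construction: clipped cell rectangles."""

    spec: TemplateSpec
    cells: list[tuple[float, float, float, float]]  # (x0, x1, y0, y1)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class TissueTemplate:
    """Triangulated 3D monolayer: the reference configuration of the tissue.

    Each cell's face set is closed and consistently outward oriented (up to
    the per-face orientation sign), so enclosed volumes follow from the
    divergence theorem.  Within the connection band adjacent cells share a
    single common wall, stored once and referenced by both cells with
    opposite signs; outside the band each cell keeps its own (initially
    coincident) wall surface.
    """

    vertices: np.ndarray                 # (n, 3) reference coordinates, µm
    triangles: np.ndarray                # (m, 3) vertex indices
    tri_cell: np.ndarray                 # (m,) primary owning cell id
    wall_type: np.ndarray                # (m,) codes, see WALL_TYPE_NAMES
    thickness: np.ndarray                # (m,) per-triangle thickness, µm
    cells: list[np.ndarray]              # per-cell triangle index arrays
    #: per-cell orientation signs (+1 outward as stored, -1 for the single
    #: shared-band wall seen from the neighboring cell)
    cell_signs: list[np.ndarray] = None
    boundary_nodes: dict[str, np.ndarray] = None
    spec: TemplateSpec | None = None
    extent: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.cell_signs is None:
            self.cell_signs = [np.ones(len(c), dtype=np.int64)
                               for c in self.cells]

    @property
    def n_nodes(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def depth(self) -> float:
        return self.spec.anticlinal_depth if self.spec is not None else 0.0

    def cell_volumes(self, vertices: np.ndarray | None = None) -> np.ndarray:
        """Enclosed volume per cell via the divergence theorem (µm³)."""
        v = self.vertices if vertices is None else vertices
        out = np.empty(len(self.cells))
        for c, (tris, signs) in enumerate(zip(self.cells, self.cell_signs)):
            t = self.triangles[tris]
            dets = np.einsum("mi,mi->m", v[t[:, 0]],
                             np.cross(v[t[:, 1]], v[t[:, 2]]))
            out[c] = np.dot(signs, dets) / 6.0
        return out

    def triangle_areas(self, vertices: np.ndarray | None = None) -> np.ndarray:
        v = self.vertices if vertices is None else vertices
        t = self.triangles
        n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(n, axis=1)

    def check(self) -> None:
        """Validate closedness, orientation and non-degeneracy; raise on failure."""
        areas = self.triangle_areas()
        if np.any(areas <= 1e-6):
            raise ValueError(f"{int(np.sum(areas <= 1e-6))} degenerate triangles")
        vols = self.cell_volumes()
        if np.any(vols <= 0):
            raise ValueError("non-positive enclosed cell volume (orientation)")
        for c, (tris, signs) in enumerate(zip(self.cells, self.cell_signs)):
            edges: dict[tuple[int, int], int] = {}
            for (a, b, cc), s in zip(self.triangles[tris], signs):
                loop = ((a, b), (b, cc), (cc, a)) if s > 0 else \
                       ((b, a), (cc, b), (a, cc))
                for e in loop:
                    edges[e] = edges.get(e, 0) + 1
            for (a, b), cnt in edges.items():
                if cnt != 1 or edges.get((b, a), 0) != 1:
                    raise ValueError(f"cell {c} surface is not closed/manifold "
                                     f"at edge ({a}, {b})")


# --------------------------------------------------------------------------
# 2D grid
# --------------------------------------------------------------------------

def make_cell_grid(spec: TemplateSpec) -> CellGrid:
    """Brick tiling of rectangular cells clipped to the template extent.

    Cell files run along x (the longitudinal axis); staggering offsets
    alternate files by half a cell length.  Border-straddling cells are
    truncated; slivers thinner than 0.5 µm are dropped.
    """
    W, H = spec.template_extent
    L, w = spec.cell_length, spec.cell_width
    if W < L or H < w:
        raise ValueError(f"template extent {(W, H)} smaller than one "
                         f"{L} x {w} cell")
    min_dim = 0.5
    cells = []
    n_rows = math.ceil(H / w)
    for i in range(n_rows):
        y0, y1 = i * w, min((i + 1) * w, H)
        if y1 - y0 < min_dim:
            continue
        off = -L / 2.0 if (spec.staggered and i % 2 == 1) else 0.0
        j0 = math.floor((0.0 - off) / L)
        j1 = math.ceil((W - off) / L)
        for j in range(j0, j1):
            x0 = max(off + j * L, 0.0)
            x1 = min(off + (j + 1) * L, W)
            if x1 - x0 < min_dim:
                continue
            cells.append((x0, x1, y0, y1))
    return CellGrid(spec=spec, cells=cells)


# --------------------------------------------------------------------------
# Extrusion
# --------------------------------------------------------------------------

def _lattice(a: float, b: float, step: float) -> np.ndarray:
    """Points of the global lattice {k*step} strictly inside (a, b), plus a, b.

    Using one global lattice guarantees that the wall discretizations of
    adjacent cells coincide exactly where the walls overlap.
    """
    tol = 1e-9
    k0 = math.floor(a / step) + 1
    k1 = math.ceil(b / step) - 1
    pts = [a]
    for k in range(k0, k1 + 1):
        x = k * step
        if a + 0.25 * step < x < b - 0.25 * step:
            pts.append(x)
    pts.append(b)
    return np.asarray(pts)


def _z_levels(spec: TemplateSpec) -> np.ndarray:
    d = spec.anticlinal_depth
    zs = [k * spec.segment_length for k in range(spec.extrusion_segments + 1)]
    band = spec.connection_band_fraction * d
    zs += [0.5 * (d - band), 0.5 * (d + band)]
    zs = sorted(zs)
    out = [zs[0]]
    for z in zs[1:]:
        if z - out[-1] > 1e-9:
            out.append(z)
    return np.asarray(out)


def _band_range(spec: TemplateSpec) -> tuple[float, float]:
    d = spec.anticlinal_depth
    band = spec.connection_band_fraction * d
    return 0.5 * (d - band), 0.5 * (d + band)


def _face(us: np.ndarray, vs: np.ndarray, embed, outward: np.ndarray):
    """Structured triangulated patch; returns (verts, tris) outward oriented."""
    U, V = np.meshgrid(us, vs, indexing="ij")
    verts = embed(U.ravel(), V.ravel())
    nu, nv = len(us), len(vs)
    idx = np.arange(nu * nv).reshape(nu, nv)
    q00 = idx[:-1, :-1].ravel()
    q10 = idx[1:, :-1].ravel()
    q11 = idx[1:, 1:].ravel()
    q01 = idx[:-1, 1:].ravel()
    tris = np.concatenate([np.stack([q00, q10, q11], axis=1),
                           np.stack([q00, q11, q01], axis=1)])
    n = np.cross(verts[tris[0, 1]] - verts[tris[0, 0]],
                 verts[tris[0, 2]] - verts[tris[0, 0]])
    if np.dot(n, outward) < 0:
        tris = tris[:, ::-1]
    return verts, tris


def extrude_template(grid: CellGrid, spec: TemplateSpec | None = None) -> TissueTemplate:
    """Extrude a 2D cell grid into a closed-per-cell triangulated monolayer.

    Anticlinal walls span the full depth, subdivided at the extrusion-segment
    boundaries and at the edges of the connection band.  Inside the band the
    facing walls of adjacent cells are fused into a single common wall
    (welded nodes, one triangle layer shared by both cells); everywhere else
    coincident walls of neighboring cells remain separate surfaces, so each
    cell is individually watertight.
    """
    spec = grid.spec if spec is None else spec
    W, H = spec.template_extent
    d = spec.anticlinal_depth
    dx = spec.cell_length / max(1, 2 * round(spec.cell_length
                                             / (2.0 * spec.vertex_spacing)))
    dy = spec.cell_width / max(1, round(spec.cell_width / spec.vertex_spacing))
    zs = _z_levels(spec)
    z_lo, z_hi = _band_range(spec)

    all_verts, all_tris, all_cell, all_type = [], [], [], []
    n_off = 0
    for cid, (x0, x1, y0, y1) in enumerate(grid.cells):
        xs = _lattice(x0, x1, dx)
        ys = _lattice(y0, y1, dy)
        faces = [
            # (us, vs, embed, outward, wall type)
            (xs, ys, lambda u, v: np.stack([u, v, np.zeros_like(u)], axis=1),
             np.array([0.0, 0.0, -1.0]), WALL_INNER_PERICLINAL),
            (xs, ys, lambda u, v: np.stack([u, v, np.full_like(u, d)], axis=1),
             np.array([0.0, 0.0, 1.0]), WALL_OUTER_PERICLINAL),
            (xs, zs, lambda u, v: np.stack([u, np.full_like(u, y0), v], axis=1),
             np.array([0.0, -1.0, 0.0]), WALL_ANTICLINAL),
            (xs, zs, lambda u, v: np.stack([u, np.full_like(u, y1), v], axis=1),
             np.array([0.0, 1.0, 0.0]), WALL_ANTICLINAL),
            (ys, zs, lambda u, v: np.stack([np.full_like(u, x0), u, v], axis=1),
             np.array([-1.0, 0.0, 0.0]), WALL_ANTICLINAL),
            (ys, zs, lambda u, v: np.stack([np.full_like(u, x1), u, v], axis=1),
             np.array([1.0, 0.0, 0.0]), WALL_ANTICLINAL),
        ]
        for us, vs, embed, outward, wtype in faces:
            verts, tris = _face(us, vs, embed, outward)
            all_verts.append(verts)
            all_tris.append(tris + n_off)
            all_cell.append(np.full(len(tris), cid))
            all_type.append(np.full(len(tris), wtype))
            n_off += len(verts)

    verts = np.concatenate(all_verts)
    tris = np.concatenate(all_tris)
    tri_cell = np.concatenate(all_cell)
    wall_type = np.concatenate(all_type)

    # Weld coincident nodes: within each cell always; across cells only in
    # the connection band.
    key = np.round(verts / _WELD_TOL).astype(np.int64)
    in_band = (verts[:, 2] > z_lo - 1e-9) & (verts[:, 2] < z_hi + 1e-9)
    vert_cell = np.empty(len(verts), dtype=np.int64)
    pos = 0
    for arr_v, arr_c in zip(all_verts, all_cell):
        vert_cell[pos:pos + len(arr_v)] = arr_c[0]
        pos += len(arr_v)
    group = np.where(in_band, -1, vert_cell)
    full_key = np.concatenate([key, group[:, None]], axis=1)
    _, first, inverse = np.unique(full_key, axis=0, return_index=True,
                                  return_inverse=True)
    new_verts = verts[first]
    new_tris = inverse[tris]

    template = _finalize(new_verts, new_tris, tri_cell, wall_type, spec, (W, H))
    template.check()
    return template


def _finalize(verts, tris, tri_cell, wall_type, spec, extent) -> TissueTemplate:
    n_cells = int(tri_cell.max()) + 1 if len(tri_cell) else 0
    # The welded facing walls of adjacent cells coincide inside the band;
    # collapse each coincident pair into a single common wall, referenced by
    # both cells with opposite orientation signs.
    first: dict[tuple[int, int, int], int] = {}
    keep = np.ones(len(tris), dtype=bool)
    sec_owner = np.full(len(tris), -1, dtype=np.int64)
    for j, t in enumerate(tris):
        key = tuple(sorted(t))
        i = first.setdefault(key, j)
        if i != j:
            keep[j] = False
            sec_owner[i] = tri_cell[j]
    if not keep.all():
        new_index = np.cumsum(keep) - 1
        tris = tris[keep]
        tri_cell = tri_cell[keep]
        wall_type = wall_type[keep]
        sec_owner = sec_owner[keep]
    wall_type = wall_type.copy()
    wall_type[sec_owner >= 0] = WALL_SHARED_BAND

    cells, signs = [], []
    for c in range(n_cells):
        own = np.nonzero(tri_cell == c)[0]
        other = np.nonzero(sec_owner == c)[0]
        cells.append(np.concatenate([own, other]))
        signs.append(np.concatenate([np.ones(len(own), dtype=np.int64),
                                     -np.ones(len(other), dtype=np.int64)]))
    W, H = extent
    tol = 1e-6
    boundary = {
        "left": np.nonzero(np.abs(verts[:, 0]) < tol)[0],
        "right": np.nonzero(np.abs(verts[:, 0] - W) < tol)[0],
        "bottom": np.nonzero(np.abs(verts[:, 1]) < tol)[0],
        "top": np.nonzero(np.abs(verts[:, 1] - H) < tol)[0],
    }
    return TissueTemplate(
        vertices=verts, triangles=tris, tri_cell=tri_cell, wall_type=wall_type,
        thickness=np.full(len(tris), spec.wall_thickness), cells=cells,
        cell_signs=signs, boundary_nodes=boundary, spec=spec, extent=extent)


# --------------------------------------------------------------------------
# Smoothing
# --------------------------------------------------------------------------

def smooth_template(mesh: TissueTemplate, spec: TemplateSpec | None = None,
                    iterations: int | None = None) -> TissueTemplate:
    """Round cell sides and ends: lens-shaped taper + Laplacian smoothing.

    Two stages: first the cross-section of every cell is tapered toward the
    cell axis away from the connection band (``rounding_taper``), giving the
    lens-like profile of real epidermal cells; then damped uniform Laplacian
    smoothing rounds the remaining corners.  ``iterations == 0`` disables
    both (identity).

    Pinned (never moved): vertices of the central extrusion segment and
    fused shared-band vertices.  Border-truncated cells are rounded like any
    others; the virtual clamps later constrain only the stretch-axis
    coordinate of the end-node sets, so the ends need not stay planar.
    Raises if smoothing degenerates any triangle.
    """
    spec = mesh.spec if spec is None else spec
    iters = spec.smoothing_iterations if iterations is None else iterations
    if iters == 0:
        return mesh
    v = mesh.vertices.copy()
    n = len(v)
    seg = spec.segment_length
    k = spec.extrusion_segments // 2
    zc0, zc1 = k * seg, (k + 1) * seg
    pinned = (v[:, 2] > zc0 - 1e-9) & (v[:, 2] < zc1 + 1e-9)
    band_tris = mesh.triangles[mesh.wall_type == WALL_SHARED_BAND]
    if len(band_tris):
        pinned[np.unique(band_tris)] = True

    if spec.rounding_taper > 0.0:
        # lens-shaped rounding: scale each cell's cross-section toward its
        # axis, increasingly away from the connection band, so neighboring
        # cells touch only at the band and open gaps elsewhere
        d = spec.anticlinal_depth
        z_lo, z_hi = _band_range(spec)
        half_band = 0.5 * (z_hi - z_lo)
        g = (np.abs(v[:, 2] - 0.5 * d) - half_band) / (0.5 * d - half_band)
        g = np.clip(g, 0.0, 1.0)
        f = 1.0 - spec.rounding_taper * g**2
        owner = np.full(n, -1, dtype=np.int64)
        for t, c in zip(mesh.triangles, mesh.tri_cell):
            owner[t] = c
        for c, tris in enumerate(mesh.cells):
            sel = np.unique(mesh.triangles[tris])
            sel = sel[(owner[sel] == c) & ~pinned[sel]]
            center = v[sel, :2].mean(axis=0)
            v[sel, :2] = center + (v[sel, :2] - center) * f[sel, None]

    t = mesh.triangles
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    deg = np.zeros(n)
    np.add.at(deg, edges[:, 0], 1.0)
    np.add.at(deg, edges[:, 1], 1.0)
    deg[deg == 0] = 1.0
    free = ~pinned
    for _ in range(iters):
        acc = np.zeros_like(v)
        np.add.at(acc, edges[:, 0], v[edges[:, 1]])
        np.add.at(acc, edges[:, 1], v[edges[:, 0]])
        lap = acc / deg[:, None] - v
        v[free] += 0.5 * lap[free]

    out = TissueTemplate(
        vertices=v, triangles=mesh.triangles, tri_cell=mesh.tri_cell,
        wall_type=mesh.wall_type, thickness=mesh.thickness, cells=mesh.cells,
        cell_signs=mesh.cell_signs, boundary_nodes=mesh.boundary_nodes,
        spec=spec, extent=mesh.extent)
    if np.any(out.triangle_areas() <= 1e-6):
        raise ValueError("smoothing produced degenerate triangles")
    return out


def make_template(spec: TemplateSpec) -> TissueTemplate:
    """Full pipeline: 2D grid -> extrusion -> smoothing."""
    return smooth_template(extrude_template(make_cell_grid(spec)))


# --------------------------------------------------------------------------
# Synthetic extensometer traces and patch-test sheets
# --------------------------------------------------------------------------

def synth_extensometer_trace(spec: SyntheticTraceSpec) -> ForceDisplacementCurve:
    """Synthetic raw force-displacement trace with toe region and noise.

    Deterministic for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    d_max = spec.toe_displacement + spec.max_strain * spec.length
    disp = np.linspace(0.0, d_max, spec.n_samples)
    area = spec.width * spec.thickness
    stretch_part = np.clip(disp - spec.toe_displacement, 0.0, None)
    force = spec.apparent_modulus * area * stretch_part / spec.length
    if spec.noise_amplitude > 0:
        force = force + rng.normal(0.0, spec.noise_amplitude, size=force.shape)
    return ForceDisplacementCurve(
        displacement=disp, force=force,
        metadata={"length0": spec.length, "width": spec.width,
                  "thickness": spec.thickness, "kind": "synthetic",
                  "apparent_modulus": spec.apparent_modulus,
                  "toe_displacement": spec.toe_displacement,
                  "rng_seed": spec.rng_seed})


def flat_sheet(width: float = 100.0, height: float = 50.0,
               spacing: float = 10.0, thickness: float = 1.0) -> TissueTemplate:
    """A flat rectangular membrane with no cells (verification fixture).

    Under uniaxial stretch with a Biot-SVK material at ν = 0 the exact
    reaction force is E · (height · thickness) · strain at every step.
    """
    xs = np.arange(0.0, width + 0.5 * spacing, spacing)
    ys = np.arange(0.0, height + 0.5 * spacing, spacing)
    verts, tris = _face(xs, ys,
                        lambda u, v: np.stack([u, v, np.zeros_like(u)], axis=1),
                        np.array([0.0, 0.0, 1.0]))
    tol = 1e-6
    boundary = {
        "left": np.nonzero(np.abs(verts[:, 0]) < tol)[0],
        "right": np.nonzero(np.abs(verts[:, 0] - width) < tol)[0],
        "bottom": np.nonzero(np.abs(verts[:, 1]) < tol)[0],
        "top": np.nonzero(np.abs(verts[:, 1] - height) < tol)[0],
    }
    return TissueTemplate(
        vertices=verts, triangles=tris,
        tri_cell=np.zeros(len(tris), dtype=np.int64),
        wall_type=np.full(len(tris), WALL_OUTER_PERICLINAL),
        thickness=np.full(len(tris), thickness),
        cells=[], boundary_nodes=boundary, spec=None,
        extent=(width, height))
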