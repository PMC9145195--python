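"""Membrane FEM: total potential energy, analytic forces, and equilibrium.

The tissue's total potential is

    Π(u) = W_E(u) - Σ_cells P · V_cell(u)

where ``W_E`` sums the SVK membrane energy density over triangles (density x
reference area x thickness) and ``V_cell`` is the volume enclosed by each
cell's closed deformed surface, computed by the divergence theorem.  The
pressure term is therefore a follower load: its gradient is always normal to
the deformed faces.

Generalized forces (∂Π/∂u) are computed analytically and are exact; the
Hessian is obtained by forward finite differences of the analytic gradient,
exploiting mesh locality through a distance-2 graph coloring so that many
columns are probed per gradient evaluation.

Equilibrium follows the pseudo-time-stepping implicit backward Euler update

    u ← u - dt · (1 + dt·ℍ)⁻¹ · ∂Π/∂u

restricted to unconstrained degrees of freedom.  ``dt`` adapts: it grows
when a step decreases the energy (approaching a full Newton step as
dt → ∞) and shrinks when the step fails or raises the energy, which also
handles indefinite Hessians without modifying them.  Convergence is declared
when the ∞-norm of the free residual drops below the tolerance (µN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import ElementMaterial, MaterialParams

try:
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

__all__ = [
    "LoadCase",
    "SolverOptions",
    "SolverState",
    "FemModel",
    "total_energy",
    "generalized_forces",
    "hessian",
    "equilibrate",
    "apply_dirichlet",
    "reaction_forces",
]


@dataclass
class LoadCase:
    """Cell pressures (MPa) plus Dirichlet displacement constraints (µm)."""

    pressure: float = 0.0
    pressurized_cells: np.ndarray | None = None   # cell ids; None = all cells
    dirichlet: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pressure < 0:
            raise ValueError("pressure must be >= 0")

    def fix(self, nodes, axis: int, values) -> "LoadCase":
        """Prescribe displacement ``values`` on ``nodes`` along ``axis``."""
        nodes = np.atleast_1d(np.asarray(nodes, dtype=int))
        values = np.broadcast_to(np.asarray(values, dtype=float), nodes.shape)
        for n, val in zip(nodes, values):
            key = (int(n), int(axis))
            if key in self.dirichlet and self.dirichlet[key] != val:
                raise ValueError(f"conflicting prescription on node {n} axis {axis}")
            self.dirichlet[key] = float(val)
        return self

    def constrained(self, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
        """(flat dof indices, prescribed values), sorted by dof."""
        if not self.dirichlet:
            return np.empty(0, dtype=int), np.empty(0)
        items = sorted(self.dirichlet.items())
        dofs = np.array([3 * n + ax for (n, ax), _ in items], dtype=int)
        vals = np.array([v for _, v in items])
        if len(dofs) and (dofs.max() >= 3 * n_nodes or dofs.min() < 0):
            raise ValueError("constraint references an invalid node")
        return dofs, vals


@dataclass
class SolverOptions:
    tol: float = 1e-4          # free-residual ∞-norm, µN
    dt0: float = 0.1
    dt_max: float = 1e6
    dt_min: float = 1e-10
    max_iter: int = 60
    fd_step: float = 1e-5      # Hessian FD step, µm
    grow: float = 2.0
    shrink: float = 0.5
    #: Newton-type steps stagnate on membrane micro-wrinkling (compressed
    #: wall patches with near-zero transverse stiffness); after this many
    #: nearly-unproductive iterations a gradient-based quasi-Newton polish
    #: (L-BFGS on the analytic forces) continues the descent.
    stagnation_window: int = 4
    polish_maxiter: int = 2000
    max_polish: int = 8
    #: recompute the Hessian every k-th iteration (1 = every iteration,
    #: as in the original scheme; larger values trade accuracy for speed)
    hessian_lag: int = 1


@dataclass
class SolverState:
    u: np.ndarray                       # (n, 3) nodal displacement, µm
    converged: bool = False
    iterations: int = 0
    residual_history: list[float] = field(default_factory=list)
    energy_history: list[float] = field(default_factory=list)
    dt: float = 0.0


# --------------------------------------------------------------------------
# Fused energy+gradient kernels (numba).  These duplicate the vectorized
# numpy path in materials.ElementMaterial for the solver hot loop; the two
# routes are cross-checked in the test suite.
# --------------------------------------------------------------------------

if HAVE_NUMBA:

    @numba.njit(cache=True)
    def _nb_pressure(x, tris, p, grad):
        Ep = 0.0
        for e in range(tris.shape[0]):
            pe = p[e]
            if pe == 0.0:
                continue
            i0, i1, i2 = tris[e, 0], tris[e, 1], tris[e, 2]
            x00, x01, x02 = x[i0, 0], x[i0, 1], x[i0, 2]
            x10, x11, x12 = x[i1, 0], x[i1, 1], x[i1, 2]
            x20, x21, x22 = x[i2, 0], x[i2, 1], x[i2, 2]
            c0 = x11 * x22 - x12 * x21
            c1 = x12 * x20 - x10 * x22
            c2 = x10 * x21 - x11 * x20
            det = x00 * c0 + x01 * c1 + x02 * c2
            Ep -= pe * det / 6.0
            k = pe / 6.0
            grad[i0, 0] -= k * c0
            grad[i0, 1] -= k * c1
            grad[i0, 2] -= k * c2
            d0 = x21 * x02 - x22 * x01
            d1 = x22 * x00 - x20 * x02
            d2 = x20 * x01 - x21 * x00
            grad[i1, 0] -= k * d0
            grad[i1, 1] -= k * d1
            grad[i1, 2] -= k * d2
            f0 = x01 * x12 - x02 * x11
            f1 = x02 * x10 - x00 * x12
            f2 = x00 * x11 - x01 * x10
            grad[i2, 0] -= k * f0
            grad[i2, 1] -= k * f1
            grad[i2, 2] -= k * f2
        return Ep

    @numba.njit(cache=True)
    def _nb_elastic(x, tris, Dinv, wv, mode, lam, mu, El, Et, mus, fr, grad):
        """Accumulate elastic energy and forces.

        mode 0: isotropic SVK on Biot strain; 1: isotropic SVK on
        Green-Lagrange strain; 2: orthotropic SVK on Green-Lagrange strain
        with per-triangle frames ``fr`` (longitudinal direction in the local
        2D chart).  Returns inf on an inverted/degenerate element.
        """
        E_total = 0.0
        for e in range(tris.shape[0]):
            i0, i1, i2 = tris[e, 0], tris[e, 1], tris[e, 2]
            a0 = x[i1, 0] - x[i0, 0]
            a1 = x[i1, 1] - x[i0, 1]
            a2 = x[i1, 2] - x[i0, 2]
            b0 = x[i2, 0] - x[i0, 0]
            b1 = x[i2, 1] - x[i0, 1]
            b2 = x[i2, 2] - x[i0, 2]
            D00 = Dinv[e, 0, 0]
            D01 = Dinv[e, 0, 1]
            D10 = Dinv[e, 1, 0]
            D11 = Dinv[e, 1, 1]
            f00 = a0 * D00 + b0 * D10
            f10 = a1 * D00 + b1 * D10
            f20 = a2 * D00 + b2 * D10
            f01 = a0 * D01 + b0 * D11
            f11 = a1 * D01 + b1 * D11
            f21 = a2 * D01 + b2 * D11
            C00 = f00 * f00 + f10 * f10 + f20 * f20
            C01 = f00 * f01 + f10 * f11 + f20 * f21
            C11 = f01 * f01 + f11 * f11 + f21 * f21
            if mode == 0:
                I1 = C00 + C11
                I2 = C00 * C11 - C01 * C01
                if I2 <= 0.0:
                    return np.inf
                d = np.sqrt(I2)
                s = np.sqrt(I1 + 2.0 * d)
                W = 0.5 * lam[e] * (s - 2.0) ** 2 + mu[e] * (I1 - 2.0 * s + 2.0)
                dWds = lam[e] * (s - 2.0) - 2.0 * mu[e]
                dI1 = dWds / (2.0 * s) + mu[e]
                dI2 = dWds / (2.0 * s * d)
                g00 = 2.0 * (dI1 * f00 + dI2 * (f00 * C11 - f01 * C01))
                g10 = 2.0 * (dI1 * f10 + dI2 * (f10 * C11 - f11 * C01))
                g20 = 2.0 * (dI1 * f20 + dI2 * (f20 * C11 - f21 * C01))
                g01 = 2.0 * (dI1 * f01 + dI2 * (f01 * C00 - f00 * C01))
                g11 = 2.0 * (dI1 * f11 + dI2 * (f11 * C00 - f10 * C01))
                g21 = 2.0 * (dI1 * f21 + dI2 * (f21 * C00 - f20 * C01))
            else:
                E00 = 0.5 * (C00 - 1.0)
                E01 = 0.5 * C01
                E11 = 0.5 * (C11 - 1.0)
                if mode == 1:
                    tr = E00 + E11
                    W = (0.5 * lam[e] * tr * tr
                         + mu[e] * (E00 * E00 + E11 * E11 + 2.0 * E01 * E01))
                    S00 = lam[e] * tr + 2.0 * mu[e] * E00
                    S11 = lam[e] * tr + 2.0 * mu[e] * E11
                    S01 = 2.0 * mu[e] * E01
                else:
                    p0 = fr[e, 0]
                    p1 = fr[e, 1]
                    q0 = -p1
                    q1 = p0
                    Eaa = p0 * p0 * E00 + 2.0 * p0 * p1 * E01 + p1 * p1 * E11
                    Ebb = q0 * q0 * E00 + 2.0 * q0 * q1 * E01 + q1 * q1 * E11
                    Eab = (p0 * q0 * E00 + (p0 * q1 + p1 * q0) * E01
                           + p1 * q1 * E11)
                    W = (0.5 * El[e] * Eaa * Eaa + 0.5 * Et[e] * Ebb * Ebb
                         + 2.0 * mus[e] * Eab * Eab)
                    Saa = El[e] * Eaa
                    Sbb = Et[e] * Ebb
                    Sab = 2.0 * mus[e] * Eab
                    S00 = p0 * p0 * Saa + q0 * q0 * Sbb + 2.0 * p0 * q0 * Sab
                    S11 = p1 * p1 * Saa + q1 * q1 * Sbb + 2.0 * p1 * q1 * Sab
                    S01 = (p0 * p1 * Saa + q0 * q1 * Sbb
                           + (p0 * q1 + p1 * q0) * Sab)
                g00 = f00 * S00 + f01 * S01
                g10 = f10 * S00 + f11 * S01
                g20 = f20 * S00 + f21 * S01
                g01 = f00 * S01 + f01 * S11
                g11 = f10 * S01 + f11 * S11
                g21 = f20 * S01 + f21 * S11
            w = wv[e]
            E_total += W * w
            ca0 = (g00 * D00 + g01 * D01) * w
            ca1 = (g10 * D00 + g11 * D01) * w
            ca2 = (g20 * D00 + g21 * D01) * w
            cb0 = (g00 * D10 + g01 * D11) * w
            cb1 = (g10 * D10 + g11 * D11) * w
            cb2 = (g20 * D10 + g21 * D11) * w
            grad[i1, 0] += ca0
            grad[i1, 1] += ca1
            grad[i1, 2] += ca2
            grad[i2, 0] += cb0
            grad[i2, 1] += cb1
            grad[i2, 2] += cb2
            grad[i0, 0] -= ca0 + cb0
            grad[i0, 1] -= ca1 + cb1
            grad[i0, 2] -= ca2 + cb2
        return E_total


class FemModel:
    """Precomputed element data for a tissue template + material."""

    def __init__(self, template, material: MaterialParams,
                 wall_moduli: dict[int, float] | None = None):
        self.template = template
        self.material = material
        self.verts0 = np.asarray(template.vertices, dtype=float)
        self.tris = np.asarray(template.triangles, dtype=np.int64)
        self.thickness = np.asarray(template.thickness, dtype=float)
        self.n_nodes = len(self.verts0)
        self.n_tris = len(self.tris)
        self.cells = template.cells

        X = self.verts0
        e1 = X[self.tris[:, 1]] - X[self.tris[:, 0]]
        e2 = X[self.tris[:, 2]] - X[self.tris[:, 0]]
        n = np.cross(e1, e2)
        n_norm = np.linalg.norm(n, axis=1)
        if np.any(n_norm <= 1e-12):
            raise ValueError("degenerate reference triangle")
        q1 = e1 / np.linalg.norm(e1, axis=1)[:, None]
        nn = n / n_norm[:, None]
        q2 = np.cross(nn, q1)
        self.Q = np.stack([q1, q2], axis=2)          # (m, 3, 2)
        D = np.empty((self.n_tris, 2, 2))
        D[:, 0, 0] = np.einsum("mi,mi->m", q1, e1)
        D[:, 1, 0] = np.einsum("mi,mi->m", q2, e1)
        D[:, 0, 1] = np.einsum("mi,mi->m", q1, e2)
        D[:, 1, 1] = np.einsum("mi,mi->m", q2, e2)
        self.Dinv = np.linalg.inv(D)
        self.area0 = 0.5 * np.linalg.det(D)
        self.wv = self.area0 * self.thickness        # reference wall volume

        self.elem_material = self._build_material(template, material, wall_moduli)
        self._coloring = None
        self._nbh = None
        self._hess_plan = None
        # flattened dof indices for fast bincount scatter of per-triangle
        # nodal force blocks (m, 3 corners, 3 axes)
        ax = np.arange(3)
        self._scatter_idx = (3 * self.tris[:, :, None] + ax).ravel()

    def _build_material(self, template, material, wall_moduli):
        if material.is_isotropic and wall_moduli is None:
            return ElementMaterial(material, self.n_tris)
        # longitudinal direction = global x projected onto each wall plane
        ex = np.array([1.0, 0.0, 0.0])
        a2 = np.einsum("mik,i->mk", self.Q, ex)
        nrm = np.linalg.norm(a2, axis=1)
        degen = nrm < 1e-6
        a2[degen] = [1.0, 0.0]
        a2[~degen] /= nrm[~degen, None]
        frames = np.empty((self.n_tris, 2, 2))
        frames[:, 0] = a2
        frames[:, 1, 0] = -a2[:, 1]
        frames[:, 1, 1] = a2[:, 0]
        if material.is_isotropic:
            em = ElementMaterial(material, self.n_tris)
            scale = np.ones(self.n_tris)
            for wtype, E in (wall_moduli or {}).items():
                scale[template.wall_type == wtype] = E / material.E_long
            em.lam *= scale
            em.mu *= scale
            return em
        El = np.where(degen, material.E_trans, material.E_long)
        Et = np.full(self.n_tris, material.E_trans)
        return ElementMaterial(material, self.n_tris, frames=frames,
                               E_long_tri=El, E_trans_tri=Et)

    # -- kinematics --------------------------------------------------------

    def deformed(self, u: np.ndarray) -> np.ndarray:
        return self.verts0 + u.reshape(self.n_nodes, 3)

    def deformation_gradients(self, x: np.ndarray) -> np.ndarray:
        """Per-triangle 3x2 tangent maps from deformed coordinates."""
        dM = np.stack([x[self.tris[:, 1]] - x[self.tris[:, 0]],
                       x[self.tris[:, 2]] - x[self.tris[:, 0]]], axis=2)
        return dM @ self.Dinv

    def _tri_pressures(self, load: LoadCase) -> np.ndarray:
        """Signed per-triangle pressure coefficients.

        A shared-band wall bounded by two equally pressurized cells gets a
        net coefficient of zero (pressure acts on both sides).
        """
        p = np.zeros(self.n_tris)
        if load.pressure == 0.0 or not self.cells:
            return p
        cell_ids = (range(len(self.cells)) if load.pressurized_cells is None
                    else load.pressurized_cells)
        signs = self.template.cell_signs
        for c in cell_ids:
            c = int(c)
            p[self.cells[c]] += load.pressure * signs[c]
        return p

    def cell_volumes(self, u: np.ndarray) -> np.ndarray:
        return self.template.cell_volumes(self.deformed(u))

    def cauchy_traces(self, u: np.ndarray) -> np.ndarray:
        """Per-element Tr(Cauchy stress) in MPa, for heatmap export."""
        F = self.deformation_gradients(self.deformed(u))
        return self.elem_material.cauchy_trace(F)

    def energy_and_grad(self, u: np.ndarray, load: LoadCase,
                        use_numba: bool | None = None,
                        ) -> tuple[float, np.ndarray]:
        """Fused Π(u) and ∂Π/∂u (the solver hot path)."""
        x = self.deformed(u)
        p = self._tri_pressures(load)
        em = self.elem_material
        if HAVE_NUMBA if use_numba is None else use_numba:
            grad = np.zeros((self.n_nodes, 3))
            empty = np.empty(0)
            empty_fr = np.empty((0, 2))
            if not em.anisotropic:
                mode = 0 if em.measure == "biot" else 1
                E = _nb_elastic(x, self.tris, self.Dinv, self.wv, mode,
                                em.lam, em.mu, empty, empty, empty, empty_fr,
                                grad)
            else:
                E = _nb_elastic(x, self.tris, self.Dinv, self.wv, 2,
                                empty, empty, em.E_l, em.E_t, em.mu_s,
                                em.frames[:, 0, :].copy(), grad)
            if not np.isfinite(E):
                raise FloatingPointError("inverted or degenerate element")
            E += _nb_pressure(x, self.tris, p, grad)
            return E, grad
        # numpy fallback (also the reference route for cross-checks)
        F = self.deformation_gradients(x)
        W, dWdF = em.energy_grad(F)
        E = float(np.dot(W, self.wv))
        G = self.wv[:, None, None] * (dWdF @ np.swapaxes(self.Dinv, 1, 2))
        blocks = np.empty((self.n_tris, 3, 3))
        blocks[:, 1] = G[:, :, 0]
        blocks[:, 2] = G[:, :, 1]
        blocks[:, 0] = -(G[:, :, 0] + G[:, :, 1])
        if np.any(p):
            t = self.tris
            x0, x1, x2 = x[t[:, 0]], x[t[:, 1]], x[t[:, 2]]
            c = (p / 6.0)[:, None]
            blocks[:, 0] -= c * np.cross(x1, x2)
            blocks[:, 1] -= c * np.cross(x2, x0)
            blocks[:, 2] -= c * np.cross(x0, x1)
            dets = np.einsum("mi,mi->m", x0, np.cross(x1, x2))
            E -= float(np.dot(p, dets)) / 6.0
        grad = np.bincount(self._scatter_idx, weights=blocks.ravel(),
                           minlength=3 * self.n_nodes)
        return E, grad.reshape(self.n_nodes, 3)

    # -- Hessian plumbing ---------------------------------------------------

    def _adjacency(self):
        if self._nbh is not None:
            return self._nbh, self._coloring
        adj = [set() for _ in range(self.n_nodes)]
        for a, b, c in self.tris:
            adj[a].update((a, b, c))
            adj[b].update((a, b, c))
            adj[c].update((a, b, c))
        nbh = [np.fromiter(sorted(s), dtype=np.int64) for s in adj]
        # greedy distance-2 coloring: no two same-colored nodes may share a
        # Hessian row, i.e. may have overlapping closed neighborhoods
        color = np.full(self.n_nodes, -1, dtype=np.int64)
        order = np.argsort([-len(s) for s in adj])
        for v in order:
            used = set()
            for w in adj[v]:
                for x_ in adj[w]:
                    if color[x_] >= 0:
                        used.add(color[x_])
            c = 0
            while c in used:
                c += 1
            color[v] = c
        groups = [np.nonzero(color == c)[0] for c in range(color.max() + 1)]
        self._nbh, self._coloring = nbh, groups
        # precompute flattened scatter plans: for each color, the nodes whose
        # gradient entries form the Hessian columns of the perturbed nodes
        ax = np.arange(3)
        plan = []
        for group in groups:
            gn = np.concatenate([nbh[v] for v in group])
            rows = (3 * gn[:, None] + ax).ravel()
            colv = np.concatenate([np.full(len(nbh[v]), v) for v in group])
            cols = np.repeat(3 * colv, 3)
            plan.append((group, gn, rows, cols))
        self._hess_plan = plan
        return nbh, groups


# --------------------------------------------------------------------------
# Energy, forces, Hessian
# --------------------------------------------------------------------------

def total_energy(model: FemModel, u: np.ndarray, load: LoadCase) -> float:
    """Π(u) = Σ W·area₀·thickness − Σ_cells P·V_cell(u), in µN·µm (pJ)."""
    return model.energy_and_grad(u, load)[0]


def generalized_forces(model: FemModel, u: np.ndarray,
                       load: LoadCase) -> np.ndarray:
    """Analytic ∂Π/∂u, shape (n_nodes, 3), in µN."""
    return model.energy_and_grad(u, load)[1]


def hessian(model: FemModel, u: np.ndarray, load: LoadCase,
            fd_step: float = 1e-5) -> sp.csr_matrix:
    """ℍ by forward differences of the analytic gradient, symmetrized.

    Uses a distance-2 coloring of the mesh graph: all nodes of one color are
    perturbed together (per axis), and each perturbed node's Hessian column
    is read off from its closed neighborhood, so a full Hessian costs
    3 x (number of colors) gradient evaluations.
    """
    model._adjacency()
    n = model.n_nodes
    u = u.reshape(n, 3)
    g0 = generalized_forces(model, u, load)
    rows, cols, vals = [], [], []
    for group, gn, rows_base, cols_base in model._hess_plan:
        for ax in range(3):
            up = u.copy()
            up[group, ax] += fd_step
            g1 = generalized_forces(model, up, load)
            diff = (g1 - g0) / fd_step
            rows.append(rows_base)
            cols.append(cols_base + ax)
            vals.append(diff[gn].ravel())
    H = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n, 3 * n)).tocsr()
    return (H + H.T) * 0.5


# --------------------------------------------------------------------------
# Equilibrium
# --------------------------------------------------------------------------

def apply_dirichlet(u: np.ndarray, load: LoadCase, n_nodes: int) -> np.ndarray:
    """Return u with constrained entries set to their prescribed values."""
    u = np.array(u, dtype=float).reshape(n_nodes, 3)
    dofs, vals = load.constrained(n_nodes)
    u.ravel()[dofs] = vals
    return u


def reaction_forces(model: FemModel, u: np.ndarray, load: LoadCase) -> np.ndarray:
    """Reaction force at each constrained dof (µN), in constraint order."""
    g = generalized_forces(model, u, load).ravel()
    dofs, _ = load.constrained(model.n_nodes)
    return g[dofs]


def _polish(model: FemModel, u: np.ndarray, load: LoadCase,
            free: np.ndarray, opts: SolverOptions):
    """Descend through wrinkling plateaus with L-BFGS on the analytic forces."""
    from scipy.optimize import minimize
    n = model.n_nodes
    u = u.reshape(n, 3)
    fixed = u.ravel()[~free]

    def assemble(x):
        w = np.empty(3 * n)
        w[free] = x
        w[~free] = fixed
        return w.reshape(n, 3)

    def fun(x):
        try:
            E, g = model.energy_and_grad(assemble(x), load)
        except FloatingPointError:
            return np.inf, np.zeros(int(free.sum()))
        return E, g.ravel()[free]

    res = minimize(fun, u.ravel()[free], jac=True, method="L-BFGS-B",
                   options={"maxiter": opts.polish_maxiter,
                            "maxcor": 30, "ftol": 1e-18, "gtol": 0.1 * opts.tol})
    u_new = assemble(res.x)
    E, g = model.energy_and_grad(u_new, load)
    return u_new, E, g.ravel()


def equilibrate(model: FemModel, load: LoadCase,
                u0: np.ndarray | None = None,
                options: SolverOptions | None = None) -> SolverState:
    """Minimize Π by the adaptive pseudo-time implicit Euler scheme."""
    opts = options or SolverOptions()
    n = model.n_nodes
    u = np.zeros((n, 3)) if u0 is None else np.array(u0, float).reshape(n, 3)
    u = apply_dirichlet(u, load, n)
    dofs, _ = load.constrained(n)
    free = np.ones(3 * n, dtype=bool)
    free[dofs] = False

    state = SolverState(u=u)
    E, g = model.energy_and_grad(u, load)
    g = g.ravel()
    res = float(np.abs(g[free]).max()) if free.any() else 0.0
    state.residual_history.append(res)
    state.energy_history.append(E)
    if res <= opts.tol:
        state.converged = True
        state.u = u
        return state

    dt = opts.dt0
    eye = sp.identity(int(free.sum()), format="csc")
    polished = 0
    Hff = None
    for it in range(1, opts.max_iter + 1):
        if Hff is None or (it - 1) % opts.hessian_lag == 0:
            H = hessian(model, u, load, opts.fd_step)
            Hff = H[free][:, free].tocsc()
        gf = g[free]
        accepted = False
        while dt >= opts.dt_min:
            A = eye + dt * Hff
            try:
                du = spla.splu(A).solve(gf)
            except RuntimeError:
                dt *= opts.shrink
                continue
            if not np.all(np.isfinite(du)):
                dt *= opts.shrink
                continue
            step = dt * du
            # predicted decrease of the linearized model; non-positive means
            # the (indefinite-Hessian) direction is not a descent direction
            pred = float(gf @ step)
            u_new = u.copy()
            u_new.ravel()[free] -= step
            try:
                E_new, g_new = model.energy_and_grad(u_new, load)
            except FloatingPointError:
                dt *= opts.shrink
                continue
            slack = 1e-10 * (1.0 + abs(E))
            if pred > 0 and E_new <= E - 1e-4 * pred + slack:
                accepted = True
                break
            dt *= opts.shrink
        if not accepted:
            if polished < opts.max_polish:
                # no descent direction from the pseudo-time step (deeply
                # indefinite Hessian); fall back to gradient-based descent
                u, E, g = _polish(model, u, load, free, opts)
                polished += 1
                dt = opts.dt0
                res = float(np.abs(g[free]).max())
                state.residual_history.append(res)
                state.energy_history.append(E)
                state.iterations = it
                if res <= opts.tol:
                    state.converged = True
                    break
                continue
            warnings.warn(f"pseudo-time solver stalled at iteration {it}, "
                          f"residual {res:.3g} µN")
            break
        u, E, g = u_new, E_new, g_new.ravel()
        dt = min(dt * opts.grow, opts.dt_max)
        res = float(np.abs(g[free]).max())
        state.residual_history.append(res)
        state.energy_history.append(E)
        state.iterations = it
        if res <= opts.tol:
            state.converged = True
            break
        w = opts.stagnation_window
        if (polished < opts.max_polish and len(state.residual_history) > w
                and res > 0.7 * state.residual_history[-1 - w]):
            u, E, g = _polish(model, u, load, free, opts)
            polished += 1
            res = float(np.abs(g[free]).max())
            state.residual_history.append(res)
            state.energy_history.append(E)
            if res <= opts.tol:
                state.converged = True
                break
    state.u = u
    state.dt = dt
    if not state.converged and res > opts.tol:
        warnings.warn(f"equilibrate did not converge: residual {res:.3g} µN "
                      f"after {state.iterations} iterations")
    return state
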