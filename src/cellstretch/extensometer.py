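"""Virtual extensometer: pressurize, clamp, stretch, log reaction forces.

The protocol mirrors a microextensometer run on an epidermal peel:

1. :func:`pressurize` inflates the cells to the target turgor pressure
   (ramped in a few increments), with only rigid-body pinning — no clamps —
   and reports the relative cell-volume increase.
2. :func:`stretch` clamps the stretch-axis coordinate of the end nodes at
   their pressurized positions, then displaces one end in equal increments,
   re-equilibrating after each step.  The reaction force along the stretch
   axis, summed over the displaced end's nodes, is logged against the
   cumulative displacement.  Displacement and force are measured relative to
   the pressurized equilibrium, whose end-to-end distance also serves as the
   reference length for strain.

Lateral edges stay free, allowing the transverse narrowing responsible for
the geometric strain stiffening of cellular tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .solver import (FemModel, LoadCase, SolverOptions, SolverState,
                     equilibrate, generalized_forces)
from .materials import MaterialParams

__all__ = [
    "StretchProtocol",
    "ForceDisplacementCurve",
    "pressurize",
    "stretch",
    "run_experiment_grid",
]


@dataclass
class StretchProtocol:
    """How to stretch: direction, total strain, step count, turgor pressure."""

    direction: str = "longitudinal"      # longitudinal (x) | transverse (y)
    total_strain: float = 0.5            # fraction of reference length
    steps: int = 25
    pressure: float = 0.5                # MPa; 0.5 turgid, 0.01 plasmolyzed

    def __post_init__(self) -> None:
        if self.direction not in ("longitudinal", "transverse"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.total_strain <= 0:
            raise ValueError("total strain must be positive")
        if self.steps < 10:
            raise ValueError("need at least 10 displacement steps")
        if self.pressure < 0:
            raise ValueError("pressure must be >= 0")

    @property
    def axis(self) -> int:
        return 0 if self.direction == "longitudinal" else 1


@dataclass
class ForceDisplacementCurve:
    """Logged extensometer output: displacement (µm) vs summed force (µN)."""

    displacement: np.ndarray
    force: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.shape != self.force.shape:
            raise ValueError("displacement and force must have equal length")
        if len(self.displacement) and np.any(np.diff(self.displacement) <= 0):
            raise ValueError("displacement samples must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"displacement_um": self.displacement,
                             "force_uN": self.force})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **metadata) -> "ForceDisplacementCurve":
        df = pd.read_csv(path)
        return cls(displacement=df["displacement_um"].to_numpy(),
                   force=df["force_uN"].to_numpy(), metadata=metadata)


# --------------------------------------------------------------------------

def _rigid_body_pins(model: FemModel, load: LoadCase, u: np.ndarray,
                     axes: tuple[int, ...] = (0, 1, 2)) -> None:
    """3-2-1 pinning of a free-floating body at current displacements."""
    X = model.verts0
    center = 0.5 * (X.max(axis=0) + X.min(axis=0))
    a = int(np.argmin(np.linalg.norm(X - center, axis=1)))
    # lever arms: farthest-in-x node, then farthest-in-y (distinct from b)
    b = int(np.argmax(np.abs(X[:, 0] - X[a, 0])))
    dy = np.abs(X[:, 1] - X[a, 1]).copy()
    dy[b] = -1.0
    c = int(np.argmax(dy))
    u = u.reshape(model.n_nodes, 3)
    for ax in axes:
        load.fix([a], ax, u[a, ax])
    for ax in (1, 2):
        load.fix([b], ax, u[b, ax])
    load.fix([c], 2, u[c, 2])


def pressurize(template, pressure: float,
               material: MaterialParams | None = None,
               options: SolverOptions | None = None,
               n_ramp: int = 2,
               model: FemModel | None = None,
               ) -> tuple[FemModel, SolverState, float]:
    """Inflate all cells to ``pressure`` (MPa); return (model, state, dV/V₀).

    The pressure is ramped in ``n_ramp`` equal increments to keep the
    pseudo-time solver in its basin of convergence.  Only rigid-body pins are
    applied.  ``volume_change`` is Σ(V−V₀)/ΣV₀ over all cells.
    """
    material = material or MaterialParams.isotropic()
    model = model or FemModel(template, material)
    u = np.zeros((model.n_nodes, 3))
    state = SolverState(u=u, converged=True)
    if pressure > 0 and model.cells:
        from dataclasses import replace as _replace
        opts = options or SolverOptions()
        ramp_opts = _replace(opts, tol=20.0 * opts.tol)  # intermediate steps
        for p in np.linspace(pressure / n_ramp, pressure, n_ramp):
            load = LoadCase(pressure=p)
            _rigid_body_pins(model, load, u)
            o = opts if p == pressure else ramp_opts
            state = equilibrate(model, load, u0=u, options=o)
            u = state.u
            if not state.converged:
                warnings.warn(f"pressurize: not converged at P={p:.3g} MPa")
    V0 = template.cell_volumes()
    V = model.cell_volumes(u)
    vol_change = float((V.sum() - V0.sum()) / V0.sum()) if len(V0) else 0.0
    return model, state, vol_change


def stretch(model: FemModel, state: SolverState, protocol: StretchProtocol,
            options: SolverOptions | None = None,
            record_fields: bool = False,
            ) -> ForceDisplacementCurve:
    """Stretch the pressurized tissue between virtual clamps.

    One end's stretch-axis coordinates are held at their pressurized values;
    the other end is displaced in ``protocol.steps`` equal increments up to
    ``total_strain x reference length``.  After each re-equilibration the
    reaction force along the axis is summed over the displaced nodes.  If a
    step fails to converge the curve is truncated with a warning.
    """
    template = model.template
    ax = protocol.axis
    lo_name, hi_name = (("left", "right") if ax == 0 else ("bottom", "top"))
    lo = template.boundary_nodes[lo_name]
    hi = template.boundary_nodes[hi_name]
    if len(lo) == 0 or len(hi) == 0:
        raise ValueError("template has no end nodes along the stretch axis")

    u = state.u.reshape(model.n_nodes, 3).copy()
    x = model.deformed(u)
    ref_length = float(x[hi, ax].mean() - x[lo, ax].mean())

    disps, forces = [0.0], []
    fields = []
    step_disp = protocol.total_strain * ref_length / protocol.steps
    u_cur = u
    last_state = state

    def make_load(total: float) -> LoadCase:
        load = LoadCase(pressure=protocol.pressure)
        load.fix(lo, ax, u[lo, ax])
        load.fix(hi, ax, u[hi, ax] + total)
        _pin_lateral(model, load, u, ax)
        return load

    # step 0: clamp at zero displacement (reaction ≈ 0 for a free-pressurized
    # equilibrium; recorded as the curve origin)
    load0 = make_load(0.0)
    st = equilibrate(model, load0, u0=u_cur, options=options)
    u_cur = st.u
    forces.append(_end_reaction(model, u_cur, load0, hi, ax))
    if record_fields:
        fields.append(model.cauchy_traces(u_cur))

    truncated = False
    for k in range(1, protocol.steps + 1):
        load = make_load(k * step_disp)
        try:
            st = equilibrate(model, load, u0=u_cur, options=options)
        except FloatingPointError as err:
            warnings.warn(f"stretch truncated at step {k}: {err}")
            truncated = True
            break
        if not st.converged:
            warnings.warn(f"stretch truncated at step {k}: no convergence")
            truncated = True
            break
        u_cur = st.u
        last_state = st
        disps.append(k * step_disp)
        forces.append(_end_reaction(model, u_cur, load, hi, ax))
        if record_fields:
            fields.append(model.cauchy_traces(u_cur))

    W, H = template.extent
    meta = {
        "direction": protocol.direction,
        "pressure": protocol.pressure,
        "length0": ref_length,
        "width": H if ax == 0 else W,
        "thickness": template.depth,
        "steps": protocol.steps,
        "truncated": truncated,
        "u_final": u_cur,
    }
    if record_fields:
        meta["cauchy_trace_fields"] = fields
    return ForceDisplacementCurve(displacement=np.array(disps),
                                  force=np.array(forces), metadata=meta)


def _pin_lateral(model: FemModel, load: LoadCase, u: np.ndarray,
                 stretch_axis: int) -> None:
    """Remove the rigid modes the end clamps leave free.

    Clamping only the stretch-axis coordinate leaves two translations and the
    rotation about the stretch axis unconstrained; two interior pins near the
    template center remove them.
    """
    other = [a for a in range(3) if a != stretch_axis]
    X = model.verts0
    center = 0.5 * (X.max(axis=0) + X.min(axis=0))
    a = int(np.argmin(np.linalg.norm(X - center, axis=1)))
    u = u.reshape(model.n_nodes, 3)
    for axx in other:
        load.fix([a], axx, u[a, axx])
    lateral = other[0]          # in-plane axis orthogonal to the stretch
    off = np.abs(X[:, lateral] - X[a, lateral])
    b = int(np.argmax(off))
    load.fix([b], 2, u[b, 2])


def _end_reaction(model: FemModel, u: np.ndarray, load: LoadCase,
                  end_nodes: np.ndarray, axis: int) -> float:
    g = generalized_forces(model, u, load)
    return float(g[end_nodes, axis].sum())


def run_experiment_grid(runs: Iterable[tuple], options=None,
                        ) -> list[ForceDisplacementCurve]:
    """Run (template, material, protocol) combinations; log failures, continue.

    Each item of ``runs`` is ``(template, material, protocol)``.  Pressurized
    states are recomputed per run; callers wanting to reuse a pressurized
    state across directions should call :func:`pressurize`/:func:`stretch`
    directly.
    """
    curves = []
    for i, (template, material, protocol) in enumerate(runs):
        try:
            model, st, dv = pressurize(template, protocol.pressure, material,
                                       options=options)
            curve = stretch(model, st, protocol, options=options)
            curve.metadata["volume_change"] = dv
            curves.append(curve)
        except Exception as err:  # individual failures must not kill the grid
            warnings.warn(f"experiment {i} failed: {err}")
    return curves
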