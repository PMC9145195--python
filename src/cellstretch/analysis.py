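"""Normalize extensometer curves and estimate cell-wall anisotropy.

Force-displacement curves (simulated or experimental-style) are converted to
tissue stress-strain: stress = force / (sample width x thickness) in MPa,
strain = 100 x displacement / original length.  The 20 % strain point is the
standard reference for comparing stiffness across samples and directions —
it sits in the elastic regime, below rupture, for both directions.

:func:`fit_longitudinal_fraction` inverts the tissue-level measurement: it
searches for the ratio of the wall's longitudinal to transverse Young's
modulus at which the *simulated* tissue stiffness ratio matches a target
(e.g. an experimentally measured one), by monotone bisection over the
fraction.  Because the anisotropic wall model uses the Green-Lagrange
strain, stresses at finite strain carry a known quadratic inflation relative
to the engineering-strain measure; an optional linearization divides each
direction's 20 %-strain stress by the Green/engineering secant factor
(1 + ε/2 at strain ε) before the ratio is formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extensometer import ForceDisplacementCurve, StretchProtocol, pressurize, stretch
from .materials import MaterialParams
from .solver import SolverOptions

__all__ = [
    "StressStrainCurve",
    "AnisotropyFit",
    "to_stress_strain",
    "remove_toe",
    "stress_at_strain",
    "stiffness_ratio",
    "fit_longitudinal_fraction",
]


@dataclass
class StressStrainCurve:
    """Normalized curve: strain in % of original length, stress in MPa."""

    strain: np.ndarray
    stress: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if np.any(self.strain < 0) or np.any(np.diff(self.strain) <= 0):
            raise ValueError("strain must be non-negative and increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"strain_percent": self.strain,
                             "stress_MPa": self.stress})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def to_stress_strain(curve: ForceDisplacementCurve, width: float,
                     thickness: float, length0: float) -> StressStrainCurve:
    """Normalize force by cross-section (width x thickness) and displacement
    by the original sample length."""
    if width <= 0 or thickness <= 0 or length0 <= 0:
        raise ValueError("sample dimensions must be positive")
    return StressStrainCurve(
        strain=100.0 * curve.displacement / length0,
        stress=curve.force / (width * thickness),
        provenance=dict(curve.metadata, width=width, thickness=thickness,
                        length0=length0))


def remove_toe(curve: ForceDisplacementCurve,
               force_floor: float) -> ForceDisplacementCurve:
    """Drop the leading low-force toe region of a raw curve.

    The toe is the slack-straightening phase of an experimental trace and
    carries no stiffness information.  Samples before the first force above
    ``force_floor`` are dropped and displacement is re-zeroed at the first
    retained sample.
    """
    above = np.nonzero(curve.force >= force_floor)[0]
    if len(above) == 0:
        raise ValueError("entire curve lies below the force floor")
    i0 = int(above[0])
    return ForceDisplacementCurve(
        displacement=curve.displacement[i0:] - curve.displacement[i0],
        force=curve.force[i0:],
        metadata=dict(curve.metadata, toe_removed_at=float(curve.displacement[i0])))


def stress_at_strain(curve: StressStrainCurve, ref_strain: float = 20.0) -> float:
    """Stress (MPa) at ``ref_strain`` %, by linear interpolation."""
    if len(curve.strain) == 0 or curve.strain[-1] < ref_strain - 1e-9:
        raise ValueError(f"curve ends at {curve.strain[-1] if len(curve.strain) else 0:.3g}% "
                         f"before the {ref_strain}% reference strain")
    return float(np.interp(ref_strain, curve.strain, curve.stress))


def stiffness_ratio(long_curve: StressStrainCurve,
                    trans_curve: StressStrainCurve,
                    ref_strain: float = 20.0) -> float:
    """Longitudinal / transverse stress ratio at the reference strain."""
    s_t = stress_at_strain(trans_curve, ref_strain)
    if s_t == 0:
        raise ValueError("zero transverse stress at the reference strain")
    return stress_at_strain(long_curve, ref_strain) / s_t


@dataclass
class AnisotropyFit:
    """Result of fitting E_long/E_trans to a target tissue stiffness ratio."""

    fraction: float
    target_ratio: float
    achieved_ratio: float
    linearized: bool
    trace: list[tuple[float, float]] = field(default_factory=list)
    at_boundary: bool = False


def _green_secant_factor(ref_strain_percent: float) -> float:
    """Green/engineering uniaxial secant ratio at strain ε: E_G/ε = 1 + ε/2."""
    eps = ref_strain_percent / 100.0
    return 1.0 + 0.5 * eps


def fit_longitudinal_fraction(template, target_ratio: float,
                              E_trans: float = 100.0,
                              pressure: float = 0.01,
                              total_strain: float = 0.2,
                              steps: int = 10,
                              ref_strain: float = 20.0,
                              fit_tol: float = 0.05,
                              linearize: bool = True,
                              options: SolverOptions | None = None,
                              ) -> AnisotropyFit:
    """Bisection for the wall modulus fraction E_long/E_trans in (0, 1].

    For each candidate fraction the template is pressurized with the
    transversely isotropic wall material and stretched in both directions to
    the reference strain; the simulated tissue stiffness ratio (optionally
    Green-linearized) is compared with ``target_ratio``.  The achieved ratio
    increases monotonically with the fraction, which justifies bisection.
    Stops within ``fit_tol`` relative of the target or when the bracket
    shrinks below 0.01; a target outside the reachable range returns the
    boundary with ``at_boundary=True`` (never a silent clamp).
    """
    if target_ratio <= 0:
        raise ValueError("target ratio must be positive")
    trace: list[tuple[float, float]] = []
    corr = _green_secant_factor(ref_strain) if linearize else 1.0

    def achieved(fraction: float) -> float:
        mat = MaterialParams.transversely_isotropic(
            E_long=fraction * E_trans, E_trans=E_trans)
        model, st, _ = pressurize(template, pressure, mat, options=options)
        stresses = {}
        for direction in ("longitudinal", "transverse"):
            proto = StretchProtocol(direction=direction,
                                    total_strain=total_strain, steps=steps,
                                    pressure=pressure)
            curve = stretch(model, st, proto, options=options)
            ss = to_stress_strain(curve, curve.metadata["width"],
                                  curve.metadata["thickness"],
                                  curve.metadata["length0"])
            stresses[direction] = stress_at_strain(ss, ref_strain) / corr
        r = stresses["longitudinal"] / stresses["transverse"]
        trace.append((fraction, r))
        return r

    hi_f, hi_r = 1.0, achieved(1.0)
    if abs(hi_r - target_ratio) / target_ratio <= fit_tol or target_ratio >= hi_r:
        return AnisotropyFit(fraction=1.0, target_ratio=target_ratio,
                             achieved_ratio=hi_r, linearized=linearize,
                             trace=trace, at_boundary=target_ratio > hi_r)
    lo_f = 0.05
    lo_r = achieved(lo_f)
    if target_ratio < lo_r:
        return AnisotropyFit(fraction=lo_f, target_ratio=target_ratio,
                             achieved_ratio=lo_r, linearized=linearize,
                             trace=trace, at_boundary=True)
    f, r = lo_f, lo_r
    while hi_f - lo_f > 0.01:
        f = 0.5 * (lo_f + hi_f)
        r = achieved(f)
        if abs(r - target_ratio) / target_ratio <= fit_tol:
            break
        if r < target_ratio:
            lo_f = f
        else:
            hi_f = f
    else:
        warnings.warn("anisotropy fit: bracket exhausted before tolerance")
    return AnisotropyFit(fraction=f, target_ratio=target_ratio,
                         achieved_ratio=r, linearized=linearize, trace=trace)
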