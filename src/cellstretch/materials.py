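"""Strain measures and hyperelastic constitutive laws for cell-wall membranes.

The cell wall is modeled as a thin hyperelastic membrane discretized with
3-node triangles.  Two Saint Venant-Kirchhoff (SVK) variants are provided:

* isotropic SVK on the *Biot* (engineering) strain ``E_B = U - 1``, where ``U``
  is the right stretch tensor.  With Poisson ratio 0 this gives an exactly
  linear uniaxial nominal-stress/engineering-strain response of slope ``E``,
  which is why it is the default for isotropic walls;
* transversely isotropic SVK on the *Green-Lagrange* strain
  ``E_G = (FᵀF - 1)/2``, allowing different in-plane Young's moduli along the
  cell's long (longitudinal) and short (transverse) axes.

Membrane kinematics are plane stress: the per-triangle deformation gradient
``F`` is the 3x2 tangent map from the 2D reference chart into 3D space, and
with nu = 0 the through-thickness strain vanishes identically.

Energy densities are per unit *reference volume* (MPa); the element energy is
``W * area0 * thickness``.  Everything here is written over the 2x2 right
Cauchy-Green tensor ``C = FᵀF`` so frame indifference is exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialParams",
    "StrainState",
    "lame_from_elastic",
    "elastic_from_lame",
    "strain_from_F",
    "svk_energy_density",
    "transversely_isotropic_energy",
    "cauchy_stress",
    "ElementMaterial",
]


# --------------------------------------------------------------------------
# Lamé / engineering constant conversions
# --------------------------------------------------------------------------

def lame_from_elastic(E: float, nu: float) -> tuple[float, float]:
    """Lamé coefficients (λ, µ) from Young's modulus E and Poisson ratio ν.

    Inverts E = µ(3λ+2µ)/(λ+µ), ν = λ/(2(λ+µ)).
    """
    if E <= 0:
        raise ValueError(f"Young's modulus must be positive, got {E}")
    if not 0 <= nu < 0.5:
        raise ValueError(f"Poisson ratio must be in [0, 0.5), got {nu}")
    mu = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return lam, mu


def elastic_from_lame(lam: float, mu: float) -> tuple[float, float]:
    """Young's modulus and Poisson ratio from Lamé coefficients."""
    if mu <= 0 or lam < 0:
        raise ValueError("need mu > 0 and lam >= 0")
    E = mu * (3.0 * lam + 2.0 * mu) / (lam + mu)
    nu = lam / (2.0 * (lam + mu))
    return E, nu


# --------------------------------------------------------------------------
# Material parameters
# --------------------------------------------------------------------------

@dataclass
class MaterialParams:
    """Directional Young's moduli (MPa), Poisson ratio, and strain measure.

    For isotropic walls ``E_long == E_trans == E_normal`` and the measure is
    normally ``"biot"``.  For anisotropic walls the measure must be
    ``"green"`` and the in-plane shear modulus is the symmetric choice
    ``µ_eff = sqrt(E_long·E_trans)/2`` which reduces to the isotropic
    µ = E/2 (at ν = 0) when the moduli coincide.

    ``E_normal`` (stiffness normal to the wall) is carried as metadata only: a
    membrane element cannot strain through its thickness.
    """

    E_long: float = 100.0
    E_trans: float = 100.0
    E_normal: float | None = None
    poisson: float = 0.0
    strain_measure: str = "biot"

    def __post_init__(self) -> None:
        if self.E_normal is None:
            self.E_normal = self.E_trans
        if self.E_long <= 0 or self.E_trans <= 0 or self.E_normal <= 0:
            raise ValueError("all moduli must be positive")
        if not 0 <= self.poisson < 0.5:
            raise ValueError(f"Poisson ratio must be in [0, 0.5), got {self.poisson}")
        if self.strain_measure not in ("biot", "green"):
            raise ValueError(f"unknown strain measure {self.strain_measure!r}")
        if not self.is_isotropic and self.strain_measure != "green":
            raise ValueError("anisotropic walls require the Green-Lagrange measure")

    @property
    def is_isotropic(self) -> bool:
        return self.E_long == self.E_trans

    @property
    def lame(self) -> tuple[float, float]:
        """(λ, µ) for the isotropic case (uses E_long)."""
        if not self.is_isotropic:
            raise ValueError("Lamé coefficients are defined for isotropic walls")
        return lame_from_elastic(self.E_long, self.poisson)

    @property
    def shear_modulus(self) -> float:
        """In-plane shear modulus µ (isotropic) or µ_eff = sqrt(E_l·E_t)/2."""
        if self.is_isotropic:
            return self.lame[1]
        return 0.5 * float(np.sqrt(self.E_long * self.E_trans))

    @classmethod
    def isotropic(cls, E: float = 100.0, nu: float = 0.0,
                  strain_measure: str = "biot") -> "MaterialParams":
        return cls(E_long=E, E_trans=E, E_normal=E, poisson=nu,
                   strain_measure=strain_measure)

    @classmethod
    def transversely_isotropic(cls, E_long: float = 30.0, E_trans: float = 100.0,
                               E_normal: float | None = None) -> "MaterialParams":
        return cls(E_long=E_long, E_trans=E_trans,
                   E_normal=E_trans if E_normal is None else E_normal,
                   poisson=0.0, strain_measure="green")


# --------------------------------------------------------------------------
# Strain measures
# --------------------------------------------------------------------------

def _sqrtm_spd2(C: np.ndarray) -> np.ndarray:
    """Closed-form square root of a batch of SPD 2x2 matrices.

    U = (C + sqrt(det C) I) / sqrt(tr C + 2 sqrt(det C)).
    """
    trC = C[..., 0, 0] + C[..., 1, 1]
    detC = C[..., 0, 0] * C[..., 1, 1] - C[..., 0, 1] * C[..., 1, 0]
    if np.any(detC <= 0):
        raise ValueError("non-positive det(C): inverted or degenerate element")
    d = np.sqrt(detC)
    s = np.sqrt(trC + 2.0 * d)
    U = C + d[..., None, None] * np.eye(2)
    return U / s[..., None, None]


@dataclass
class StrainState:
    """Per-element kinematic and stress quantities derived from F."""

    F: np.ndarray            # (..., 3, 2) or (..., 2, 2) tangent map
    U: np.ndarray            # (..., 2, 2) right stretch tensor
    R: np.ndarray            # (..., 3, 2)/(..., 2, 2) rotation factor, F = R U
    J: np.ndarray            # (...,) in-plane Jacobian det(U)
    E_biot: np.ndarray       # (..., 2, 2)
    E_green: np.ndarray      # (..., 2, 2)
    S: np.ndarray | None = None       # work-conjugate stress of active measure
    sigma: np.ndarray | None = None   # Cauchy stress (spatial)
    trace_sigma: np.ndarray | None = None


def strain_from_F(F: np.ndarray, measure: str = "biot") -> StrainState:
    """Kinematics from a (batch of) membrane deformation gradient(s).

    ``F`` maps the 2D reference chart to deformed space; shape (..., 3, 2) for
    a membrane in 3D or (..., 2, 2) for planar problems.  Requires
    det(FᵀF) > 0 (no inverted or collapsed elements).
    """
    F = np.asarray(F, dtype=float)
    if F.shape[-1] != 2 or F.shape[-2] not in (2, 3):
        raise ValueError(f"F must be (..., 3, 2) or (..., 2, 2), got {F.shape}")
    if measure not in ("biot", "green"):
        raise ValueError(f"unknown strain measure {measure!r}")
    C = np.swapaxes(F, -1, -2) @ F
    U = _sqrtm_spd2(C)
    Uinv = np.linalg.inv(U)
    R = F @ Uinv
    I2 = np.eye(2)
    E_biot = U - I2
    E_green = 0.5 * (C - I2)
    J = np.linalg.det(U)
    return StrainState(F=F, U=U, R=R, J=J, E_biot=E_biot, E_green=E_green)


# --------------------------------------------------------------------------
# Energy densities
# --------------------------------------------------------------------------

def svk_energy_density(E: np.ndarray, lam: float, mu: float) -> np.ndarray:
    """SVK energy density W = (λ/2)·Tr(E)² + µ·Tr(E²) for a symmetric strain E."""
    E = np.asarray(E, dtype=float)
    trE = np.trace(E, axis1=-2, axis2=-1)
    trE2 = np.trace(E @ E, axis1=-2, axis2=-1)
    return 0.5 * lam * trE**2 + mu * trE2


def transversely_isotropic_energy(E_green: np.ndarray, params: MaterialParams,
                                  frame: np.ndarray) -> np.ndarray:
    """Orthotropic quadratic energy in the Green-Lagrange strain.

    ``frame`` holds the two orthonormal in-plane material directions as rows
    (shape (..., 2, 2)): row 0 is the longitudinal axis, row 1 the transverse.
    With ν = 0 there is no normal coupling:

        W = ½·E_l·E_ll² + ½·E_t·E_tt² + 2·µ_eff·E_lt²

    and the small-strain uniaxial tangent along axis k is exactly E_k.
    Reduces to isotropic SVK (λ = 0) when E_long == E_trans.
    """
    if params.strain_measure != "green":
        raise ValueError("transversely isotropic law requires the Green measure")
    frame = np.asarray(frame, dtype=float)
    if frame.shape[-2:] != (2, 2):
        raise ValueError("material frame must be (..., 2, 2) row vectors")
    Em = frame @ np.asarray(E_green, dtype=float) @ np.swapaxes(frame, -1, -2)
    mus = params.shear_modulus
    return (0.5 * params.E_long * Em[..., 0, 0] ** 2
            + 0.5 * params.E_trans * Em[..., 1, 1] ** 2
            + 2.0 * mus * Em[..., 0, 1] ** 2)


def _conjugate_stress(state: StrainState, params: MaterialParams,
                      frame: np.ndarray | None) -> np.ndarray:
    """Stress conjugate to the active strain measure (2x2, material)."""
    if params.is_isotropic:
        lam, mu = params.lame
        E = state.E_biot if params.strain_measure == "biot" else state.E_green
        trE = np.trace(E, axis1=-2, axis2=-1)
        return lam * trE[..., None, None] * np.eye(2) + 2.0 * mu * E
    if frame is None:
        raise ValueError("anisotropic stress recovery needs the material frame")
    frame = np.asarray(frame, dtype=float)
    Em = frame @ state.E_green @ np.swapaxes(frame, -1, -2)
    mus = params.shear_modulus
    Sm = np.zeros_like(Em)
    Sm[..., 0, 0] = params.E_long * Em[..., 0, 0]
    Sm[..., 1, 1] = params.E_trans * Em[..., 1, 1]
    Sm[..., 0, 1] = Sm[..., 1, 0] = 2.0 * mus * Em[..., 0, 1]
    return np.swapaxes(frame, -1, -2) @ Sm @ frame


def cauchy_stress(state: StrainState, params: MaterialParams,
                  frame: np.ndarray | None = None) -> StrainState:
    """Recover the Cauchy stress σ and its trace from a StrainState.

    For the Green measure S is the second Piola-Kirchhoff stress and
    σ = (1/J)·F·S·Fᵀ.  For the Biot measure the conjugate stress T gives the
    nominal stress P = R·T, hence σ = (1/J)·R·(T·U)·Rᵀ (T and U commute for
    isotropic SVK so σ is symmetric).  Traces are reported in MPa.
    """
    S = _conjugate_stress(state, params, frame)
    Jinv = 1.0 / state.J[..., None, None]
    if params.strain_measure == "green":
        sigma = Jinv * (state.F @ S @ np.swapaxes(state.F, -1, -2))
    else:
        sigma = Jinv * (state.R @ (S @ state.U) @ np.swapaxes(state.R, -1, -2))
    state.S = S
    state.sigma = sigma
    state.trace_sigma = np.trace(sigma, axis1=-2, axis2=-1)
    return state


# --------------------------------------------------------------------------
# Vectorized energy + gradient for the FEM hot path
# --------------------------------------------------------------------------

class ElementMaterial:
    """Per-triangle material evaluator: batched energy density and ∂W/∂F.

    Built once per mesh.  ``lam``/``mu`` (isotropic) or ``E_l``/``E_t``/
    ``mu_s``/``frames`` (anisotropic) are broadcastable per-triangle arrays,
    which lets wall types carry different moduli.
    """

    def __init__(self, params: MaterialParams, n_tri: int,
                 frames: np.ndarray | None = None,
                 E_long_tri: np.ndarray | None = None,
                 E_trans_tri: np.ndarray | None = None):
        self.params = params
        self.measure = params.strain_measure
        self.n_tri = n_tri
        if params.is_isotropic and E_long_tri is None:
            lam, mu = params.lame
            self.lam = np.full(n_tri, lam)
            self.mu = np.full(n_tri, mu)
            self.anisotropic = False
        else:
            if frames is None:
                raise ValueError("anisotropic material requires per-triangle frames")
            self.anisotropic = True
            self.frames = np.broadcast_to(frames, (n_tri, 2, 2)).copy()
            El = params.E_long if E_long_tri is None else E_long_tri
            Et = params.E_trans if E_trans_tri is None else E_trans_tri
            self.E_l = np.broadcast_to(np.asarray(El, float), (n_tri,)).copy()
            self.E_t = np.broadcast_to(np.asarray(Et, float), (n_tri,)).copy()
            self.mu_s = 0.5 * np.sqrt(self.E_l * self.E_t)

    def energy_grad(self, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (W, dW/dF) per triangle; W in MPa, dW/dF shape (m, 3, 2)."""
        C = np.swapaxes(F, -1, -2) @ F
        if self.anisotropic:
            return self._green_ortho(F, C)
        if self.measure == "biot":
            return self._biot_iso(F, C)
        return self._green_iso(F, C)

    # -- isotropic SVK on Biot strain, via invariants of C -----------------
    # tr U = s = sqrt(I1 + 2 sqrt(I2)), tr(E_B) = s - 2,
    # tr(E_B²) = I1 - 2 s + 2, so W is a function of (I1, I2) only.
    def _biot_iso(self, F, C):
        I1 = C[:, 0, 0] + C[:, 1, 1]
        I2 = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] * C[:, 1, 0]
        if np.any(I2 <= 0):
            bad = int(np.argmax(I2 <= 0))
            raise FloatingPointError(f"inverted/degenerate element {bad}")
        d = np.sqrt(I2)
        s = np.sqrt(I1 + 2.0 * d)
        lam, mu = self.lam, self.mu
        W = 0.5 * lam * (s - 2.0) ** 2 + mu * (I1 - 2.0 * s + 2.0)
        dWds = lam * (s - 2.0) - 2.0 * mu
        dWdI1 = dWds / (2.0 * s) + mu
        dWdI2 = dWds / (2.0 * s * d)
        adjC = np.empty_like(C)
        adjC[:, 0, 0] = C[:, 1, 1]
        adjC[:, 1, 1] = C[:, 0, 0]
        adjC[:, 0, 1] = -C[:, 0, 1]
        adjC[:, 1, 0] = -C[:, 1, 0]
        dWdF = (2.0 * dWdI1[:, None, None] * F
                + 2.0 * dWdI2[:, None, None] * (F @ adjC))
        return W, dWdF

    def _green_iso(self, F, C):
        E = 0.5 * (C - np.eye(2))
        trE = E[:, 0, 0] + E[:, 1, 1]
        trE2 = np.einsum("mij,mji->m", E, E)
        lam, mu = self.lam, self.mu
        W = 0.5 * lam * trE**2 + mu * trE2
        S = lam * trE[:, None, None] * np.eye(2) + 2.0 * mu[:, None, None] * E
        return W, F @ S

    def _green_ortho(self, F, C):
        E = 0.5 * (C - np.eye(2))
        Q = self.frames
        Em = Q @ E @ np.swapaxes(Q, -1, -2)
        Ell, Ett, Elt = Em[:, 0, 0], Em[:, 1, 1], Em[:, 0, 1]
        W = (0.5 * self.E_l * Ell**2 + 0.5 * self.E_t * Ett**2
             + 2.0 * self.mu_s * Elt**2)
        Sm = np.zeros_like(Em)
        Sm[:, 0, 0] = self.E_l * Ell
        Sm[:, 1, 1] = self.E_t * Ett
        Sm[:, 0, 1] = Sm[:, 1, 0] = 2.0 * self.mu_s * Elt
        S = np.swapaxes(Q, -1, -2) @ Sm @ Q
        return W, F @ S

    def cauchy_trace(self, F: np.ndarray) -> np.ndarray:
        """Tr(σ) per element (MPa): (∂W/∂F : F) / J for either measure."""
        _, dWdF = self.energy_grad(F)
        C = np.swapaxes(F, -1, -2) @ F
        J = np.sqrt(np.linalg.det(C))
        return np.einsum("mij,mij->m", dWdF, F) / J
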