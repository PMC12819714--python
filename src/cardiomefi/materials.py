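"""Hyperelastic material laws at the material-point level.

Myocardium: compressible neo-Hookean matrix plus the
Holzapfel-Gasser-Ogden (HGO) exponential fiber term with dispersion
kappa,

    W = mu/2 (I1 - 3) - mu ln J + lambda/2 (ln J)^2
        + k1/(2 k2) sum_alpha [ exp(k2 E_alpha^2) - 1 ],
    E_alpha = kappa (I1_bar - 3) + (1 - 3 kappa)(I4_bar,alpha - 1),

where the matrix term is the standard compressible neo-Hookean law (full
first invariant; this is the unique member of the family that leaves the
reference configuration stress free), the fiber strain measure uses the
isochoric invariants I1_bar = J^(-2/3) tr C and I4_bar = J^(-2/3) a.C.a,
and fiber recruitment is tension-only (a family contributes only where
its effective strain E_alpha is positive; at kappa = 0 this is the
classic I4_bar >= 1 criterion).

Aortic leaflets: exponential isotropic matrix
W = C10 [exp(C01 (I1_bar - 3)) - 1] plus the same HGO fiber term with two
in-plane families (radial and circumferential), and a configurable
volumetric penalty (the in-plane law itself carries no volumetric term).

Second Piola-Kirchhoff stress S = dW/dE is evaluated analytically; all
stresses in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class MaterialError(ValueError):
    pass


@dataclass(frozen=True)
class MyocardiumMaterial:
    mu: float = 500.0            # kPa (0.5 MPa)
    lam: float = 200.0           # kPa (0.2 MPa)
    k1: float = 1.685            # kPa
    k2: float = 15.779
    kappa: float = 0.0           # fiber dispersion, 0 <= kappa <= 1/3
    printed_isochoric: bool = False   # audit flag: 1/2 mu (I1-1) + mu ln J

    def validate(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise MaterialError("k1, k2 must be positive")
        if not 0.0 <= self.kappa <= 1.0 / 3.0 + 1e-12:
            raise MaterialError("dispersion kappa must be in [0, 1/3]")


@dataclass(frozen=True)
class LeafletMaterial:
    C10: float = 3.47            # kPa (stress-like; see swap_c_params)
    C01: float = 30.03           # exponent parameter
    k1: float = 74.5             # kPa
    k2: float = 63.19
    kappa: float = 0.2
    kappa_vol: float = 1e4       # kPa, near-incompressibility penalty
    swap_c_params: bool = False  # audit flag: use C01 as the stress scale

    def validate(self) -> None:
        if min(self.C10, self.C01, self.k1, self.k2) <= 0:
            raise MaterialError("leaflet parameters must be positive")

    @property
    def c_stress(self) -> float:
        return self.C01 if self.swap_c_params else self.C10

    @property
    def c_exponent(self) -> float:
        return self.C10 if self.swap_c_params else self.C01


def _invariants(F: np.ndarray):
    F = np.asarray(F, float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise MaterialError("deformation gradient with det F <= 0")
    C = np.einsum("...ki,...kj->...ij", F, F)
    I1 = np.einsum("...ii->...", C)
    return C, J, I1


def _fiber_terms(C, J, I1, fibers, k1, k2, kappa):
    """Energy and dE_alpha/dC pieces of the HGO sum, tension-only."""
    Jm23 = J ** (-2.0 / 3.0)
    I1b = Jm23 * I1
    W = np.zeros(np.shape(J))
    contribs = []
    for a in fibers:
        a = np.asarray(a, float)
        I4 = np.einsum("...i,...ij,...j->...", a, C, a)
        I4b = Jm23 * I4
        # tension-only recruitment: the family contributes only where its
        # effective strain measure is positive (reduces to I4_bar >= 1 at
        # kappa = 0 and is direction-free at full dispersion kappa = 1/3)
        E = kappa * (I1b - 3.0) + (1.0 - 3.0 * kappa) * (I4b - 1.0)
        active = E >= 0.0
        E = np.where(active, E, 0.0)
        # clamp the exponent: beyond ~e300 the Newton line search rejects
        # the state anyway, and the clamp avoids overflow warnings
        W = W + k1 / (2.0 * k2) * (np.exp(np.minimum(k2 * E ** 2, 700.0)) - 1.0)
        contribs.append((a, I4, E, active))
    return W, contribs, I1b


def strain_energy_myocardium(F, material: MyocardiumMaterial,
                             fiber_dirs) -> np.ndarray:
    """Strain-energy density (kPa); ``fiber_dirs`` is a list of one or two
    unit reference fiber directions (or (...,3) arrays)."""
    material.validate()
    C, J, I1 = _invariants(F)
    lnJ = np.log(J)
    I1b = J ** (-2.0 / 3.0) * I1
    if material.printed_isochoric:
        Wiso = 0.5 * material.mu * (I1b - 1.0) + material.mu * lnJ \
            + 0.5 * material.lam * lnJ ** 2
    else:
        Wiso = 0.5 * material.mu * (I1 - 3.0) - material.mu * lnJ \
            + 0.5 * material.lam * lnJ ** 2
    Wfib, _, _ = _fiber_terms(C, J, I1, fiber_dirs,
                              material.k1, material.k2, material.kappa)
    return Wiso + Wfib


def strain_energy_leaflet(F, material: LeafletMaterial,
                          fiber_dirs) -> np.ndarray:
    """Leaflet energy density (kPa) with two in-plane fiber families and a
    volumetric penalty 0.5 kappa_vol (J - 1)^2."""
    material.validate()
    C, J, I1 = _invariants(F)
    I1b = J ** (-2.0 / 3.0) * I1
    Wm = material.c_stress * (np.exp(material.c_exponent * (I1b - 3.0)) - 1.0)
    Wfib, _, _ = _fiber_terms(C, J, I1, fiber_dirs,
                              material.k1, material.k2, material.kappa)
    return Wm + Wfib + 0.5 * material.kappa_vol * (J - 1.0) ** 2


# ---------------------------------------------------------------------------
# analytic second Piola-Kirchhoff stress

def _inv3x3(A: np.ndarray) -> np.ndarray:
    """Vectorized adjugate inverse of symmetric-enough 3x3 stacks."""
    a = np.asarray(A, float)
    c = np.empty_like(a)
    c[..., 0, 0] = a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1]
    c[..., 0, 1] = a[..., 0, 2] * a[..., 2, 1] - a[..., 0, 1] * a[..., 2, 2]
    c[..., 0, 2] = a[..., 0, 1] * a[..., 1, 2] - a[..., 0, 2] * a[..., 1, 1]
    c[..., 1, 0] = a[..., 1, 2] * a[..., 2, 0] - a[..., 1, 0] * a[..., 2, 2]
    c[..., 1, 1] = a[..., 0, 0] * a[..., 2, 2] - a[..., 0, 2] * a[..., 2, 0]
    c[..., 1, 2] = a[..., 0, 2] * a[..., 1, 0] - a[..., 0, 0] * a[..., 1, 2]
    c[..., 2, 0] = a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0]
    c[..., 2, 1] = a[..., 0, 1] * a[..., 2, 0] - a[..., 0, 0] * a[..., 2, 1]
    c[..., 2, 2] = a[..., 0, 0] * a[..., 1, 1] - a[..., 0, 1] * a[..., 1, 0]
    det = (a[..., 0, 0] * c[..., 0, 0] + a[..., 0, 1] * c[..., 1, 0]
           + a[..., 0, 2] * c[..., 2, 0])
    return c / det[..., None, None]


def _dev_terms(C, J, I1, Cinv=None):
    """d(I1_bar)/dE and d(lnJ)/dE building blocks.

    dI1b/dE = 2 J^{-2/3} (I - I1/3 C^{-1});  d(lnJ)/dE = C^{-1}.
    """
    if Cinv is None:
        Cinv = _inv3x3(C)
    eye = np.broadcast_to(np.eye(3), C.shape)
    Jm23 = J ** (-2.0 / 3.0)
    dI1b = 2.0 * Jm23[..., None, None] * (eye - (I1 / 3.0)[..., None, None] * Cinv)
    return Cinv, dI1b, Jm23


def _fiber_stress(C, J, I1, fibers, k1, k2, kappa, dev=None):
    Cinv, dI1b, Jm23 = dev if dev is not None else _dev_terms(C, J, I1)
    S = np.zeros(C.shape)
    for a in fibers:
        a = np.asarray(a, float)
        I4 = np.einsum("...i,...ij,...j->...", a, C, a)
        I4b = Jm23 * I4
        E = kappa * (I1b_of(Jm23, I1) - 3.0) + (1.0 - 3.0 * kappa) * (I4b - 1.0)
        active = E >= 0.0
        aa = np.einsum("...i,...j->...ij", a, a)
        dI4b = 2.0 * Jm23[..., None, None] * (aa - (I4 / 3.0)[..., None, None] * Cinv)
        dE = kappa * dI1b + (1.0 - 3.0 * kappa) * dI4b
        coef = k1 * E * np.exp(np.minimum(k2 * E ** 2, 700.0))
        coef = np.where(active, coef, 0.0)
        S = S + coef[..., None, None] * dE
    return S


def I1b_of(Jm23, I1):
    return Jm23 * I1


def pk2_stress_myocardium(F, material: MyocardiumMaterial, fiber_dirs,
                          active_tensor=None) -> np.ndarray:
    """S = dW/dE (kPa), optionally plus the active stress tensor."""
    material.validate()
    C, J, I1 = _invariants(F)
    Cinv, dI1b, Jm23 = _dev_terms(C, J, I1)
    lnJ = np.log(J)
    eye = np.broadcast_to(np.eye(3), C.shape)
    if material.printed_isochoric:
        S = 0.5 * material.mu * dI1b \
            + (material.mu + material.lam * lnJ)[..., None, None] * Cinv
    else:
        S = material.mu * (eye - Cinv) \
            + (material.lam * lnJ)[..., None, None] * Cinv
    S = S + _fiber_stress(C, J, I1, fiber_dirs,
                          material.k1, material.k2, material.kappa,
                          dev=(Cinv, dI1b, Jm23))
    if active_tensor is not None:
        S = S + active_tensor
    return S


def pk2_stress_leaflet(F, material: LeafletMaterial, fiber_dirs) -> np.ndarray:
    material.validate()
    C, J, I1 = _invariants(F)
    Cinv, dI1b, Jm23 = _dev_terms(C, J, I1)
    I1b = Jm23 * I1
    cexp = material.c_exponent
    Sm = material.c_stress * cexp * np.exp(cexp * (I1b - 3.0))
    S = Sm[..., None, None] * dI1b
    S = S + _fiber_stress(C, J, I1, fiber_dirs,
                          material.k1, material.k2, material.kappa,
                          dev=(Cinv, dI1b, Jm23))
    S = S + (material.kappa_vol * (J - 1.0) * J)[..., None, None] * Cinv
    return S


def cauchy_from_pk2(F, S) -> np.ndarray:
    """Push-forward sigma = J^-1 F S F^T."""
    F = np.asarray(F, float)
    J = np.linalg.det(F)
    return np.einsum("...ik,...kl,...jl->...ij", F, S, F) / J[..., None, None]


def von_mises(sigma) -> np.ndarray:
    s = np.asarray(sigma, float)
    tr = np.einsum("...ii->...", s) / 3.0
    dev = s - tr[..., None, None] * np.broadcast_to(np.eye(3), s.shape)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))
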