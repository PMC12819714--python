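"""Active contractile stress driven by the mapped transmembrane potential.

A scalar active stress sigma_a relaxes toward its potential-dependent
target k (Phi - Phi_r) at a rate epsilon(Phi) that switches smoothly
(Gompertz sigmoid) between a slow resting rate and a fast depolarized
rate — contraction therefore lags the electrical upstroke and decays
slowly after repolarization.  The scalar is distributed anisotropically
over the fiber (eta1), sheet (eta2) and sheet-normal (eta3) directions as
a symmetric second Piola-Kirchhoff contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ActiveStressParams:
    k: float = 15.0           # saturated active stress gain, kPa/mV
                              # (EF-calibrated on the coarse coupled model;
                              # see calibrate_k_for_ef)
    Phi_r: float = -80.0      # resting potential, mV
    eps0: float = 0.005       # slow rate, 1/ms (resting limit)
    eps1: float = 0.05        # fast rate, 1/ms (depolarized limit)
    zeta: float = 0.2         # transition rate, 1/mV
    Phi_t: float = -55.0      # phase-shift potential, mV
    eta1: float = 0.1         # fiber weight
    eta2: float = 0.2         # sheet weight
    eta3: float = 0.6         # sheet-normal weight
    printed_amplitude: bool = False   # audit flag: (eps0 + eps1) amplitude

    def validate(self) -> None:
        problems = []
        if self.eps0 <= 0 or self.eps1 <= 0:
            problems.append("rate constants eps0, eps1 must be positive")
        if min(self.eta1, self.eta2, self.eta3) < 0:
            problems.append("distribution weights eta_i must be >= 0")
        if problems:
            raise ValueError("; ".join(problems))


def delay_function(Phi, params: ActiveStressParams) -> np.ndarray:
    """Rate epsilon(Phi) = eps0 + (eps1 - eps0) exp(-exp(-zeta (Phi - Phi_t))).

    Monotone non-decreasing with limits eps0 (Phi -> -inf) and eps1
    (Phi -> +inf).  The audit flag ``printed_amplitude`` switches the
    sigmoid amplitude to (eps0 + eps1).
    """
    amp = (params.eps0 + params.eps1) if params.printed_amplitude \
        else (params.eps1 - params.eps0)
    z = -params.zeta * (np.asarray(Phi, float) - params.Phi_t)
    return params.eps0 + amp * np.exp(-np.exp(z))


def step_active_stress(sigma_a, Phi, dt: float,
                       params: ActiveStressParams) -> np.ndarray:
    """Implicit (unconditionally stable) update of
    d sigma_a / dt = eps(Phi) [ k (Phi - Phi_r) - sigma_a ].

    Exact for constant Phi over the step (exponential integrator).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    eps = delay_function(Phi, params)
    target = params.k * (np.asarray(Phi, float) - params.Phi_r)
    decay = np.exp(-eps * dt)
    return target + (np.asarray(sigma_a, float) - target) * decay


def active_stress_tensor(sigma_a, fiber, sheet, sheet_normal,
                         params: ActiveStressParams,
                         isotropic_mask=None,
                         tol: float = 1e-8) -> np.ndarray:
    """Symmetric active stress tensor
    sigma = sigma_a (eta1 a(x)a + eta2 s(x)s + eta3 n(x)n), kPa.

    ``fiber``/``sheet``/``sheet_normal`` are (..., 3) unit vectors forming
    an orthonormal triad (rejected otherwise).  Elements flagged in
    ``isotropic_mask`` (the apex cylinder, whose microstructure carries no
    preferred direction) receive the trace-preserving isotropic tensor
    sigma_a (eta1+eta2+eta3)/3 I instead.
    """
    a = np.asarray(fiber, float)
    s = np.asarray(sheet, float)
    n = np.asarray(sheet_normal, float)
    for v in (a, s, n):
        if np.any(np.abs(np.linalg.norm(v, axis=-1) - 1.0) > tol):
            raise ValueError("triad vectors must be unit length")
    if np.any(np.abs(np.einsum("...i,...i->...", a, s)) > tol) \
            or np.any(np.abs(np.einsum("...i,...i->...", a, n)) > tol) \
            or np.any(np.abs(np.einsum("...i,...i->...", s, n)) > tol):
        raise ValueError("triad vectors must be mutually orthogonal")
    sig = np.asarray(sigma_a, float)[..., None, None]
    out = sig * (params.eta1 * np.einsum("...i,...j->...ij", a, a)
                 + params.eta2 * np.einsum("...i,...j->...ij", s, s)
                 + params.eta3 * np.einsum("...i,...j->...ij", n, n))
    if isotropic_mask is not None and np.any(isotropic_mask):
        eta_mean = (params.eta1 + params.eta2 + params.eta3) / 3.0
        iso = sig * eta_mean * np.broadcast_to(np.eye(3), out.shape)
        out = np.where(np.asarray(isotropic_mask)[..., None, None], iso, out)
    return out
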