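"""Linear (P1) tetrahedral finite-element primitives.

Shared by the harmonic fiber-coordinate solver, the monodomain stepper and
the solid mechanics assembly: shape-function gradients, anisotropic
stiffness, lumped mass, and Dirichlet elimination.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def tet_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Constant shape-function gradients per element.

    Returns (grads, volumes): grads[e, a, :] = dN_a/dx on element e,
    volumes in mm^3.
    """
    x = nodes[tets]
    d = x[:, 1:] - x[:, :1]                       # (E, 3, 3) edge matrix
    vol6 = np.linalg.det(d)
    dinv = np.linalg.inv(d)                       # rows: gradients of N1..N3
    g123 = np.transpose(dinv, (0, 2, 1))
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)
    return grads, vol6 / 6.0


def stiffness_matrix(nodes: np.ndarray, tets: np.ndarray,
                     tensor) -> sp.csr_matrix:
    """Assemble K_ab = sum_e V_e grad(N_a) . D_e . grad(N_b).

    ``tensor`` is a scalar, a (3,3) matrix, or per-element (E,3,3) tensors.
    """
    grads, vol = tet_gradients(nodes, tets)
    tensor = np.asarray(tensor, float)
    if tensor.ndim == 0:
        dg = tensor * grads
    elif tensor.ndim == 2:
        dg = np.einsum("ij,eaj->eai", tensor, grads)
    else:
        dg = np.einsum("eij,eaj->eai", tensor, grads)
    ke = np.einsum("eai,ebi->eab", grads, dg) * vol[:, None, None]
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    n = len(nodes)
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def lumped_mass(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Row-sum (lumped) mass vector: a quarter of each tet volume per node."""
    _, vol = tet_gradients(nodes, tets)
    m = np.zeros(len(nodes))
    np.add.at(m, tets.ravel(), np.repeat(vol / 4.0, 4))
    return m


def dirichlet_reduce(K: sp.csr_matrix, f: np.ndarray,
                     fixed: np.ndarray, values: np.ndarray):
    """Eliminate Dirichlet dofs; returns (K_ff, f_f, free index array)."""
    n = K.shape[0]
    free = np.setdiff1d(np.arange(n), fixed)
    u = np.zeros(n)
    u[fixed] = values
    f_mod = f - K @ u
    return K[free][:, free], f_mod[free], free


def element_means(field_nodal: np.ndarray, tets: np.ndarray) -> np.ndarray:
    return field_nodal[tets].mean(axis=1)
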