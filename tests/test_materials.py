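"""Constitutive laws: stress-free reference, symbolic-algebra energy
oracles, analytic-vs-finite-difference stress, objectivity and material
symmetry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiomefi.materials import (LeafletMaterial, MaterialError,
                                  MyocardiumMaterial, cauchy_from_pk2,
                                  pk2_stress_leaflet, pk2_stress_myocardium,
                                  strain_energy_leaflet,
                                  strain_energy_myocardium, von_mises)

A0 = np.array([1.0, 0.0, 0.0])
A1 = np.array([0.0, 1.0, 0.0])
MYO = MyocardiumMaterial()
LEAF = LeafletMaterial()


def _random_F(rng, scale=0.1):
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if 0.8 <= np.linalg.det(F) <= 1.2:
            return F


def _fd_pk2(W_of_F, F, h=1e-6):
    """Central finite differences of W with respect to the Green-Lagrange
    strain (independent oracle for S = dW/dE)."""
    C = F.T @ F
    S = np.zeros((3, 3))

    def W_of_C(Cm):
        w, V = np.linalg.eigh(Cm)
        return W_of_F(V @ np.diag(np.sqrt(w)) @ V.T)

    for i in range(3):
        for j in range(3):
            dC = np.zeros((3, 3))
            dC[i, j] += h
            dC[j, i] += h          # dE_ij = dC_ij / 2, symmetrized
            S[i, j] = (W_of_C(C + dC) - W_of_C(C - dC)) / (2 * h)
    return S


# ---------------------------------------------------------------------------
# reference state and basic structure

def test_energy_and_stress_vanish_at_reference():
    I = np.eye(3)
    assert strain_energy_myocardium(I, MYO, [A0]) == 0.0
    assert strain_energy_leaflet(I, LEAF, [A0, A1]) == 0.0
    assert np.abs(pk2_stress_myocardium(I, MYO, [A0])).max() == 0.0
    assert np.abs(pk2_stress_leaflet(I, LEAF, [A0, A1])).max() == 0.0


def test_full_dispersion_isotropizes_fiber_term():
    """kappa = 1/3 removes the I4 dependence: rotating the fiber direction
    leaves the energy unchanged."""
    mat = MyocardiumMaterial(kappa=1.0 / 3.0)
    rng = np.random.default_rng(0)
    F = _random_F(rng)
    w_ref = strain_energy_myocardium(F, mat, [A0])
    for v in ([0.0, 1.0, 0.0], [0.5, 0.5, np.sqrt(0.5)]):
        w = strain_energy_myocardium(F, mat, [np.asarray(v)])
        assert w == pytest.approx(w_ref, rel=1e-12)


def test_uniaxial_fiber_stretch_matches_symbolic_oracle():
    sympy = pytest.importorskip("sympy")
    lam = 1.1
    F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])  # isochoric
    mat = MyocardiumMaterial(kappa=0.0)
    w = strain_energy_myocardium(F, mat, [A0])

    ls = sympy.Symbol("lam", positive=True)
    J = sympy.Integer(1)
    I1 = ls ** 2 + 2 / ls
    I4 = ls ** 2
    E = (I4 - 1)                      # kappa = 0
    mu, lamp, k1, k2 = (sympy.Float(mat.mu), sympy.Float(mat.lam),
                        sympy.Float(mat.k1), sympy.Float(mat.k2))
    W = (mu / 2 * (I1 - 3) - mu * sympy.log(J)
         + lamp / 2 * sympy.log(J) ** 2
         + k1 / (2 * k2) * (sympy.exp(k2 * E ** 2) - 1))
    w_ref = float(W.subs(ls, lam))
    assert w == pytest.approx(w_ref, rel=1e-10)


def test_leaflet_energy_matches_symbolic_oracle():
    sympy = pytest.importorskip("sympy")
    lam = 1.08
    F = np.diag([lam, lam, 1 / lam ** 2])     # isochoric equibiaxial
    w = strain_energy_leaflet(F, LEAF, [A0, A1])

    ls = sympy.Symbol("lam", positive=True)
    I1 = 2 * ls ** 2 + ls ** -4
    I4 = ls ** 2                              # both in-plane families
    kap = sympy.Float(LEAF.kappa)
    E = kap * (I1 - 3) + (1 - 3 * kap) * (I4 - 1)
    C10, C01 = sympy.Float(LEAF.C10), sympy.Float(LEAF.C01)
    k1, k2 = sympy.Float(LEAF.k1), sympy.Float(LEAF.k2)
    W = C10 * (sympy.exp(C01 * (I1 - 3)) - 1) \
        + 2 * k1 / (2 * k2) * (sympy.exp(k2 * E ** 2) - 1)
    w_ref = float(W.subs(ls, lam))
    assert w == pytest.approx(w_ref, rel=1e-10)


def test_equibiaxial_sweep_is_strictly_increasing():
    lams = np.linspace(1.0, 1.2, 21)
    ws = [float(strain_energy_leaflet(
        np.diag([l, l, 1.0]), LEAF, [A0, A1])) for l in lams]
    assert np.all(np.diff(ws) > 0)


# ---------------------------------------------------------------------------
# analytic stress vs finite differences

@pytest.mark.parametrize("seed", range(5))
def test_myocardium_stress_matches_fd(seed):
    rng = np.random.default_rng(seed)
    F = _random_F(rng)
    S = pk2_stress_myocardium(F, MYO, [A0])
    S_fd = _fd_pk2(lambda FF: float(strain_energy_myocardium(FF, MYO, [A0])),
                   F)
    assert np.abs(S - S_fd).max() < 1e-6 * max(np.abs(S).max(), 1.0)


@pytest.mark.parametrize("seed", range(5))
def test_leaflet_stress_matches_fd(seed):
    rng = np.random.default_rng(100 + seed)
    F = _random_F(rng, scale=0.05)
    S = pk2_stress_leaflet(F, LEAF, [A0, A1])
    S_fd = _fd_pk2(lambda FF: float(strain_energy_leaflet(FF, LEAF,
                                                          [A0, A1])), F)
    assert np.abs(S - S_fd).max() < 1e-6 * max(np.abs(S).max(), 1.0)


def test_stress_with_dispersion_matches_fd():
    mat = MyocardiumMaterial(kappa=0.25)
    rng = np.random.default_rng(42)
    F = _random_F(rng)
    S = pk2_stress_myocardium(F, mat, [A0])
    S_fd = _fd_pk2(lambda FF: float(strain_energy_myocardium(FF, mat, [A0])),
                   F)
    assert np.abs(S - S_fd).max() < 1e-6 * max(np.abs(S).max(), 1.0)


# ---------------------------------------------------------------------------
# invariance properties

@settings(deadline=None, max_examples=100)
@given(st.integers(0, 10_000))
def test_objectivity_under_random_rotations(seed):
    """W(QF) = W(F) for random rotations Q; pure rotations carry no
    stress (frame indifference)."""
    rng = np.random.default_rng(seed)
    F = _random_F(rng)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    w1 = strain_energy_myocardium(F, MYO, [A0])
    w2 = strain_energy_myocardium(q @ F, MYO, [A0])
    assert w2 == pytest.approx(w1, rel=1e-10, abs=1e-10)
    assert np.abs(pk2_stress_myocardium(q, MYO, [A0])).max() < 1e-9


def test_fiber_flip_symmetry():
    rng = np.random.default_rng(5)
    for _ in range(20):
        F = _random_F(rng)
        w1 = strain_energy_myocardium(F, MYO, [A0])
        w2 = strain_energy_myocardium(F, MYO, [-A0])
        assert w1 == w2


def test_energy_grows_along_radial_loading_paths():
    rng = np.random.default_rng(9)
    for _ in range(10):
        H = 0.2 * rng.standard_normal((3, 3))
        ts = np.linspace(0.0, 1.0, 15)
        ws = []
        for t in ts:
            F = np.eye(3) + t * H
            if np.linalg.det(F) <= 0.05:
                break
            ws.append(float(strain_energy_myocardium(F, MYO, [A0])))
        assert np.all(np.diff(ws) > -1e-12)


def test_tension_only_fiber_recruitment():
    """Fiber compression leaves only the matrix response."""
    lam = 0.9
    F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
    mat_no_fiber = MyocardiumMaterial(k1=1e-30)
    w = strain_energy_myocardium(F, MYO, [A0])
    w_matrix = strain_energy_myocardium(F, mat_no_fiber, [A0])
    assert w == pytest.approx(w_matrix, rel=1e-12)


def test_invalid_states_rejected():
    with pytest.raises(MaterialError):
        strain_energy_myocardium(np.diag([1.0, 1.0, -1.0]), MYO, [A0])
    with pytest.raises(MaterialError):
        MyocardiumMaterial(kappa=0.5).validate()


def test_cauchy_pushforward_and_von_mises():
    rng = np.random.default_rng(2)
    F = _random_F(rng)
    S = pk2_stress_myocardium(F, MYO, [A0])
    sig = cauchy_from_pk2(F, S)
    assert np.abs(sig - sig.T).max() < 1e-9
    # hydrostatic state has zero von Mises stress
    assert von_mises(5.0 * np.eye(3)) == pytest.approx(0.0, abs=1e-12)
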