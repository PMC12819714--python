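"""Solid mechanics: patch test, equilibrium balance, shell inflation
against the classical closed form, Newmark dynamics, and the kinematic
metrics."""

import numpy as np
import pytest
from scipy.optimize import brentq

from cardiomefi.materials import MyocardiumMaterial, pk2_stress_myocardium
from cardiomefi.mechanics import (MechanicsProblem, MechanicsState,
                                  max_principal_strain, torsion_angle)
from cardiomefi.shapes import (make_box_mesh, make_spherical_shell_patch,
                               shell_patch_cut_normals)

A0 = [np.array([1.0, 0.0, 0.0])]
SOFT = MyocardiumMaterial(mu=100.0, lam=100.0, k1=1e-10, k2=1.0)


def _box_problem(material=SOFT, divisions=(3, 3, 3), lengths=(10., 10., 10.),
                 fixed=("base",), pressure_tag=None):
    m = make_box_mesh(lengths, divisions, {"z0": "base"})
    return m, MechanicsProblem(m, material, A0, fixed_tags=fixed,
                               pressure_tag=pressure_tag)


def test_zero_load_stays_at_rest():
    _, prob = _box_problem()
    st = prob.solve_quasistatic()
    assert np.abs(st.u).max() == 0.0
    assert np.abs(st.sigma_vm).max() == 0.0


def test_patch_test_constant_strain_reproduced_exactly():
    """A homogeneous deformation imposed on the nodes is reproduced
    exactly at every quadrature point by linear tets, and the quadrature
    stress equals the material-point evaluation."""
    m, prob = _box_problem()
    F = np.eye(3) + np.array([[0.04, 0.02, 0.0],
                              [0.0, -0.03, 0.01],
                              [0.0, 0.0, 0.02]])
    u = m.nodes @ (F - np.eye(3)).T
    Fel = prob.deformation_gradients(u)
    assert np.abs(Fel - F).max() < 1e-13
    S_fem = pk2_stress_myocardium(Fel, SOFT, A0)
    S_pt = pk2_stress_myocardium(F, SOFT, A0)
    assert np.abs(S_fem - S_pt).max() < 1e-10


def test_single_tet_matches_material_point_oracle():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    tets = np.array([[0, 1, 2, 3]])
    from cardiomefi.mesh import VolumeMesh
    mesh = VolumeMesh(nodes=nodes, tets=tets)
    prob = MechanicsProblem(mesh, SOFT, A0, fixed_tags=(), pressure_tag=None)
    F = np.diag([1.1, 0.95, 1.02])
    u = nodes @ (F - np.eye(3)).T
    S = pk2_stress_myocardium(prob.deformation_gradients(u), SOFT, A0)[0]
    S_ref = pk2_stress_myocardium(F, SOFT, A0)
    assert np.abs(S - S_ref).max() < 1e-12


def test_internal_force_frame_indifferent():
    m, prob = _box_problem()
    rng = np.random.default_rng(1)
    u = 0.05 * rng.standard_normal(m.nodes.shape)
    f = prob.internal_force(u)
    th = 0.7
    Q = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    u_rot = (m.nodes + u) @ Q.T - m.nodes
    f_rot = prob.internal_force(u_rot)
    assert np.abs(f_rot - f @ Q.T).max() < 1e-8 * max(np.abs(f).max(), 1.0)


def test_global_equilibrium_under_pressure():
    """The reaction force at the fixed base balances the applied pressure
    load: sum of reactions = -(total external force)."""
    m = make_box_mesh((10., 10., 10.), (3, 3, 3),
                      {"z0": "base", "z1": "endocardium"})
    prob = MechanicsProblem(m, SOFT, A0, fixed_tags=("base",),
                            pressure_tag="endocardium")
    st = prob.solve_quasistatic(pressure_kpa=1.0, tol=1e-11)
    f_int = prob.internal_force(st.u)
    f_ext = prob.external_force(st.u, 1.0)
    fixed = m.surface_nodes("base")
    reaction = (f_int - f_ext)[fixed].sum(axis=0)
    total_load = f_ext.sum(axis=0)
    assert np.linalg.norm(reaction + total_load) < \
        1e-8 * np.linalg.norm(total_load)


def test_thick_shell_inflation_matches_closed_form():
    """Nearly incompressible neo-Hookean spherical shell under internal
    pressure: the inflated inner radius matches the classical
    incompressible inflation relation within 2%."""
    A, B, mu, p = 10.0, 11.5, 30.0, 2.0
    mat = MyocardiumMaterial(mu=mu, lam=3000.0, k1=1e-10, k2=1.0)
    sh = make_spherical_shell_patch(A, B, nr=3, nang=10)
    prob = MechanicsProblem(sh, mat, A0, fixed_tags=(),
                            roller_planes=shell_patch_cut_normals(),
                            pressure_tag="inner")
    st = prob.solve_quasistatic(pressure_kpa=p)
    inner = sh.surface_nodes("inner")
    a_fem = np.linalg.norm(sh.nodes[inner] + st.u[inner], axis=1).mean()

    def pressure_of_a(a):
        b = (B ** 3 + a ** 3 - A ** 3) ** (1 / 3)
        g = lambda lam: 1 / (2 * lam ** 4) + 2 / lam
        return mu * (g(b / B) - g(a / A))

    a_exact = brentq(lambda a: pressure_of_a(a) - p, A, 1.5 * A)
    assert a_fem - A == pytest.approx(a_exact - A, rel=0.02)


def test_solver_reports_divergence_on_excessive_load():
    from cardiomefi.mechanics import MechanicsError
    sh = make_spherical_shell_patch(10.0, 10.5, nr=1, nang=4)
    soft = MyocardiumMaterial(mu=1.0, lam=2.0, k1=1e-10, k2=1.0)
    prob = MechanicsProblem(sh, soft, A0, fixed_tags=(),
                            roller_planes=shell_patch_cut_normals(),
                            pressure_tag="inner")
    with pytest.raises(MechanicsError):
        prob.solve_quasistatic(pressure_kpa=500.0)


# ---------------------------------------------------------------------------
# Newmark dynamics

def test_newmark_stationary_without_loads():
    m, prob = _box_problem()
    st = MechanicsState(u=np.zeros_like(m.nodes))
    for _ in range(5):
        st = prob.step_newmark(st, dt=0.5)
    assert np.abs(st.u).max() < 1e-12


def test_newmark_bar_frequency_matches_analytic():
    """Fundamental longitudinal frequency of a fixed-free elastic bar:
    f1 = c / (4 L) with c = sqrt(E_eff / rho)."""
    L = 20.0
    mu, lam = 100.0, 100.0
    mat = MyocardiumMaterial(mu=mu, lam=lam, k1=1e-10, k2=1.0)
    m = make_box_mesh((2.0, 2.0, L), (1, 1, 24), {"z0": "base"})
    rho = 1.055e-3  # light loading keeps it linear; value arbitrary here
    prob = MechanicsProblem(m, mat, A0, fixed_tags=("base",),
                            pressure_tag=None, density=rho)
    # 1D bar modulus: constrained lateral contraction is free in a thin
    # bar, so the effective modulus is Young's E = mu(3 lam + 2 mu)/(lam+mu)
    E = mu * (3 * lam + 2 * mu) / (lam + mu)
    f_exact = np.sqrt(E / rho) / (4 * L)       # 1/ms

    z = m.nodes[:, 2]
    u0 = np.zeros_like(m.nodes)
    u0[:, 2] = 1e-4 * np.sin(np.pi * z / (2 * L))   # fundamental mode shape
    st = MechanicsState(u=u0)
    dt = 1.0 / (f_exact * 40.0)          # 40 steps per period
    tip = np.argmax(z)
    disp = []
    n = 400
    for _ in range(n):
        st = prob.step_newmark(st, dt=dt)
        disp.append(st.u[tip, 2])
    disp = np.array(disp)
    # frequency from FFT peak
    freqs = np.fft.rfftfreq(n, d=dt)
    amp = np.abs(np.fft.rfft(disp - disp.mean()))
    f_meas = freqs[np.argmax(amp[1:]) + 1]
    # refine by parabolic interpolation around the peak
    i = np.argmax(amp[1:]) + 1
    if 1 <= i < len(amp) - 1:
        d = 0.5 * (amp[i - 1] - amp[i + 1]) / \
            (amp[i - 1] - 2 * amp[i] + amp[i + 1])
        f_meas = freqs[i] + d * (freqs[1] - freqs[0])
    assert f_meas == pytest.approx(f_exact, rel=0.02)


def test_newmark_damped_energy_non_increasing():
    m, prob = _box_problem()
    rng = np.random.default_rng(0)
    u0 = np.zeros_like(m.nodes)
    free = m.nodes[:, 2] > 0
    u0[free] = 0.01 * rng.standard_normal(u0[free].shape)
    st = MechanicsState(u=u0)
    mvec = prob.mass.reshape(-1, 3)

    def energy(s):
        from cardiomefi.materials import strain_energy_myocardium
        W = strain_energy_myocardium(prob.deformation_gradients(s.u),
                                     SOFT, A0)
        _, vol = np.broadcast_arrays(W, prob.vol)
        ke = 0.0 if s.v is None else 0.5 * np.sum(mvec * s.v ** 2)
        return float(np.sum(W * prob.vol)) + ke

    energies = [energy(st)]
    for _ in range(20):
        st = prob.step_newmark(st, dt=0.5, damping=0.2)
        energies.append(energy(st))
    assert np.all(np.diff(energies) <= 1e-10)


# ---------------------------------------------------------------------------
# kinematic metrics

def test_rigid_rotation_gives_zero_torsion(case1_mesh):
    th = np.deg2rad(10.0)
    Q = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    u = case1_mesh.nodes @ Q.T - case1_mesh.nodes
    assert torsion_angle(case1_mesh, u) == pytest.approx(0.0, abs=1e-9)


def test_prescribed_linear_twist_recovered():
    from cardiomefi.shapes import make_annulus_mesh
    m = make_annulus_mesh(20.0, 27.0, 50.0, nr=2, ntheta=32, nz=10)
    z = m.nodes[:, 2]
    ang = np.deg2rad(15.0) * z / z.max()
    x, y = m.nodes[:, 0], m.nodes[:, 1]
    u = np.zeros_like(m.nodes)
    u[:, 0] = x * np.cos(ang) - y * np.sin(ang) - x
    u[:, 1] = x * np.sin(ang) + y * np.cos(ang) - y
    assert torsion_angle(m, u) == pytest.approx(15.0, abs=1e-6)


def test_max_principal_strain_uniaxial():
    F = np.diag([1.2, 1.0, 1.0])[None, :, :]
    # Green-Lagrange E_xx = (1.2^2 - 1)/2 = 0.22
    assert max_principal_strain(F) == pytest.approx(22.0, rel=1e-12)
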