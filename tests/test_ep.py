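"""Electrophysiology: reaction kinetics against independent oracles,
single-cell action potential, potential mapping, and the anisotropic
monodomain stepper (rest invariance, decoupled limit, conduction-speed
scaling, front resolution)."""

import numpy as np
import pytest

from cardiomefi.ep import (EPParams, EPState, MonodomainModel,
                           activation_time_field, calibrate_potential_mapping,
                           calibrated_params, ionic_current_electrical,
                           map_potential, recovery_rhs, simulate_single_cell,
                           stretch_current, time_scale)
from cardiomefi.fibers import FiberField
from cardiomefi.shapes import make_box_mesh


def uniform_fibers(mesh, d=(1.0, 0.0, 0.0)):
    E = mesh.n_elements
    f = np.tile(np.asarray(d, float), (E, 1))
    s = np.tile(np.array([0.0, 0.0, 1.0]), (E, 1))
    return FiberField(beta=np.zeros(E), theta=np.zeros(E), fiber=f, sheet=s,
                      sheet_normal=np.cross(f, s),
                      isotropic_mask=np.zeros(E, dtype=bool))


# ---------------------------------------------------------------------------
# reaction terms (arithmetic oracles)

@pytest.mark.parametrize("phi,r,expected", [
    (0.0, 0.7, 0.0),                      # phi factor
    (1.0, 0.0, 0.0),                      # (phi - 1) factor
    (0.5, 0.2, 8 * 0.5 * 0.49 * (-0.5) + 0.1),   # direct arithmetic
])
def test_electrical_current_examples(phi, r, expected):
    p = EPParams(alpha=0.01, c=8.0)
    assert ionic_current_electrical(phi, r, p) == pytest.approx(expected,
                                                                abs=1e-12)


def test_stretch_current_examples():
    p = EPParams(Gs=10.0, phi_s=0.6)
    on = np.array(True)
    assert stretch_current(1.0, 0.8, on, p) == 0.0          # lambda = 1
    assert stretch_current(1.2, 0.5, on, p) == 0.0          # below phi_s
    assert stretch_current(1.1, 0.8, np.array(False), p) == 0.0  # gate shut
    assert stretch_current(1.1, 0.8, on, p) == pytest.approx(0.2, abs=1e-12)


def test_recovery_kinetics_against_symbolic_oracle():
    sympy = pytest.importorskip("sympy")
    phi_s, r_s = sympy.symbols("phi r")
    p = EPParams()
    expr = (p.gamma + p.mu1 * r_s / (p.mu2 + phi_s)) \
        * (-r_s - p.c * phi_s * (phi_s - p.b - 1))
    for phi, r in [(0.9, 1.0), (0.2, 0.5), (0.0, 0.0), (1.0, 2.0)]:
        expected = float(expr.subs({phi_s: phi, r_s: r}))
        assert recovery_rhs(phi, r, p) == pytest.approx(expected, rel=1e-12)
    # rest is a fixed point; large r at rest decays
    assert recovery_rhs(0.0, 0.0, p) == 0.0
    assert recovery_rhs(0.0, 3.0, p) < 0.0


# ---------------------------------------------------------------------------
# single cell and potential mapping

def test_subthreshold_perturbation_decays():
    out = simulate_single_cell(phi0=0.005, stimulus=(0.0, 0.0, 0.0),
                               duration=500.0)
    assert out["phi"].max() <= 0.005 + 1e-9
    assert np.all(np.diff(out["phi"]) <= 1e-12)   # monotone decay, no AP
    assert abs(out["phi"][-1]) < 1e-3


def test_action_potential_shape_and_peak():
    out = simulate_single_cell()
    assert 0.9 < out["phi_max"] < 1.1           # upstroke to the plateau
    assert abs(out["phi"][-1]) < 1e-3           # repolarized at the end
    # mapped potential honors the anchors after calibration
    p = calibrated_params()
    out2 = simulate_single_cell(p)
    Phi = map_potential(out2["phi"], p)
    assert Phi[0] == pytest.approx(-80.0, abs=1e-9)
    assert Phi.max() == pytest.approx(20.0, abs=1e-6)


def test_apd_shortens_with_faster_recovery():
    apds = []
    for gamma in (0.002, 0.004, 0.008):
        out = simulate_single_cell(EPParams(gamma=gamma))
        above = out["t"][out["phi"] > 0.5]
        apds.append(above.max() - above.min())
    assert apds[0] > apds[1] > apds[2]


def test_potential_mapping_calibration():
    d, b = calibrate_potential_mapping(0.0, 1.0)
    assert (d, b) == (-80.0, 100.0)
    # affine midpoint
    assert b * 0.5 + d == pytest.approx(-30.0)
    with pytest.raises(ValueError):
        calibrate_potential_mapping(0.5, 0.5)


def test_activation_time_profile_and_scale():
    p = EPParams(t_alpha=30.0, t0=0.0, t1=30.0, tau0=0.2, t_beta=12.0)
    za = 70.0
    assert activation_time_field(0.0, p, za) == pytest.approx(p.t_alpha)
    assert activation_time_field(za, p, za) == pytest.approx(0.0)
    # t_a = t0 puts the bracket at zero: beta_t = t_beta
    assert time_scale(p.t0, p) == pytest.approx(p.t_beta)
    with pytest.raises(ValueError):
        time_scale(10.0, EPParams(t0=5.0, t1=5.0))


# ---------------------------------------------------------------------------
# monodomain

def test_resting_state_is_stationary(ep_defaults):
    m = make_box_mesh((8.0, 2.0, 2.0), (8, 2, 2))
    model = MonodomainModel(m, uniform_fibers(m), ep_defaults)
    st = EPState.resting(m.n_nodes)
    for _ in range(5):
        st = model.step(st, 0.1)
    assert np.abs(st.phi).max() == 0.0
    assert np.abs(st.r).max() == 0.0
    assert np.allclose(st.mapped_potential(ep_defaults), -80.0)


def test_vanishing_conductivity_recovers_single_cell(ep_defaults):
    """With D -> 0 every node follows the decoupled cell trajectory."""
    from dataclasses import replace
    m = make_box_mesh((2.0, 1.0, 1.0), (2, 1, 1))
    p = replace(ep_defaults, d_fiber=1e-12, d_cross=1e-12, d_trans=1e-12)
    model = MonodomainModel(m, uniform_fibers(m), p)
    st = EPState.resting(m.n_nodes)
    st.phi[:] = 0.3                      # suprathreshold initial condition
    dt = 0.02
    for _ in range(int(40.0 / dt)):
        st = model.step(st, dt)
    z = m.nodes[:, 2]
    beta_t = time_scale(activation_time_field(
        np.clip(z, 0, z.max()), p, z.max()), p)
    # reference: tight-tolerance ODE integration per distinct time scale
    from scipy.integrate import solve_ivp
    from cardiomefi.ep import recovery_rhs, ionic_current_electrical
    for bt in np.unique(np.round(beta_t, 12)):
        sol = solve_ivp(
            lambda t, y: [-ionic_current_electrical(y[0], y[1], p) / bt,
                          recovery_rhs(y[0], y[1], p) / bt],
            (0, 40.0), [0.3, 0.0], rtol=1e-10, atol=1e-12)
        sel = np.isclose(beta_t, bt)
        assert np.abs(st.phi[sel] - sol.y[0, -1]).max() < 2e-3


def _cable_speed(d_scale=1.0, direction="along", h=0.25, length=40.0,
                 dt=0.1, params=None):
    from dataclasses import replace
    p = params or calibrated_params()
    p = replace(p, d_fiber=p.d_fiber * d_scale, d_cross=p.d_cross * d_scale,
                d_trans=p.d_trans * d_scale, Gs=0.0)
    m = make_box_mesh((length, 2 * h, 2 * h), (int(length / h), 2, 2))
    fdir = (1, 0, 0) if direction == "along" else (0, 1, 0)
    model = MonodomainModel(m, uniform_fibers(m, fdir), p)
    st = EPState.resting(m.n_nodes)
    mask = m.nodes[:, 0] < 1.0
    for _ in range(int(300.0 / dt)):
        stim = 0.15 * mask if st.t < 2.5 else None
        st = model.step(st, dt, stim_current=stim)
        x_act = m.nodes[~np.isnan(st.activation_time), 0]
        if len(x_act) and x_act.max() > 0.95 * length:
            break
    act, x = st.activation_time, m.nodes[:, 0]

    def t_at(xq):
        return np.nanmean(act[np.abs(x - xq) < 0.55 * h])

    # measure well clear of the initiation transient (front width scales
    # with sqrt(D), so faster cables need a longer run-in)
    x1, x2 = 0.4 * length, 0.85 * length
    return (x2 - x1) / (t_at(x2) - t_at(x1)), st, m


def test_wavefront_speed_anisotropy_follows_sqrt_conductivity(ep_defaults):
    """Along-fiber vs cross-fiber speed ratio equals sqrt(0.6/0.2) for the
    printed conductivities (monodomain square-root law)."""
    v_along, _, _ = _cable_speed(direction="along", h=0.125, dt=0.05,
                                 params=ep_defaults)
    v_cross, _, _ = _cable_speed(direction="cross", h=0.125, dt=0.05,
                                 length=30.0, params=ep_defaults)
    assert v_along / v_cross == pytest.approx(np.sqrt(3.0), rel=0.05)


def test_wavefront_speed_scales_with_sqrt_conductivity(ep_defaults):
    v1, _, _ = _cable_speed(1.0, h=0.125, dt=0.05, params=ep_defaults)
    v4, _, _ = _cable_speed(4.0, h=0.25, dt=0.05, length=80.0,
                            params=ep_defaults)
    assert v4 / v1 == pytest.approx(2.0, rel=0.05)


def test_front_resolved_with_five_nodes_per_wavelength(ep_defaults):
    """Upstroke width (spatial extent of the 0.1..0.9 phi rise) spans at
    least five nodes at the default cable resolution."""
    h = 0.25
    _, st, m = _cable_speed(h=h, params=ep_defaults)
    # rebuild a mid-propagation snapshot: run again and stop mid-cable
    model = MonodomainModel(m, uniform_fibers(m), ep_defaults)
    st = EPState.resting(m.n_nodes)
    mask = m.nodes[:, 0] < 1.0
    while True:
        stim = 0.15 * mask if st.t < 2.5 else None
        st = model.step(st, 0.1, stim_current=stim)
        mid = np.nanmean(st.phi[np.abs(m.nodes[:, 0] - 20.0) < 0.2])
        if mid > 0.5:
            break
    line = np.abs(m.nodes[:, 1]) < 1e-9
    x = m.nodes[line, 0]
    order = np.argsort(x)
    phi = st.phi[line][order]
    x = x[order]
    rising = (phi > 0.1) & (phi < 0.9) & (x > 5.0)
    width = x[rising].max() - x[rising].min()
    assert width >= 5 * h


def test_mapped_potential_band_on_small_mesh(ep_defaults, case1_fibers,
                                             case1_mesh):
    """Short 3D run: the mapped potential never leaves [-81, 21] mV."""
    from cardiomefi.ep import septal_apical_stimulus
    model = MonodomainModel(case1_mesh, case1_fibers, ep_defaults)
    st = EPState.resting(case1_mesh.n_nodes)
    stim = septal_apical_stimulus(case1_mesh)
    lo, hi = 0.0, 0.0
    for _ in range(600):
        cur = stim.current(st.t)
        st = model.step(st, 0.1, stim_current=cur)
        Phi = st.mapped_potential(ep_defaults)
        lo = min(lo, Phi.min())
        hi = max(hi, Phi.max())
    assert lo >= -81.0
    assert hi <= 21.0
    assert hi > 15.0      # the wave actually depolarized the wall
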