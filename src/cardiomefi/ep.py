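"""Electrophysiology: two-variable excitable-media kinetics with a
stretch-activated current, dimensional potential mapping, and anisotropic
monodomain propagation on tetrahedral meshes.

The cell model is the phenomenological two-variable (potential phi,
recovery r) excitation model of the Aliev-Panfilov family, with an added
mechano-electrical-feedback current proportional to (lambda - 1), gated by
an activation window and a potential threshold.  The dimensionless
potential is mapped to millivolts by the affine transform
Phi = beta_phi * phi + delta_phi, calibrated so that the cell's rest and
peak land exactly on -80 mV and +20 mV.  Dimensionless time tau relates to
milliseconds through a local scale beta_t that depends on an apicobasal
activation-time profile, so basal and apical tissue repolarize on
different clocks.

Propagation is the anisotropic monodomain model: effective diffusivities
0.6 / 0.2 / 0.1 mm^2/ms along the fiber, across the fiber (in-sheet
normal) and through the wall thickness, zero-flux on all boundaries
(including the epicardium), semi-implicit P1 finite elements with mass
lumping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

from .fem import stiffness_matrix, lumped_mass
from .fibers import FiberField
from .mesh import VolumeMesh

# diffusivities, mm^2/ms: along fiber / across fiber / transmural
DEFAULT_CONDUCTIVITIES = (0.6, 0.2, 0.1)


class EPError(RuntimeError):
    pass


@dataclass(frozen=True)
class EPParams:
    # excitation kinetics (dimensionless)
    alpha: float = 0.01       # excitation threshold
    c: float = 8.0            # upstroke gain
    b: float = 0.15           # plateau shift
    gamma: float = 0.002      # recovery base rate
    mu1: float = 0.2
    mu2: float = 0.3
    # stretch-activated current
    Gs: float = 1.0           # gain
    phi_s: float = 0.6        # potential threshold
    # conductivities (mm^2/ms): fiber / cross-fiber / transmural
    d_fiber: float = 0.6
    d_cross: float = 0.2
    d_trans: float = 0.1
    # dimensional potential mapping, mV
    delta_phi: float = -80.0
    beta_phi: float = 100.0
    Phi_rest: float = -80.0
    Phi_peak: float = 20.0
    # time scaling, ms: t = beta_t * tau with
    # beta_t = t_beta (1 - tau0 (t_a - t0)/(t1 - t0)), t_a = t_alpha (1 - Z/Z_apex)
    t_beta: float = 12.0
    tau0: float = 0.2
    t0: float = 0.0
    t1: float = 30.0
    t_alpha: float = 30.0

    def validate(self) -> None:
        problems = []
        if not 0 < self.alpha < 1:
            problems.append("need 0 < alpha < 1")
        if self.beta_phi <= 0:
            problems.append("beta_phi must be positive")
        if min(self.d_fiber, self.d_cross, self.d_trans) <= 0:
            problems.append("conductivities must be positive")
        if self.t1 == self.t0:
            problems.append("need t1 != t0 in the time-scale rule")
        if problems:
            raise ValueError("; ".join(problems))


@dataclass
class EPState:
    phi: np.ndarray              # nodal dimensionless potential
    r: np.ndarray                # nodal recovery variable
    lambda_f: np.ndarray         # nodal fiber stretch (from mechanics)
    window: np.ndarray           # bool, activation window gate per node
    activation_time: np.ndarray  # ms, nan until phi upcrosses 0.5
    t: float = 0.0               # ms

    @classmethod
    def resting(cls, n_nodes: int) -> "EPState":
        return cls(phi=np.zeros(n_nodes), r=np.zeros(n_nodes),
                   lambda_f=np.ones(n_nodes),
                   window=np.zeros(n_nodes, dtype=bool),
                   activation_time=np.full(n_nodes, np.nan))

    def mapped_potential(self, params: EPParams) -> np.ndarray:
        return map_potential(self.phi, params)


# ---------------------------------------------------------------------------
# reaction terms

def ionic_current_electrical(phi, r, params: EPParams):
    """Excitation current: c phi (phi - alpha)(phi - 1) + r phi."""
    return params.c * phi * (phi - params.alpha) * (phi - 1.0) + r * phi


def stretch_current(lambda_f, phi, window, params: EPParams):
    """Stretch-activated current, active only inside the response window
    and above the potential threshold phi_s."""
    gate = np.asarray(window, dtype=float) * (np.asarray(phi) > params.phi_s)
    return gate * params.Gs * (np.asarray(lambda_f) - 1.0) * (phi - params.phi_s)


def recovery_rhs(phi, r, params: EPParams):
    """dr/dtau = (gamma + mu1 r / (mu2 + phi)) (-r - c phi (phi - b - 1))."""
    rate = params.gamma + params.mu1 * r / (params.mu2 + phi)
    return rate * (-r - params.c * phi * (phi - params.b - 1.0))


def map_potential(phi, params: EPParams):
    """Dimensional transmembrane potential Phi = beta_phi phi + delta_phi (mV)."""
    return params.beta_phi * np.asarray(phi) + params.delta_phi


def calibrate_potential_mapping(phi_rest: float, phi_max: float,
                                Phi_rest: float = -80.0,
                                Phi_peak: float = 20.0):
    """Solve the affine two-point calibration for (delta_phi, beta_phi)."""
    if phi_max <= phi_rest:
        raise ValueError("need phi_max > phi_rest for the potential mapping")
    beta_phi = (Phi_peak - Phi_rest) / (phi_max - phi_rest)
    delta_phi = Phi_rest - beta_phi * phi_rest
    return delta_phi, beta_phi


def activation_time_field(z, params: EPParams, z_apex: float):
    """Apicobasal activation-time profile t_a = t_alpha (1 - Z/Z_apex), ms."""
    z = np.asarray(z, float)
    if np.any(z < -1e-9) or np.any(z > z_apex + 1e-9):
        raise ValueError("Z outside [0, Z_LVapex]")
    return params.t_alpha * (1.0 - np.clip(z, 0, z_apex) / z_apex)


def time_scale(t_a, params: EPParams):
    """Local ms-per-tau factor beta_t(t_a)."""
    if params.t1 == params.t0:
        raise ValueError("t1 == t0 makes the time-scale rule singular")
    return params.t_beta * (1.0 - params.tau0 * (np.asarray(t_a, float)
                                                 - params.t0)
                            / (params.t1 - params.t0))


# ---------------------------------------------------------------------------
# single cell

def simulate_single_cell(params: EPParams | None = None,
                         stimulus: tuple[float, float, float] = (1.0, 1.0, 0.3),
                         duration: float = 600.0, dt: float = 0.05,
                         lambda_f: float = 1.0, phi0: float = 0.0,
                         r0: float = 0.0, rtol: float = 1e-8):
    """One cell in dimensionless time mapped to ms via beta_t.

    ``stimulus`` = (t_on ms, t_dur ms, amplitude) adds a rectangular
    dphi/dtau source.  Returns dict with t (ms), phi, r, Phi (mV) and the
    recorded peak.  Stiff-safe adaptive integration (Radau fallback).
    """
    p = params or EPParams()
    p.validate()
    bt = float(time_scale(p.t_alpha * 0.5, p))  # mid-wall clock for the cell
    t_on, t_dur, amp = stimulus

    window = {"open": False}

    def rhs(t, y):
        phi, r = y
        gate = 1.0 if (window["open"] and phi > p.phi_s) else 0.0
        Im = gate * p.Gs * (lambda_f - 1.0) * (phi - p.phi_s)
        Ie = ionic_current_electrical(phi, r, p)
        stim = amp if t_on <= t < t_on + t_dur else 0.0
        dphi = (-(Ie + Im) + stim) / bt
        dr = recovery_rhs(phi, r, p) / bt
        return [dphi, dr]

    # integrate in segments so the stimulus edges are resolved exactly
    edges = [0.0, t_on, t_on + t_dur, duration]
    edges = sorted({e for e in edges if 0.0 <= e <= duration})
    ts, phis, rs = [0.0], [phi0], [r0]
    y = [phi0, r0]
    for a, bnd in zip(edges[:-1], edges[1:]):
        t_eval = np.arange(a, bnd, dt)[1:]
        sol = solve_ivp(rhs, (a, bnd), y, method="LSODA", rtol=rtol,
                        atol=1e-10, t_eval=np.append(t_eval, bnd))
        if not sol.success or np.any(~np.isfinite(sol.y)):
            raise EPError(f"single-cell integration failed: {sol.message}")
        ts.extend(sol.t.tolist())
        phis.extend(sol.y[0].tolist())
        rs.extend(sol.y[1].tolist())
        y = [sol.y[0, -1], sol.y[1, -1]]
        if y[0] > 0.5:
            window["open"] = True
        if window["open"] and y[0] < 0.5 and bnd > t_on + t_dur:
            window["open"] = False
    t_arr = np.array(ts)
    phi_arr = np.array(phis)
    return {
        "t": t_arr, "phi": phi_arr, "r": np.array(rs),
        "Phi": map_potential(phi_arr, p),
        "phi_max": float(phi_arr.max()), "phi_rest": float(phi0),
        "beta_t": bt,
    }


def calibrated_params(params: EPParams | None = None, **cell_kwargs) -> EPParams:
    """Return params with (delta_phi, beta_phi) calibrated from a simulated
    single-cell action potential (rest -> -80 mV, peak -> +20 mV)."""
    p = params or EPParams()
    cell = simulate_single_cell(p, **cell_kwargs)
    d, b = calibrate_potential_mapping(0.0, cell["phi_max"],
                                       p.Phi_rest, p.Phi_peak)
    return replace(p, delta_phi=d, beta_phi=b)


# ---------------------------------------------------------------------------
# monodomain on a mesh

def conductivity_tensors(fibers: FiberField,
                         params: EPParams | None = None) -> np.ndarray:
    """Per-element SPD diffusivity tensors (mm^2/ms) in the fiber frame.

    Eigenvalues (d_fiber, d_cross, d_trans) along (fiber, sheet-normal,
    sheet/transmural); apex-cylinder elements get the isotropic mean."""
    p = params or EPParams()
    D = (p.d_fiber * np.einsum("ei,ej->eij", fibers.fiber, fibers.fiber)
         + p.d_cross * np.einsum("ei,ej->eij", fibers.sheet_normal,
                                 fibers.sheet_normal)
         + p.d_trans * np.einsum("ei,ej->eij", fibers.sheet, fibers.sheet))
    iso = fibers.isotropic_mask
    if np.any(iso):
        mean = (p.d_fiber + p.d_cross + p.d_trans) / 3.0
        D[iso] = mean * np.eye(3)
    return D


def _m_matrix_correction(K):
    """Clip positive off-diagonal stiffness entries into the diagonal.

    Anisotropic P1 stiffness on obtuse tetrahedra loses the M-matrix
    property and lets the potential under/overshoot its physical band;
    moving the offending (positive off-diagonal) couplings onto the
    diagonal preserves row sums (constants stay exact) and restores the
    discrete maximum principle at the cost of slight extra smearing.
    """
    A = K.tocoo()
    off = A.row != A.col
    bad = off & (A.data > 0)
    if not np.any(bad):
        return K.tocsr()
    moved = np.zeros(A.shape[0])
    np.add.at(moved, A.row[bad], A.data[bad])
    data = A.data.copy()
    data[bad] = 0.0
    out = sp.coo_matrix((data, (A.row, A.col)), shape=A.shape).tocsr()
    return out + sp.diags(moved)


class MonodomainModel:
    """Semi-implicit monodomain stepper (diffusion implicit, reaction
    explicit) with a spatially varying time-scale field."""

    def __init__(self, mesh: VolumeMesh, fibers: FiberField,
                 params: EPParams | None = None,
                 z_apex: float | None = None,
                 monotone: bool = True):
        self.mesh = mesh
        self.params = params or EPParams()
        self.params.validate()
        self.K = stiffness_matrix(mesh.nodes, mesh.tets,
                                  conductivity_tensors(fibers, self.params))
        if monotone:
            self.K = _m_matrix_correction(self.K)
        self.M = lumped_mass(mesh.nodes, mesh.tets)
        za = float(mesh.nodes[:, 2].max()) if z_apex is None else z_apex
        z = np.clip(mesh.nodes[:, 2], 0.0, za)
        self.beta_t = time_scale(activation_time_field(z, self.params, za),
                                 self.params)
        if np.any(self.beta_t <= 0):
            raise EPError("time-scale field beta_t must stay positive; "
                          "check tau0/t0/t1/t_alpha")
        self._solver = None
        self._dt = None

    def _factorize(self, dt: float):
        if self._dt == dt and self._solver is not None:
            return
        A = sp.diags(self.M / dt) + self.K.tocsc()
        self._solver = spla.factorized(A.tocsc())
        self._dt = dt

    def step(self, state: EPState, dt: float,
             stim_current: np.ndarray | None = None,
             max_halvings: int = 8) -> EPState:
        """Advance one step of size dt (ms); halves dt internally on
        instability (non-finite or wildly out-of-range potentials)."""
        for attempt in range(max_halvings + 1):
            sub = 2 ** attempt
            ok, new = self._try_steps(state, dt / sub, sub, stim_current)
            if ok:
                return new
        raise EPError("monodomain step failed even after step halving")

    def _try_steps(self, state: EPState, dt, n_sub, stim_current):
        p = self.params
        phi, r = state.phi.copy(), state.r.copy()
        window = state.window.copy()
        act = state.activation_time.copy()
        t = state.t
        self._factorize(dt)
        for _ in range(n_sub):
            Ie = ionic_current_electrical(phi, r, p)
            Im = stretch_current(state.lambda_f, phi, window, p)
            react = -(Ie + Im) / self.beta_t
            if stim_current is not None:
                react = react + stim_current
            rhs = self.M * (phi / dt + react)
            phi_new = self._solver(rhs)
            r_new = r + dt * recovery_rhs(phi, r, p) / self.beta_t
            if not (np.all(np.isfinite(phi_new)) and np.all(np.isfinite(r_new))
                    and np.abs(phi_new).max() < 10.0):
                return False, None
            t += dt
            up = (phi < 0.5) & (phi_new >= 0.5)
            act[up & np.isnan(act)] = t
            window = window | up
            window = window & ~((phi >= 0.5) & (phi_new < 0.5))
            phi, r = phi_new, r_new
        new = EPState(phi=phi, r=r, lambda_f=state.lambda_f, window=window,
                      activation_time=act, t=t)
        return True, new


@dataclass
class StimulusProtocol:
    """Brief endocardial stimulus: node mask + rectangular time course.

    ``amplitude`` is a dimensionless dphi/dtau source converted by the
    local time scale inside the stepper caller (applied as dphi/dt here).
    """
    node_mask: np.ndarray
    t_on: float = 0.0        # ms
    duration: float = 2.5    # ms (printed protocol: 2-3 ms pulses)
    amplitude: float = 0.15  # per ms; lifts phi well past threshold without
                             # overshooting the action-potential peak

    def current(self, t: float) -> np.ndarray | None:
        if self.t_on <= t < self.t_on + self.duration:
            return self.amplitude * self.node_mask.astype(float)
        return None


def septal_apical_stimulus(mesh: VolumeMesh, z_apex: float | None = None,
                           apex_fraction: float = 0.25,
                           septal_halfwidth_deg: float = 40.0,
                           **kwargs) -> StimulusProtocol:
    """Default activation sites: apical endocardium plus a septal
    endocardial strip (early foci on the septum and apical side)."""
    za = float(mesh.nodes[:, 2].max()) if z_apex is None else z_apex
    endo = mesh.surface_nodes("endocardium")
    mask = np.zeros(mesh.n_nodes, dtype=bool)
    xyz = mesh.nodes[endo]
    apical = xyz[:, 2] > (1.0 - apex_fraction) * za
    ang = np.degrees(np.arctan2(xyz[:, 1], xyz[:, 0]))
    septal = (np.abs(np.abs(ang) - 180.0) < septal_halfwidth_deg) \
        & (xyz[:, 2] < 0.5 * za) & (xyz[:, 2] > 0.1 * za)
    mask[endo[apical | septal]] = True
    return StimulusProtocol(node_mask=mask, **kwargs)


def basal_patch_initial_condition(mesh: VolumeMesh, params: EPParams,
                                  patch_potential_mv: float = -10.0,
                                  z_extent: float = 0.15,
                                  halfwidth_deg: float = 45.0) -> np.ndarray:
    """Initial potential: resting everywhere except a rectangular basal
    patch raised to ``patch_potential_mv`` (in phi units)."""
    za = float(mesh.nodes[:, 2].max())
    ang = np.degrees(np.arctan2(mesh.nodes[:, 1], mesh.nodes[:, 0]))
    patch = (mesh.nodes[:, 2] < z_extent * za) & (np.abs(ang) < halfwidth_deg)
    phi = np.zeros(mesh.n_nodes)
    phi[patch] = (patch_potential_mv - params.delta_phi) / params.beta_phi
    return phi


def run_monodomain(mesh: VolumeMesh, fibers: FiberField,
                   params: EPParams | None = None, duration: float = 500.0,
                   dt: float = 0.1, stimulus: StimulusProtocol | None = None,
                   initial_phi: np.ndarray | None = None,
                   lambda_f: np.ndarray | None = None,
                   record_every: int = 10):
    """Activation-recovery run; returns summary dict with the trace of
    mean/min/max mapped potential and the activation-time field."""
    p = params or EPParams()
    model = MonodomainModel(mesh, fibers, p)
    state = EPState.resting(mesh.n_nodes)
    if initial_phi is not None:
        state.phi = initial_phi.copy()
    if lambda_f is not None:
        state.lambda_f = lambda_f
    times, mean_mv, min_mv, max_mv = [], [], [], []
    n_steps = int(round(duration / dt))
    run_min, run_max = np.inf, -np.inf
    for i in range(n_steps):
        stim = stimulus.current(state.t) if stimulus is not None else None
        state = model.step(state, dt, stim_current=stim)
        Phi = state.mapped_potential(p)
        run_min = min(run_min, float(Phi.min()))
        run_max = max(run_max, float(Phi.max()))
        if i % record_every == 0 or i == n_steps - 1:
            times.append(state.t)
            mean_mv.append(float(Phi.mean()))
            min_mv.append(float(Phi.min()))
            max_mv.append(float(Phi.max()))
    return {
        "t": np.array(times), "Phi_mean": np.array(mean_mv),
        "Phi_min": np.array(min_mv), "Phi_max": np.array(max_mv),
        "Phi_run_min": run_min, "Phi_run_max": run_max,
        "activation_time": state.activation_time, "state": state,
    }
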