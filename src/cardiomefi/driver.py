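"""Staggered systolic simulation of one LV case.

Per time step: (1) the anisotropic monodomain model advances the
potential with the current fiber stretch feeding the stretch-activated
current; (2) the active stress relaxes toward its potential-driven
target; (3) the wall equilibrates quasi-statically under the active
stress and the cavity pressure; (4) the 0D cavity surrogate closes the
loop — during isovolumic phases the cavity pressure is the scalar that
holds the cavity volume fixed, and during ejection pressure and flow are
made consistent with the two-element Windkessel afterload
(P = Q Rc + P_Wk).  Sub-iterations at each step run until the relative
L2 change of displacement and pressure drops below the configured
tolerance.

Diastolic filling is out of scope: the run starts from the end-diastolic
configuration (treated as an effectively prestressed state equilibrated
at the end-diastolic pressure) and continues through isovolumic
contraction and ejection until the 0D aortic valve closes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .active_stress import step_active_stress, active_stress_tensor
from .config import ParameterSet, load_config
from .ep import (EPState, MonodomainModel, calibrated_params,
                 septal_apical_stimulus, basal_patch_initial_condition)
from .fibers import generate_fibers
from .geometry import CASES, build_lv_geometry
from .mechanics import (MechanicsProblem, torsion_angle,
                        max_principal_strain)
from .mesh import VolumeMesh, close_surface_with_cap, enclosed_volume_mm3
from .units import MMHG_TO_KPA, KPA_TO_MMHG
from .windkessel import windkessel_step, pv_loop


class CouplingError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    case_id: int = 1
    resolution: str = "coarse"
    duration: float = 420.0            # ms of systole simulated
    dt_mech: float = 2.5               # ms, mechanics/coupling step
    dt_ep: float = 0.25                # ms, monodomain substep
    dt_bounds: tuple = (1e-3, 1.0)     # ms, adaptive band
    subiteration_tol: float = 1e-4     # relative L2, displacement & pressure
    max_subiterations: int = 20
    ed_pressure: float = 10.0 * MMHG_TO_KPA        # kPa
    aortic_diastolic_pressure: float = 80.0 * MMHG_TO_KPA  # kPa (P_Wk init)
    electromech_delay: float = 0.0     # ms (value unprinted; default 0)
    stimulus: str = "septal_apical"    # or "basal_patch"
    seed: int = 0
    record_fields: bool = False
    params: ParameterSet | None = None

    def validate(self) -> None:
        problems = []
        if self.subiteration_tol <= 0:
            problems.append("subiteration tolerance must be positive")
        if self.dt_bounds[0] > self.dt_bounds[1]:
            problems.append("need dt_min <= dt_max")
        if self.case_id not in CASES:
            problems.append(f"case_id must be one of {sorted(CASES)}")
        if problems:
            raise ValueError("; ".join(problems))


@dataclass
class SimulationTrace:
    t: np.ndarray                 # ms
    volume: np.ndarray            # mL
    p_cavity: np.ndarray          # mmHg
    p_aortic: np.ndarray          # mmHg
    flow: np.ndarray              # mL/s (aortic; 0 when valve closed)
    phi_mean: np.ndarray          # mV
    phi_max: np.ndarray           # mV
    sigma_a_mean: np.ndarray      # kPa
    vm_max: np.ndarray            # kPa
    strain_max: np.ndarray        # %
    apex_xy: np.ndarray           # (T, 2) mm
    apex_z: np.ndarray            # mm
    torsion: np.ndarray           # deg
    valve_open: np.ndarray        # bool
    active_work: np.ndarray = None  # cumulative active-stress work, kPa mm^3
    meta: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ms": self.t, "volume_mL": self.volume,
            "p_cavity_mmHg": self.p_cavity, "p_aortic_mmHg": self.p_aortic,
            "flow_mL_per_s": self.flow, "phi_mean_mV": self.phi_mean,
            "phi_max_mV": self.phi_max, "sigma_a_mean_kPa": self.sigma_a_mean,
            "von_mises_max_kPa": self.vm_max, "strain_max_pct": self.strain_max,
            "apex_x_mm": self.apex_xy[:, 0], "apex_y_mm": self.apex_xy[:, 1],
            "apex_z_mm": self.apex_z, "torsion_deg": self.torsion,
            "valve_open": self.valve_open.astype(int),
        })

    def pv_metrics(self):
        return pv_loop(self.volume, self.p_cavity)


def _deformed_cavity_volume(mesh: VolumeMesh, u: np.ndarray) -> float:
    faces = mesh.surface_tags["endocardium"]
    nodes, closed = close_surface_with_cap(mesh.nodes + u, faces)
    return enclosed_volume_mm3(nodes, closed) / 1000.0


def _nodal_fiber_stretch(mesh: VolumeMesh, F: np.ndarray,
                         fiber: np.ndarray) -> np.ndarray:
    C = np.einsum("eki,ekj->eij", F, F)
    lam = np.sqrt(np.einsum("ei,eij,ej->e", fiber, C, fiber))
    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    np.add.at(num, mesh.tets.ravel(), np.repeat(lam, 4))
    np.add.at(den, mesh.tets.ravel(), 1.0)
    return num / np.maximum(den, 1.0)


class SystolicModel:
    """Assembled case: mesh, fibers, EP model, mechanics problem."""

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        p = config.params or load_config(
            overrides={"case": {"case_id": config.case_id}})
        self.params = replace(p, ep=calibrated_params(p.ep))
        self.mesh = build_lv_geometry(p.case, config.resolution)
        self.fibers = generate_fibers(self.mesh,
                                      p.fibers.beta_method,
                                      p.fibers.theta_epi_max,
                                      p.fibers.theta_endo_max)
        self.ep_model = MonodomainModel(self.mesh, self.fibers,
                                        self.params.ep)
        self.mech = MechanicsProblem(self.mesh, p.myocardium,
                                     [self.fibers.fiber])
        if config.stimulus == "septal_apical":
            self.stimulus = septal_apical_stimulus(self.mesh)
            self.initial_phi = None
        elif config.stimulus == "basal_patch":
            self.stimulus = None
            self.initial_phi = basal_patch_initial_condition(
                self.mesh, self.params.ep)
        else:
            raise ValueError(f"unknown stimulus {config.stimulus!r}")

    # -- 0D cavity coupling -------------------------------------------------

    def _volume_at_pressure(self, p_kpa, active, u_guess):
        st = self.mech.solve_quasistatic(pressure_kpa=p_kpa,
                                         active_tensors=active, u0=u_guess)
        return _deformed_cavity_volume(self.mesh, st.u), st

    def run(self) -> SimulationTrace:
        cfg = self.config
        ep_p = self.params.ep
        act_p = self.params.active
        wk = self.params.windkessel
        rng = np.random.default_rng(cfg.seed)   # reserved for perturbations
        del rng

        # end-diastolic equilibration: prestressed initial state
        p_cav = cfg.ed_pressure
        mst = self.mech.solve_quasistatic(pressure_kpa=p_cav)
        u = mst.u
        V = _deformed_cavity_volume(self.mesh, u)
        V_hold = V

        ep_state = EPState.resting(self.mesh.n_nodes)
        if self.initial_phi is not None:
            ep_state.phi = self.initial_phi.copy()
        sigma_a = np.zeros(self.mesh.n_elements)
        p_wk = cfg.aortic_diastolic_pressure * KPA_TO_MMHG   # mmHg
        valve_open = False
        closed_after_ejection = False
        dVdP = None                     # mL/kPa secant slope

        apex_node = int(np.argmax(self.mesh.nodes[:, 2]))
        rec = {k: [] for k in ("t", "V", "pc", "pa", "q", "phim", "phix",
                               "sa", "vm", "strain", "ax", "ay", "az",
                               "tors", "open", "wact")}
        vols = self.mech.vol
        E_green = 0.5 * (np.einsum("eki,ekj->eij", mst.F, mst.F) - np.eye(3))
        w_active = 0.0                 # energy delivered by contraction
        n_steps = int(round(cfg.duration / cfg.dt_mech))
        n_sub = max(1, int(round(cfg.dt_mech / cfg.dt_ep)))
        dt_ep = cfg.dt_mech / n_sub

        delay_steps = int(round(cfg.electromech_delay / cfg.dt_mech))
        phi_history: list[np.ndarray] = []

        for step in range(n_steps):
            # (1) electrophysiology with current fiber stretch
            ep_state.lambda_f = _nodal_fiber_stretch(self.mesh, mst.F,
                                                     self.fibers.fiber)
            for _ in range(n_sub):
                stim = self.stimulus.current(ep_state.t) \
                    if self.stimulus is not None else None
                ep_state = self.ep_model.step(ep_state, dt_ep,
                                              stim_current=stim)
            Phi = ep_state.mapped_potential(ep_p)
            Phi_el = Phi[self.mesh.tets].mean(axis=1)

            # (2) active stress (optionally delayed potential)
            phi_history.append(Phi_el)
            Phi_used = phi_history[max(0, len(phi_history) - 1 - delay_steps)]
            sigma_a = step_active_stress(sigma_a, Phi_used, cfg.dt_mech, act_p)
            active = active_stress_tensor(sigma_a, self.fibers.fiber,
                                          self.fibers.sheet,
                                          self.fibers.sheet_normal, act_p,
                                          isotropic_mask=self.fibers.isotropic_mask)

            # (3)+(4) mechanics with the 0D valve/afterload sub-iteration
            V_prev = V
            p_ao_mmhg = p_wk            # Q = 0 reference
            if not valve_open:
                p_cav, V, mst, dVdP = self._isovolumic_step(
                    p_cav, V_hold, active, u, dVdP)
                q_ml_s = 0.0
                if p_cav * KPA_TO_MMHG >= p_ao_mmhg and not closed_after_ejection:
                    valve_open = True
            if valve_open:
                p_cav, V, mst, q_ml_s, p_wk, p_ao_mmhg, dVdP = \
                    self._ejection_step(p_cav, V_prev, active, u, p_wk,
                                        wk, dVdP)
                if q_ml_s <= 0.0:
                    valve_open = False
                    closed_after_ejection = True
                    V_hold = V
            else:
                # Windkessel keeps decaying with zero inflow while closed
                p_wk, _ = windkessel_step(p_wk, 0.0, cfg.dt_mech / 1000.0, wk)
            u = mst.u
            E_new = 0.5 * (np.einsum("eki,ekj->eij", mst.F, mst.F)
                           - np.eye(3))
            # the contractile element delivers -S_act : dE to the tissue
            w_active -= float(np.einsum("eij,eij,e->", active,
                                        E_new - E_green, vols))
            E_green = E_new

            rec["t"].append(ep_state.t)
            rec["V"].append(V)
            rec["pc"].append(p_cav * KPA_TO_MMHG)
            rec["pa"].append(p_ao_mmhg)
            rec["q"].append(q_ml_s)
            rec["phim"].append(float(Phi.mean()))
            rec["phix"].append(float(Phi.max()))
            rec["sa"].append(float(sigma_a.mean()))
            rec["vm"].append(float(mst.sigma_vm.max()))
            rec["strain"].append(max_principal_strain(mst.F))
            rec["ax"].append(u[apex_node, 0])
            rec["ay"].append(u[apex_node, 1])
            rec["az"].append(u[apex_node, 2])
            rec["tors"].append(torsion_angle(self.mesh, u))
            rec["wact"].append(w_active)
            rec["open"].append(valve_open)

        return SimulationTrace(
            t=np.array(rec["t"]), volume=np.array(rec["V"]),
            p_cavity=np.array(rec["pc"]), p_aortic=np.array(rec["pa"]),
            flow=np.array(rec["q"]), phi_mean=np.array(rec["phim"]),
            phi_max=np.array(rec["phix"]), sigma_a_mean=np.array(rec["sa"]),
            vm_max=np.array(rec["vm"]), strain_max=np.array(rec["strain"]),
            apex_xy=np.column_stack([rec["ax"], rec["ay"]]),
            apex_z=np.array(rec["az"]), torsion=np.array(rec["tors"]),
            valve_open=np.array(rec["open"]),
            active_work=np.array(rec["wact"]),
            meta={"edv": V_hold if not closed_after_ejection else None,
                  "config": dataclasses.asdict(
                      replace(self.config, params=None))})

    def _isovolumic_step(self, p_cav, V_hold, active, u_guess, dVdP):
        """Find the cavity pressure holding the volume at V_hold."""
        cfg = self.config
        if dVdP is None:
            dVdP = 2.0                         # mL/kPa initial slope guess
        p = p_cav
        V, mst = self._volume_at_pressure(p, active, u_guess)
        for it in range(cfg.max_subiterations):
            err = V - V_hold
            if abs(err) < cfg.subiteration_tol * max(V_hold, 1.0):
                return p, V, mst, dVdP
            p_new = p - err / dVdP
            p_new = min(max(p_new, p - 8.0), p + 8.0)   # kPa trust region
            V_new, mst = self._volume_at_pressure(p_new, active, u_guess)
            if abs(p_new - p) > 1e-12:
                dVdP = max((V_new - V) / (p_new - p), 1e-3)
            p, V = p_new, V_new
        raise CouplingError("isovolumic pressure iteration did not converge "
                            f"(|dV| = {abs(V - V_hold):.3e} mL)")

    def _ejection_step(self, p_cav, V_prev, active, u_guess, p_wk, wk, dVdP):
        """Pressure/flow consistent with the Windkessel during ejection."""
        cfg = self.config
        dt_s = cfg.dt_mech / 1000.0
        if dVdP is None:
            dVdP = 2.0

        def residual(p_kpa):
            V, mst = self._volume_at_pressure(p_kpa, active, u_guess)
            q = (V_prev - V) / dt_s                  # mL/s
            p_wk_new, p_ao = windkessel_step(p_wk, q, dt_s, wk)
            return p_kpa - p_ao * MMHG_TO_KPA, V, mst, q, p_wk_new, p_ao

        p = p_cav
        r, V, mst, q, p_wk_new, p_ao = residual(p)
        for it in range(cfg.max_subiterations):
            if abs(r) < cfg.subiteration_tol * max(abs(p), 1.0):
                return p, V, mst, q, p_wk_new, p_ao, dVdP
            # d(residual)/dp = 1 + (dV/dp)/dt * (Rc + dPwk/dQ) in kPa units
            slope = 1.0 + (dVdP / dt_s) * wk.Rc * MMHG_TO_KPA
            p_new = p - r / slope
            r_new, V_new, mst, q, p_wk_new, p_ao = residual(p_new)
            if abs(p_new - p) > 1e-12:
                dVdP = max((V_new - V) / (p_new - p), 1e-3)
            p, r, V = p_new, r_new, V_new
        raise CouplingError("ejection sub-iteration did not converge "
                            f"(residual {r:.3e} kPa)")


def run_systolic_case(config: SimulationConfig | None = None,
                      **kwargs) -> SimulationTrace:
    """Build and run one systolic case; see :class:`SimulationConfig`."""
    cfg = config or SimulationConfig(**kwargs)
    return SystolicModel(cfg).run()


# ---------------------------------------------------------------------------
# outlet waveform export

def export_lvot_velocity_profile(trace: SimulationTrace,
                                 lvot_radius_mm: float) -> pd.DataFrame:
    """Outlet flow and mean-velocity waveform from the volume trace.

    Q(t) = -dV/dt (central differences) clipped to the open-valve phase;
    the mean velocity divides by the LVOT area.  Serves as the 0D
    surrogate for the 3D outflow velocity field.
    """
    t = trace.t
    Q_ml_ms = -np.gradient(trace.volume, t)          # mL/ms
    Q_ml_s = Q_ml_ms * 1000.0
    area_mm2 = np.pi * lvot_radius_mm ** 2
    v_m_s = Q_ml_ms * 1000.0 / area_mm2              # mm^3/ms / mm^2 = m/s
    return pd.DataFrame({
        "time_ms": t,
        "volume_mL": trace.volume,
        "flow_mL_per_s": Q_ml_s,
        "mean_velocity_m_per_s": v_m_s,
        "valve_open": trace.valve_open.astype(int),
    })


# ---------------------------------------------------------------------------
# calibration

@dataclass
class CalibrationReport:
    achieved: float
    target: float
    value: float          # calibrated parameter value
    history: list


def calibrate_k_for_ef(target_ef: float, config: SimulationConfig | None = None,
                       bracket=(5.0, 45.0), tol: float = 1.0,
                       max_iter: int = 6) -> CalibrationReport:
    """Bounded scalar search on the saturated active-stress gain k so the
    coarse coupled model matches the target ejection fraction.

    EF is monotone non-decreasing in k over the physiologic bracket, so a
    guarded secant/bisection suffices.  ``tol`` in EF percentage points.
    """
    cfg = config or SimulationConfig()
    history = []

    def ef_of(k):
        p = cfg.params or load_config(
            overrides={"case": {"case_id": cfg.case_id}})
        p = replace(p, active=replace(p.active, k=k))
        trace = run_systolic_case(replace(cfg, params=p))
        ef = trace.pv_metrics().ef
        history.append((k, ef))
        return ef

    lo, hi = bracket
    f_lo, f_hi = ef_of(lo) - target_ef, ef_of(hi) - target_ef
    if abs(f_lo) < tol:
        return CalibrationReport(f_lo + target_ef, target_ef, lo, history)
    if abs(f_hi) < tol:
        return CalibrationReport(f_hi + target_ef, target_ef, hi, history)
    if f_lo * f_hi > 0:
        best = min(history, key=lambda kv: abs(kv[1] - target_ef))
        raise CouplingError(
            f"EF target {target_ef}% unreachable in k bracket {bracket}; "
            f"best achieved {best[1]}% at k={best[0]}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = ef_of(mid) - target_ef
        if abs(f_mid) < tol:
            return CalibrationReport(f_mid + target_ef, target_ef, mid,
                                     history)
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    k_best, ef_best = min(history, key=lambda kv: abs(kv[1] - target_ef))
    return CalibrationReport(ef_best, target_ef, k_best, history)


def sweep_eta3_torsion(values, config: SimulationConfig | None = None):
    """Peak apical torsion for each sheet-normal weight eta3 (the twist
    study); returns list of (eta3, peak torsion deg)."""
    cfg = config or SimulationConfig()
    out = []
    for eta3 in values:
        p = cfg.params or load_config(
            overrides={"case": {"case_id": cfg.case_id}})
        p = replace(p, active=replace(p.active, eta3=eta3))
        trace = run_systolic_case(replace(cfg, params=p))
        peak = float(np.max(np.abs(trace.torsion)))
        out.append((eta3, peak))
    return out
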