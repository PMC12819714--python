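"""Finite-element momentum balance for the actively contracting wall.

Total-Lagrangian linear tetrahedra with one-point quadrature, Newton
iterations with consistent-by-differencing element tangents, follower
(cavity) pressure on the tagged endocardial surface, rigid basal fixation
and optional roller (symmetry-plane) constraints.  Quasi-static solves
drive the coupled systolic loop; an implicit Newmark stepper covers the
dynamic benchmarks.

Internal units: mm, ms, kPa; density in mg/mm^3 (1 g/cm^3 = 1.0) so that
rho * accel balances stress/length consistently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import tet_gradients, lumped_mass
from .materials import (MaterialError, MyocardiumMaterial,
                        pk2_stress_myocardium, cauchy_from_pk2, von_mises)
from .mesh import VolumeMesh, MeshError


class MechanicsError(RuntimeError):
    pass


@dataclass
class MechanicsState:
    u: np.ndarray                    # (N, 3) nodal displacement, mm
    v: np.ndarray | None = None      # mm/ms
    a: np.ndarray | None = None      # mm/ms^2
    F: np.ndarray | None = None      # (E, 3, 3) deformation gradient
    sigma_vm: np.ndarray | None = None
    volumetric_strain: np.ndarray | None = None


class DofConstraints:
    """Per-node fixed directions, eliminated through a local basis change."""

    def __init__(self, n_nodes: int):
        self.n = n_nodes
        self.dirs: dict[int, list[np.ndarray]] = {}

    def fix_nodes(self, nodes: np.ndarray) -> None:
        for n in np.asarray(nodes).ravel():
            self.dirs[int(n)] = [np.eye(3)[i] for i in range(3)]

    def roller(self, nodes: np.ndarray, normal) -> None:
        d = np.asarray(normal, float)
        d = d / np.linalg.norm(d)
        for n in np.asarray(nodes).ravel():
            lst = self.dirs.setdefault(int(n), [])
            if len(lst) >= 3:
                continue
            # keep only the component orthogonal to existing constraints
            v = d.copy()
            for e in lst:
                v = v - (v @ e) * e
            nn = np.linalg.norm(v)
            if nn > 1e-9:
                lst.append(v / nn)

    def build(self):
        """Returns (T, free_mask): global dofs u = T q with q the rotated
        dofs; free_mask selects the unconstrained entries of q."""
        blocks = sp.identity(3 * self.n, format="lil")
        free = np.ones(3 * self.n, dtype=bool)
        for node, dirs in self.dirs.items():
            basis = _complete_basis(dirs)
            blocks[3 * node:3 * node + 3, 3 * node:3 * node + 3] = basis.T
            free[3 * node:3 * node + len(dirs)] = False
        return blocks.tocsr(), free


def _complete_basis(dirs: list[np.ndarray]) -> np.ndarray:
    """Orthonormal 3x3 basis whose first rows are the constrained dirs."""
    rows = [d for d in dirs]
    for cand in np.eye(3):
        if len(rows) == 3:
            break
        v = cand.copy()
        for r in rows:
            v = v - (v @ r) * r
        if np.linalg.norm(v) > 1e-8:
            rows.append(v / np.linalg.norm(v))
    return np.array(rows)


class MechanicsProblem:
    """Assembles residual and tangent for one mesh + material + fiber set."""

    def __init__(self, mesh: VolumeMesh, material: MyocardiumMaterial,
                 fiber_dirs, fixed_tags=("base",),
                 roller_planes: dict | None = None,
                 pressure_tag: str = "endocardium",
                 density: float = 1.055):
        self.mesh = mesh
        self.material = material
        self.fibers = [np.asarray(f, float) for f in fiber_dirs]
        self.grads, self.vol = tet_gradients(mesh.nodes, mesh.tets)
        self.density = density

        self.pressure_faces = self._oriented_boundary(pressure_tag) \
            if pressure_tag in mesh.surface_tags else None

        cons = DofConstraints(mesh.n_nodes)
        for tag in fixed_tags:
            if tag in mesh.surface_tags:
                cons.fix_nodes(mesh.surface_nodes(tag))
        for tag, normal in (roller_planes or {}).items():
            cons.roller(mesh.surface_nodes(tag), normal)
        self.T, self.free = cons.build()
        self.mass = np.repeat(lumped_mass(mesh.nodes, mesh.tets)
                              * self.density, 3)

    def _oriented_boundary(self, tag: str) -> np.ndarray:
        """Tagged facets reordered to the outward-from-solid orientation."""
        outward = {tuple(np.sort(f)): f for f in self.mesh.boundary_faces()}
        out = []
        for f in self.mesh.surface_tags[tag]:
            key = tuple(np.sort(f))
            if key not in outward:
                raise MeshError(f"tagged facet {key} is not on the boundary")
            out.append(outward[key])
        return np.array(out)

    # -- forces ------------------------------------------------------------

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        F = np.einsum("eai,eaj->eij", u[self.mesh.tets], self.grads)
        return F + np.eye(3)

    def internal_force(self, u: np.ndarray,
                       active_tensors: np.ndarray | None = None) -> np.ndarray:
        f_el = self._element_forces(u[self.mesh.tets], active_tensors)
        f = np.zeros((self.mesh.n_nodes, 3))
        np.add.at(f, self.mesh.tets.ravel(), f_el.reshape(-1, 3))
        return f

    def _element_forces(self, ue: np.ndarray,
                        active_tensors: np.ndarray | None) -> np.ndarray:
        """Per-element nodal internal forces, (E, 4, 3)."""
        F = np.einsum("eai,eaj->eij", ue, self.grads) + np.eye(3)
        S = pk2_stress_myocardium(F, self.material, self.fibers,
                                  active_tensor=active_tensors)
        P = np.einsum("eik,ekj->eij", F, S)
        return np.einsum("eij,eaj,e->eai", P, self.grads, self.vol)

    def external_force(self, u: np.ndarray, pressure_kpa: float) -> np.ndarray:
        """Follower cavity-pressure load on the deformed wetted surface."""
        f = np.zeros((self.mesh.n_nodes, 3))
        if self.pressure_faces is None or pressure_kpa == 0.0:
            return f
        y = (self.mesh.nodes + u)[self.pressure_faces]
        av = 0.5 * np.cross(y[:, 1] - y[:, 0], y[:, 2] - y[:, 0])
        contrib = (-pressure_kpa / 3.0) * av
        for a in range(3):
            np.add.at(f, self.pressure_faces[:, a], contrib)
        return f

    def residual(self, u, pressure_kpa=0.0, active_tensors=None):
        return self.internal_force(u, active_tensors) \
            - self.external_force(u, pressure_kpa)

    # -- tangent by vectorized differencing --------------------------------

    def tangent(self, u, pressure_kpa=0.0, active_tensors=None,
                h: float = 1e-6) -> sp.csr_matrix:
        tets = self.mesh.tets
        ue = u[tets]
        base = self._element_forces(ue, active_tensors)
        E = len(tets)
        Ke = np.empty((E, 12, 12))
        for a in range(4):
            for i in range(3):
                up = ue.copy()
                up[:, a, i] += h
                Ke[:, 3 * a + i, :] = \
                    ((self._element_forces(up, active_tensors) - base) / h
                     ).reshape(E, 12)
        Ke = np.transpose(Ke, (0, 2, 1))     # rows: force dof, cols: disp dof
        dof = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(E, 12)
        rows = np.repeat(dof, 12, axis=1).ravel()
        cols = np.tile(dof, (1, 12)).ravel()
        K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                          shape=(3 * self.mesh.n_nodes,) * 2).tocsr()
        if self.pressure_faces is not None and pressure_kpa != 0.0:
            K = K - self._pressure_tangent(u, pressure_kpa, h)
        return K

    def _pressure_tangent(self, u, pressure_kpa, h):
        faces = self.pressure_faces
        y0 = (self.mesh.nodes + u)[faces]

        def face_forces(y):
            av = 0.5 * np.cross(y[:, 1] - y[:, 0], y[:, 2] - y[:, 0])
            return np.repeat((-pressure_kpa / 3.0) * av[:, None, :], 3, axis=1)

        base = face_forces(y0)
        Fc = len(faces)
        Ke = np.empty((Fc, 9, 9))
        for a in range(3):
            for i in range(3):
                yp = y0.copy()
                yp[:, a, i] += h
                Ke[:, 3 * a + i, :] = ((face_forces(yp) - base) / h
                                       ).reshape(Fc, 9)
        Ke = np.transpose(Ke, (0, 2, 1))
        dof = (3 * faces[:, :, None] + np.arange(3)[None, None, :]).reshape(Fc, 9)
        rows = np.repeat(dof, 9, axis=1).ravel()
        cols = np.tile(dof, (1, 9)).ravel()
        return sp.coo_matrix((Ke.ravel(), (rows, cols)),
                             shape=(3 * self.mesh.n_nodes,) * 2).tocsr()

    # -- solvers -----------------------------------------------------------

    def _factorized_tangent(self, u, pressure_kpa, active_tensors):
        K = self.tangent(u, pressure_kpa, active_tensors)
        Kq = (self.T.T @ K @ self.T)[self.free][:, self.free]
        return spla.splu(Kq.tocsc())

    def _expand(self, dq):
        dfull = np.zeros(3 * self.mesh.n_nodes)
        dfull[self.free] = dq
        return (self.T @ dfull).reshape(-1, 3)

    def _reduced_solve(self, K, r):
        T = self.T
        Kq = (T.T @ K @ T)[self.free][:, self.free]
        rq = (T.T @ r.ravel())[self.free]
        return self._expand(spla.spsolve(Kq.tocsc(), -rq))

    def newton(self, u0, pressure_kpa=0.0, active_tensors=None,
               tol: float = 1e-6, max_iter: int = 40):
        """Newton iterations to ||R_free|| < tol * max(||f_ref||, 1).

        The tangent factorization is reused while the residual keeps
        contracting (modified Newton) and refreshed when it stalls.
        """
        u = u0.copy()
        ref = None
        solver = None
        fresh = False
        last_nr = np.inf
        for it in range(max_iter):
            try:
                r = self.residual(u, pressure_kpa, active_tensors)
            except MaterialError:
                return u, False
            rq = (self.T.T @ r.ravel())[self.free]
            nr = np.linalg.norm(rq)
            if ref is None:
                fint = self.internal_force(u, active_tensors)
                fext = self.external_force(u, pressure_kpa)
                ref = max(np.linalg.norm(fint), np.linalg.norm(fext), 1e-8)
            if nr < tol * ref or nr < 1e-12:
                return u, True
            if solver is None or (nr > 0.5 * last_nr and not fresh):
                solver = self._factorized_tangent(u, pressure_kpa,
                                                  active_tensors)
                fresh = True
            else:
                fresh = False
            du = self._expand(solver.solve(-rq))
            # backtracking line search on the residual norm; a step is
            # accepted only if the state is evaluable and the residual
            # does not blow up
            step, accepted = 1.0, None
            for _ in range(10):
                u_try = u + step * du
                try:
                    r_try = self.residual(u_try, pressure_kpa, active_tensors)
                except MaterialError:
                    step *= 0.5
                    continue
                nr_try = np.linalg.norm((self.T.T @ r_try.ravel())[self.free])
                if np.isfinite(nr_try) and (nr_try < nr * (1 - 1e-4 * step)
                                            or nr_try < tol * ref):
                    accepted = step
                    break
                if np.isfinite(nr_try) and accepted is None:
                    accepted = step          # fallback: evaluable state
                step *= 0.5
            if accepted is None:
                return u, False
            u = u + accepted * du
            last_nr = nr
        return u, False

    def solve_quasistatic(self, pressure_kpa=0.0, active_tensors=None,
                          u0=None, tol=1e-6, max_load_steps: int = 32
                          ) -> MechanicsState:
        """Equilibrium under pressure + active stress with adaptive load
        stepping (bisection cutback on Newton failure)."""
        u = np.zeros((self.mesh.n_nodes, 3)) if u0 is None else u0.copy()
        done, target = 0.0, 1.0
        step = 1.0
        n_steps = 0
        while done < target - 1e-12:
            lam = min(done + step, target)
            act = None if active_tensors is None else lam * active_tensors
            try:
                u_new, ok = self.newton(u, lam * pressure_kpa, act, tol=tol)
            except MaterialError:
                u_new, ok = u, False
            n_steps += 1
            if ok:
                u, done = u_new, lam
                step = min(2 * step, 1.0)
            else:
                step *= 0.5
                if n_steps > max_load_steps or step < 1e-4:
                    raise MechanicsError(
                        f"quasi-static solve diverged at load fraction {done}")
        return self.state_from_u(u)

    def state_from_u(self, u, v=None, a=None) -> MechanicsState:
        F = self.deformation_gradients(u)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise MechanicsError(
                f"element inversion (first at {int(np.argmin(J))})")
        S = pk2_stress_myocardium(F, self.material, self.fibers)
        vm = von_mises(cauchy_from_pk2(F, S))
        return MechanicsState(u=u, v=v, a=a, F=F, sigma_vm=vm,
                              volumetric_strain=J - 1.0)

    # -- dynamics: implicit Newmark ---------------------------------------

    def step_newmark(self, state: MechanicsState, dt: float,
                     pressure_kpa=0.0, active_tensors=None,
                     beta: float = 0.25, gamma: float = 0.5,
                     damping: float = 0.0, tol: float = 1e-8,
                     max_iter: int = 25) -> MechanicsState:
        """One implicit Newmark step (average acceleration by default).

        ``damping`` is a mass-proportional coefficient (1/ms).
        """
        n = self.mesh.n_nodes
        u0 = state.u
        v0 = state.v if state.v is not None else np.zeros((n, 3))
        a0 = state.a if state.a is not None else np.zeros((n, 3))
        m = self.mass.reshape(-1, 3)

        def kinematics(u):
            a_new = (u - u0 - dt * v0) / (beta * dt * dt) \
                - (0.5 - beta) / beta * a0
            v_new = v0 + dt * ((1 - gamma) * a0 + gamma * a_new)
            return v_new, a_new

        u = u0.copy()
        c_a = 1.0 / (beta * dt * dt)
        c_v = gamma / (beta * dt)
        ref = None
        for it in range(max_iter):
            v_new, a_new = kinematics(u)
            r = m * a_new + damping * m * v_new \
                + self.residual(u, pressure_kpa, active_tensors)
            rq = (self.T.T @ r.ravel())[self.free]
            nr = np.linalg.norm(rq)
            if ref is None:
                ref = max(np.linalg.norm(m * a_new), 1.0)
            if nr < tol * ref or nr < 1e-14:
                break
            K = self.tangent(u, pressure_kpa, active_tensors)
            K = K + sp.diags(self.mass * (c_a + damping * c_v))
            u = u + self._reduced_solve(K, r)
        else:
            raise MechanicsError("Newmark step failed to converge")
        v_new, a_new = kinematics(u)
        return self.state_from_u(u, v=v_new, a=a_new)


# ---------------------------------------------------------------------------
# kinematic outputs

@dataclass
class KinematicMetrics:
    apex_xy_trajectory: np.ndarray   # (T, 2) mm
    apex_z: np.ndarray               # (T,) mm (displacement, + toward apex)
    torsion_angle: np.ndarray        # (T,) deg, apical minus basal rotation
    max_strain: np.ndarray           # (T,) %, max principal Green-Lagrange


def _ring_rotation(nodes, u, ring, axis_z=2) -> float:
    """Mean circumferential rotation (deg) of a node ring about the z axis."""
    x = nodes[ring]
    y = x + u[ring]
    a0 = np.arctan2(x[:, 1], x[:, 0])
    a1 = np.arctan2(y[:, 1], y[:, 0])
    d = np.degrees(np.arctan2(np.sin(a1 - a0), np.cos(a1 - a0)))
    return float(d.mean())


def select_rings(mesh: VolumeMesh, r_min: float = 3.0,
                 band_frac: float = 0.02):
    """(apical, basal) node rings for the torsion metric: nodes at least
    ``r_min`` off the long axis, within a thin z band at each extreme."""
    r = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
    ok = r >= r_min
    z = mesh.nodes[:, 2]
    z_ok = z[ok]
    lo, hi = z_ok.min(), z_ok.max()
    band = band_frac * (hi - lo)
    apical = np.where(ok & (z >= hi - band))[0]
    basal = np.where(ok & (z <= lo + band))[0]
    if len(apical) == 0 or len(basal) == 0:
        raise MeshError("could not identify torsion reference rings")
    return apical, basal


def torsion_angle(mesh: VolumeMesh, u: np.ndarray, r_min: float = 3.0,
                  band_frac: float = 0.02) -> float:
    apical, basal = select_rings(mesh, r_min, band_frac)
    return _ring_rotation(mesh.nodes, u, apical) \
        - _ring_rotation(mesh.nodes, u, basal)


def max_principal_strain(F: np.ndarray) -> float:
    """Largest principal Green-Lagrange strain over elements, in percent."""
    C = np.einsum("...ki,...kj->...ij", F, F)
    E = 0.5 * (C - np.eye(3))
    ev = np.linalg.eigvalsh(E)
    return float(ev[..., -1].max()) * 100.0


def kinematic_metrics(mesh: VolumeMesh, states: list[MechanicsState],
                      r_min: float = 3.0, band_frac: float = 0.02
                      ) -> KinematicMetrics:
    """Apex trajectory, longitudinal shortening, torsion and peak strain
    from a sequence of displacement states on the same mesh."""
    apex_node = int(np.argmax(mesh.nodes[:, 2]))
    xy, zz, tors, strain = [], [], [], []
    for st in states:
        xy.append(st.u[apex_node, :2].copy())
        zz.append(st.u[apex_node, 2])
        tors.append(torsion_angle(mesh, st.u, r_min, band_frac))
        strain.append(max_principal_strain(st.F) if st.F is not None
                      else np.nan)
    return KinematicMetrics(apex_xy_trajectory=np.array(xy),
                            apex_z=np.array(zz),
                            torsion_angle=np.array(tors),
                            max_strain=np.array(strain))
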