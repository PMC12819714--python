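"""Rule-based myocardial fiber architecture.

Transmural coordinate beta (0 = epicardium, 1 = endocardium), helix angle
with a linear transmural and apicobasal variation (+/-60 degrees at the
basal endo/epicardium by default, 0 at the apex), and per-element
orthonormal fiber/sheet/sheet-normal triads.  The transmural direction
comes from a harmonic (Laplace) field with Dirichlet data on the tagged
surfaces; beta itself defaults to the Euclidean-distance ratio
D_epi / (D_epi + D_end), with the harmonic field available as an option.

A 1-cm-diameter cylinder about the long axis at the apex is flagged
isotropic (the rule-based construction is singular there).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from .fem import stiffness_matrix, tet_gradients, dirichlet_reduce, element_means
from .mesh import VolumeMesh, MeshError, point_triangle_distance

DEFAULT_THETA_EPI = -60.0   # deg, basal epicardium, relative to circumferential
DEFAULT_THETA_ENDO = 60.0   # deg, basal endocardium


class FiberError(ValueError):
    pass


@dataclass
class HarmonicField:
    U: np.ndarray        # nodal, 0 on epicardium .. 1 on endocardium
    e: np.ndarray        # per-element unit vector, -grad(U)/|grad(U)|


@dataclass
class FiberField:
    beta: np.ndarray             # per-element transmural coordinate
    theta: np.ndarray            # per-element helix angle, deg
    fiber: np.ndarray            # a-bar, per-element unit vector
    sheet: np.ndarray            # s-bar (transmural)
    sheet_normal: np.ndarray     # n-bar, completes right-handed triad
    isotropic_mask: np.ndarray   # True inside the apex cylinder

    def triads(self) -> np.ndarray:
        """(E, 3, 3) array with rows (fiber, sheet, sheet-normal)."""
        return np.stack([self.fiber, self.sheet, self.sheet_normal], axis=1)


def solve_transmural_laplace(mesh: VolumeMesh, epi_tag: str = "epicardium",
                             endo_tag: str = "endocardium") -> HarmonicField:
    """Discrete harmonic field: U=0 on the epicardium, U=1 on the
    endocardium, natural (zero-flux) elsewhere; e = -grad U normalized."""
    epi = mesh.surface_nodes(epi_tag)
    endo = mesh.surface_nodes(endo_tag)
    K = stiffness_matrix(mesh.nodes, mesh.tets, 1.0)
    fixed = np.concatenate([epi, endo])
    vals = np.concatenate([np.zeros(len(epi)), np.ones(len(endo))])
    Kff, ff, free = dirichlet_reduce(K, np.zeros(mesh.n_nodes), fixed, vals)
    U = np.zeros(mesh.n_nodes)
    U[fixed] = vals
    U[free] = spla.spsolve(Kff.tocsc(), ff)

    grads, _ = tet_gradients(mesh.nodes, mesh.tets)
    g = np.einsum("eai,ea->ei", grads, U[mesh.tets])
    norm = np.linalg.norm(g, axis=1)
    e = np.zeros_like(g)
    ok = norm > 1e-12
    e[ok] = -g[ok] / norm[ok, None]
    if np.any(~ok):
        e[~ok] = _neighbor_average(mesh, e, ~ok)
    return HarmonicField(U=U, e=e)


def transmural_beta(mesh: VolumeMesh, method: str = "distance",
                    harmonic: HarmonicField | None = None) -> np.ndarray:
    """Per-element transmural coordinate in [0, 1].

    ``distance``: beta = D_epi / (D_epi + D_end) with Euclidean distances
    from the element centroid to the tagged surfaces.  ``harmonic``: the
    element mean of the Laplace field (same Dirichlet anchors).
    """
    if method == "harmonic":
        if harmonic is None:
            harmonic = solve_transmural_laplace(mesh)
        return np.clip(element_means(harmonic.U, mesh.tets), 0.0, 1.0)
    if method != "distance":
        raise ValueError(f"unknown beta method {method!r}")
    cent = mesh.element_centroids()
    d_epi = point_triangle_distance(cent, mesh.nodes,
                                    mesh.surface_tags["epicardium"])
    d_end = point_triangle_distance(cent, mesh.nodes,
                                    mesh.surface_tags["endocardium"])
    return d_epi / (d_epi + d_end)


def beta_at_points(mesh: VolumeMesh, points: np.ndarray) -> np.ndarray:
    """Distance-ratio transmural coordinate at arbitrary points (mm).

    Exactly 0 on the epicardial surface and 1 on the endocardial surface.
    """
    points = np.atleast_2d(points)
    d_epi = point_triangle_distance(points, mesh.nodes,
                                    mesh.surface_tags["epicardium"])
    d_end = point_triangle_distance(points, mesh.nodes,
                                    mesh.surface_tags["endocardium"])
    return d_epi / (d_epi + d_end)


def helix_angles(beta: np.ndarray, z: np.ndarray, z_apex: float,
                 theta_epi_max: float = DEFAULT_THETA_EPI,
                 theta_endo_max: float = DEFAULT_THETA_ENDO) -> np.ndarray:
    """Helix angle (deg): linear transmural blend of the epicardial and
    endocardial profiles, each tapering linearly to zero at the apex."""
    z = np.asarray(z, float)
    if np.any(z < -1e-9) or np.any(z > z_apex + 1e-9):
        raise FiberError("Z coordinates outside [0, Z_LVapex]")
    taper = 1.0 - np.clip(z, 0.0, z_apex) / z_apex
    th_epi = theta_epi_max * taper
    th_end = theta_endo_max * taper
    return beta * th_end + (1.0 - beta) * th_epi


def build_triads(e: np.ndarray, theta_deg: np.ndarray,
                 z_axis=(0.0, 0.0, 1.0),
                 isotropic_mask: np.ndarray | None = None,
                 mesh: VolumeMesh | None = None,
                 beta: np.ndarray | None = None) -> FiberField:
    """Per-element orthonormal (fiber, sheet, sheet-normal) triads.

    Local frame: a1 = transmural (e), a2 = apicobasal projected into the
    wall, a3 = a1 x a2 (circumferential).  The fiber is a3 rotated by the
    helix angle about a1 toward a2 (right-hand rule about the outward
    transmural axis is the recorded sign convention); the sheet is
    transmural and the sheet-normal completes the right-handed triad.
    """
    e = np.asarray(e, float)
    z = np.broadcast_to(np.asarray(z_axis, float), e.shape)
    a1 = e / np.linalg.norm(e, axis=1, keepdims=True)
    a2 = z - np.einsum("ei,ei->e", z, a1)[:, None] * a1
    n2 = np.linalg.norm(a2, axis=1)
    bad = n2 < 1e-8
    if np.any(bad):
        if mesh is None:
            raise FiberError(
                f"{bad.sum()} elements have transmural axis parallel to the "
                "apicobasal axis and no mesh for a neighbor fallback")
        a2[bad] = _neighbor_average(mesh, np.where(bad[:, None], 0.0, a2), bad)
        n2 = np.linalg.norm(a2, axis=1)
        still = n2 < 1e-8
        a2[still] = _any_orthogonal(a1[still])
        n2 = np.linalg.norm(a2, axis=1)
    a2 = a2 / n2[:, None]
    a2 -= np.einsum("ei,ei->e", a2, a1)[:, None] * a1
    a2 /= np.linalg.norm(a2, axis=1, keepdims=True)
    a3 = np.cross(a1, a2)

    th = np.deg2rad(np.asarray(theta_deg, float))
    fiber = np.cos(th)[:, None] * a3 + np.sin(th)[:, None] * a2
    sheet = a1
    sheet_normal = np.cross(fiber, sheet)

    if isotropic_mask is None:
        if mesh is not None and "apex_cylinder" in mesh.region_tags:
            isotropic_mask = np.zeros(len(e), dtype=bool)
            isotropic_mask[mesh.region_tags["apex_cylinder"]] = True
        else:
            isotropic_mask = np.zeros(len(e), dtype=bool)
    return FiberField(beta=np.asarray(beta) if beta is not None
                      else np.full(len(e), np.nan),
                      theta=np.asarray(theta_deg, float), fiber=fiber,
                      sheet=sheet, sheet_normal=sheet_normal,
                      isotropic_mask=isotropic_mask)


def generate_fibers(mesh: VolumeMesh, beta_method: str = "distance",
                    theta_epi_max: float = DEFAULT_THETA_EPI,
                    theta_endo_max: float = DEFAULT_THETA_ENDO) -> FiberField:
    """Full pipeline: harmonic directions + distance beta + helix triads."""
    harm = solve_transmural_laplace(mesh)
    beta = transmural_beta(mesh, beta_method, harmonic=harm)
    cent = mesh.element_centroids()
    z_apex = float(mesh.nodes[:, 2].max())
    theta = helix_angles(beta, np.clip(cent[:, 2], 0.0, None), z_apex,
                         theta_epi_max, theta_endo_max)
    return build_triads(harm.e, theta, mesh=mesh, beta=beta)


def _neighbor_average(mesh: VolumeMesh, field: np.ndarray,
                      mask: np.ndarray) -> np.ndarray:
    """Average of node-sharing neighbor elements, for degenerate fallbacks."""
    out = np.zeros((mask.sum(), field.shape[1]))
    bad_ids = np.where(mask)[0]
    node_sets = [set(mesh.tets[i]) for i in bad_ids]
    good = np.where(~mask)[0]
    for k, (i, ns) in enumerate(zip(bad_ids, node_sets)):
        share = [j for j in good if ns & set(mesh.tets[j])]
        if share:
            v = field[share].mean(axis=0)
            out[k] = v
    return out


def _any_orthogonal(a: np.ndarray) -> np.ndarray:
    trial = np.tile(np.array([1.0, 0.0, 0.0]), (len(a), 1))
    near = np.abs(a[:, 0]) > 0.9
    trial[near] = [0.0, 1.0, 0.0]
    v = trial - np.einsum("ei,ei->e", trial, a)[:, None] * a
    return v / np.linalg.norm(v, axis=1, keepdims=True)
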