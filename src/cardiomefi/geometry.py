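"""Parameterized left-ventricle (and aortic-root) geometry.

The LV wall is generated from elliptical cross-sections stacked along the
long axis: the endocardium is a smooth surface through the section
ellipses, closed with an ellipsoidal apex cap; the epicardium is offset
from it by a circumferentially varying wall-thickness map.  The base plane
sits at Z = 0 with the apex at Z = Z_LVapex > 0, all lengths in mm.

Each Table-like case card fixes the printed clinical dimensions (EDV,
long-axis length, internal diameter, wall-thickness extremes); an outer
calibration loop rescales the endocardial semi-axes (long axis fixed)
until the meshed cavity volume matches the target EDV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .mesh import VolumeMesh, cavity_volume
from .shapes import mesh_from_grid

__all__ = [
    "LVCaseSpec", "EllipseSection", "MeshResolution", "LeafletSpec",
    "SurfaceMesh", "CASES", "build_lv_geometry", "wall_thickness_map",
    "build_aortic_root", "long_axis_length", "cavity_volume",
]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class LVCaseSpec:
    """Printed geometric/clinical parameters of one LV case.

    ``thickness_spec`` is (WTmax, WTmin, WTavg) in mm; volumes in mL,
    lengths in mm, tilt in degrees.
    """
    case_id: int
    edv: float                      # mL
    long_axis: float                # mm, apex-to-base
    lvid: float                     # mm, internal diameter
    thickness_spec: tuple           # (WTmax, WTmin, WTavg) mm
    sv: float | None = None         # mL, stroke volume (reported)
    lvot_radius: float = 10.0       # mm
    lvot_tilt: float = 0.0          # deg
    n_levels: int = 9
    aspect_ratio: float = 0.9       # minor/major endocardial semi-axis

    def validate(self) -> None:
        wtmax, wtmin, wtavg = self.thickness_spec
        problems = []
        if self.edv <= 0:
            problems.append("edv must be positive")
        if self.long_axis <= 0:
            problems.append("long_axis must be positive")
        if min(self.thickness_spec) <= 0:
            problems.append("thickness targets must be positive")
        if not (wtmin <= wtavg <= wtmax):
            problems.append("need WTmin <= WTavg <= WTmax")
        if self.n_levels < 3:
            problems.append("n_levels must be >= 3")
        if self.long_axis <= wtavg:
            problems.append("long axis shorter than apex wall thickness")
        if problems:
            raise GeometryError("; ".join(problems))


@dataclass(frozen=True)
class EllipseSection:
    """One elliptical cross-section of the wall at centerline parameter s."""
    s: float
    center: tuple                   # (xc, yc) mm
    a_endo: float
    b_endo: float
    a_epi: float
    b_epi: float

    def validate(self) -> None:
        if not (self.a_epi > self.a_endo > 0 and self.b_epi > self.b_endo > 0):
            raise GeometryError(
                f"section s={self.s}: need a_epi > a_endo > 0, b_epi > b_endo > 0")


@dataclass(frozen=True)
class MeshResolution:
    """Structured mesh density: circumferential x meridional x transmural."""
    n_theta: int = 16
    n_axial: int = 12
    n_layers: int = 2
    n_lvot: int = 3

    def refined(self, factor: int = 2) -> "MeshResolution":
        return MeshResolution(self.n_theta * factor, self.n_axial * factor,
                              self.n_layers * factor, self.n_lvot)


RESOLUTIONS = {
    "tiny": MeshResolution(12, 8, 2),
    "coarse": MeshResolution(16, 12, 2),
    "medium": MeshResolution(24, 18, 3),
    "fine": MeshResolution(36, 26, 4),
}

#: printed case cards: EDV (mL), long axis (mm), LVID (mm),
#: (WTmax, WTmin, WTavg) (mm), SV (mL).  LVOT radius/tilt are not printed;
#: the defaults are a single documented choice (tilted outflow in case 4).
CASES = {
    1: LVCaseSpec(1, 117.3, 74.2, 54.4, (8.4, 3.3, 6.2), sv=81.1),
    2: LVCaseSpec(2, 122.5, 74.8, 54.4, (12.1, 4.8, 9.3), sv=86.5),
    3: LVCaseSpec(3, 83.2, 77.9, 50.0, (11.7, 4.5, 9.1), sv=51.5,
                  lvot_radius=8.0),
    4: LVCaseSpec(4, 117.5, 84.6, 54.4, (8.6, 3.4, 6.7), sv=72.1,
                  lvot_tilt=10.0),
    5: LVCaseSpec(5, 157.5, 86.1, 62.4, (8.8, 4.0, 6.5), sv=94.4),
}


# ---------------------------------------------------------------------------
# thickness map and section profiles

def thickness_fourier(thickness_spec) -> tuple[float, float, float]:
    """Coefficients (c0, c1, c2) of t(theta) = c0 + c1 cos(theta) + c2 cos(2 theta).

    Chosen so the circumferential mean equals WTavg exactly while the
    extremes at theta = 0 / pi equal WTmax / WTmin.
    """
    wtmax, wtmin, wtavg = thickness_spec
    c0 = wtavg
    c1 = 0.5 * (wtmax - wtmin)
    c2 = 0.5 * (wtmax + wtmin) - wtavg
    return c0, c1, c2


def thickness_of_theta(theta: np.ndarray, thickness_spec) -> np.ndarray:
    c0, c1, c2 = thickness_fourier(thickness_spec)
    return c0 + c1 * np.cos(theta) + c2 * np.cos(2 * theta)


def sections_from_profile(spec: LVCaseSpec, scale: float = 1.0):
    """The n_levels printed-style ellipse sections implied by a case card."""
    wt = spec.thickness_spec
    t_major = thickness_of_theta(np.array(0.0), wt)
    t_minor = thickness_of_theta(np.array(np.pi / 2), wt)
    a0 = scale * spec.lvid / 2.0
    b0 = spec.aspect_ratio * a0
    out = []
    for s in np.linspace(0.0, 0.9, spec.n_levels):
        shape = np.sqrt(max(1.0 - s ** 2, 0.0))
        a, b = a0 * shape, b0 * shape
        sec = EllipseSection(s=float(s), center=(0.0, 0.0), a_endo=a,
                             b_endo=b, a_epi=a + float(t_major),
                             b_epi=b + float(t_minor))
        sec.validate()
        out.append(sec)
    return out


# ---------------------------------------------------------------------------
# LV wall mesh

def _endo_point_and_normal(psi, theta, shape_a, shape_b, lc):
    """Endocardial surface point and outward (into-wall) unit normal.

    Parameterization x = A(psi) cos(psi) cos(theta), z = lc sin(psi); the
    normal comes from the parametric tangents, with the apex pole handled
    analytically (normal = +z).
    """
    A = shape_a(psi)
    B = shape_b(psi)
    cp, sp = np.cos(psi), np.sin(psi)
    ct, st = np.cos(theta), np.sin(theta)
    P = np.stack([A * cp * ct, B * cp * st, lc * sp], axis=-1)

    h = 1e-5
    Ap, Bp = (shape_a(psi + h) - shape_a(psi - h)) / (2 * h), \
             (shape_b(psi + h) - shape_b(psi - h)) / (2 * h)
    d_psi = np.stack([(Ap * cp - A * sp) * ct,
                      (Bp * cp - B * sp) * st,
                      lc * cp * np.ones_like(ct)], axis=-1)
    d_theta = np.stack([-A * cp * st, B * cp * ct, np.zeros_like(ct)], axis=-1)
    n = np.cross(d_theta, d_psi)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    pole = nn[..., 0] < 1e-12
    n = np.where(pole[..., None], np.array([0.0, 0.0, 1.0]), n / np.maximum(nn, 1e-30))
    # orient outward from the cavity (positive radial / +z component)
    sign = np.sign(np.einsum("...i,...i->...", n, P - np.array([0, 0, 0.0])))
    sign = np.where(sign == 0, 1.0, sign)
    return P, n * sign[..., None]


def _build_wall_nodes(spec: LVCaseSpec, res: MeshResolution, scale: float,
                      include_lvot: bool):
    """Node grid of the wall: axial rows x theta x transmural layers."""
    wt = spec.thickness_spec
    t_apex = wt[2]
    lc = spec.long_axis - t_apex
    secs = sections_from_profile(spec, scale)
    s_vals = np.array([s.s for s in secs])
    psi_secs = np.arcsin(s_vals)
    # shape functions A(psi), B(psi): equatorial-equivalent semi-axes
    A_vals = np.array([s.a_endo for s in secs]) / np.cos(psi_secs)
    B_vals = np.array([s.b_endo for s in secs]) / np.cos(psi_secs)
    shape_a = PchipInterpolator(psi_secs, A_vals, extrapolate=False)
    shape_b = PchipInterpolator(psi_secs, B_vals, extrapolate=False)
    a_end, b_end = A_vals[-1], B_vals[-1]

    def sa(p):
        p = np.asarray(p, float)
        return np.where(p <= psi_secs[-1],
                        np.nan_to_num(shape_a(np.clip(p, 0, psi_secs[-1]))),
                        a_end)

    def sb(p):
        p = np.asarray(p, float)
        return np.where(p <= psi_secs[-1],
                        np.nan_to_num(shape_b(np.clip(p, 0, psi_secs[-1]))),
                        b_end)

    ntheta, nax, nr = res.n_theta, res.n_axial, res.n_layers
    theta = np.linspace(0, 2 * np.pi, ntheta + 1)[:-1]
    psi = np.arcsin(np.linspace(0.0, 1.0, nax + 1))[:-1]   # pole row separate
    t_th = thickness_of_theta(theta, wt)

    PSI, TH = np.meshgrid(psi, theta, indexing="ij")
    P, N = _endo_point_and_normal(PSI, TH, sa, sb, lc)

    # near-apex offset direction is blended toward "radial from the
    # osculating centre" to keep the offset surface fold-free when the
    # wall is thick relative to the apex curvature radius
    r_m = min(a_end, b_end) ** 2 / lc                 # meridian curvature radius
    C = np.array([0.0, 0.0, lc - r_m])
    w = np.clip((PSI - np.deg2rad(55)) / np.deg2rad(35), 0.0, 1.0) ** 2
    radial = P - C
    radial /= np.linalg.norm(radial, axis=-1, keepdims=True)
    D = (1 - w)[..., None] * N + w[..., None] * radial
    D /= np.linalg.norm(D, axis=-1, keepdims=True)

    layers = np.linspace(0.0, 1.0, nr + 1)
    rows = P[:, :, None, :] + layers[None, None, :, None] * \
        t_th[None, :, None, None] * D[:, :, None, :]   # (nax, ntheta, nr+1, 3)

    pole = np.array([0.0, 0.0, lc])[None, :] + \
        layers[:, None] * t_apex * np.array([0.0, 0.0, 1.0])[None, :]

    lvot_rows = None
    if include_lvot:
        h = 0.18 * spec.long_axis
        zeta = np.linspace(1.0, 0.0, res.n_lvot + 1)[:-1]  # outlet -> base
        blend = 3 * zeta ** 2 - 2 * zeta ** 3
        a0, b0 = float(sa(0.0)), float(sb(0.0))
        tilt = np.deg2rad(spec.lvot_tilt)
        lvot_rows = np.empty((len(zeta), ntheta, nr + 1, 3))
        for i, (zt, bl) in enumerate(zip(zeta, blend)):
            a = (1 - bl) * a0 + bl * spec.lvot_radius
            b = (1 - bl) * b0 + bl * spec.lvot_radius
            xc = bl * h * np.tan(tilt)
            ring = np.stack([xc + a * np.cos(theta), b * np.sin(theta),
                             np.full_like(theta, -zt * h)], axis=-1)
            nrm = np.stack([np.cos(theta), np.sin(theta),
                            np.zeros_like(theta)], axis=-1)
            lvot_rows[i] = ring[:, None, :] + \
                layers[None, :, None] * t_th[:, None, None] * nrm[:, None, :]
    return rows, pole, lvot_rows


def build_lv_geometry(spec: LVCaseSpec, resolution="coarse",
                      include_lvot: bool = False,
                      volume_tol: float = 0.002,
                      max_calibration_iters: int = 30) -> VolumeMesh:
    """Build a tagged tetrahedral LV wall mesh matching the case card.

    The endocardial semi-axes are uniformly rescaled (long axis fixed)
    until the meshed cavity volume matches ``spec.edv`` within
    ``volume_tol`` (default 0.2%, well inside the 1% contract).
    """
    spec.validate()
    res = RESOLUTIONS[resolution] if isinstance(resolution, str) else resolution

    scale = 1.0
    mesh = None
    for _ in range(max_calibration_iters):
        mesh = _assemble_lv_mesh(spec, res, scale, include_lvot)
        v = cavity_volume(mesh)
        if abs(v - spec.edv) / spec.edv < volume_tol:
            mesh.validate()
            return mesh
        scale *= np.sqrt(spec.edv / v)
    raise GeometryError(
        f"EDV calibration did not converge within {max_calibration_iters} "
        f"iterations (last volume {v:.2f} mL vs target {spec.edv} mL)")


def _assemble_lv_mesh(spec, res, scale, include_lvot) -> VolumeMesh:
    rows, pole, lvot_rows = _build_wall_nodes(spec, res, scale, include_lvot)
    nax, ntheta, nlay = rows.shape[0], rows.shape[1], rows.shape[2]

    blocks = [rows.reshape(-1, 3)]
    if lvot_rows is not None:
        blocks.insert(0, lvot_rows.reshape(-1, 3))
    blocks.append(pole)
    nodes = np.concatenate(blocks)

    n_lvot = 0 if lvot_rows is None else lvot_rows.shape[0]
    off_wall = n_lvot * ntheta * nlay
    off_pole = off_wall + nax * ntheta * nlay

    grid = np.empty((n_lvot + nax + 1, ntheta + 1, nlay), dtype=int)
    if n_lvot:
        ids = np.arange(off_wall).reshape(n_lvot, ntheta, nlay)
        grid[:n_lvot, :-1] = ids
    ids = off_wall + np.arange(nax * ntheta * nlay).reshape(nax, ntheta, nlay)
    grid[n_lvot:-1, :-1] = ids
    grid[-1, :-1] = off_pole + np.arange(nlay)[None, :]
    grid[:, -1] = grid[:, 0]                                   # theta wrap

    top_tag = "lvot_outlet" if include_lvot else "base"
    mesh = mesh_from_grid(
        nodes, grid,
        {"endocardium": (2, 0), "epicardium": (2, 1), top_tag: (0, 0)},
        wrap_axis=1)

    # apex region: elements intersecting the 1-cm-diameter cylinder about
    # the long axis (any vertex within radius 5 mm)
    r_nodes = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
    apex_mask = (r_nodes[mesh.tets] <= 5.0).any(axis=1)
    mesh.region_tags["apex_cylinder"] = np.where(apex_mask)[0]
    mesh.region_tags["bulk"] = np.where(~apex_mask)[0]
    return mesh


def long_axis_length(mesh: VolumeMesh, base_tag: str | None = None) -> float:
    """Euclidean apex-to-base distance: apex node to basal-plane centroid."""
    if base_tag is None:
        base_tag = "base" if "base" in mesh.surface_tags else "lvot_outlet"
    base_nodes = mesh.nodes[mesh.surface_nodes(base_tag)]
    apex = mesh.nodes[np.argmax(mesh.nodes[:, 2])]
    return float(np.linalg.norm(apex - base_nodes.mean(axis=0)))


# ---------------------------------------------------------------------------
# wall thickness measurement (normal-ray projection)

def wall_thickness_map(endo, epi, mesh: VolumeMesh | None = None):
    """Wall thickness t = (X_epi - X_endo) . n_endo per endocardial facet.

    ``endo``/``epi`` are (nodes, faces) triangulated surfaces (pass
    ``mesh.nodes`` with the tagged facet arrays).  A ray is cast from each
    endocardial facet centroid along its outward normal onto the epicardial
    surface; the hit distance is the thickness.  Strictly positive by
    contract; crossing surfaces are rejected.

    Returns (thickness array, sample centroids).
    """
    endo_nodes, endo_faces = endo
    epi_nodes, epi_faces = epi
    x = endo_nodes[endo_faces]
    centers = x.mean(axis=1)
    normals = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    # orient the endocardial normals outward, away from the enclosed
    # cavity side (centroid heuristic; facet winding is not assumed), so
    # that a crossing / inside-out surface pair fails to project
    centroid = endo_nodes[np.unique(endo_faces)].mean(axis=0)
    sign = np.sign(np.einsum("ij,ij->i", normals, centers - centroid))
    normals *= np.where(sign == 0, 1.0, sign)[:, None]
    t = _ray_cast(centers, normals, epi_nodes, epi_faces)
    miss = ~np.isfinite(t)
    if np.any(miss):
        raise GeometryError(
            f"outward normal ray missed the epicardial surface for "
            f"{int(miss.sum())} of {len(t)} samples: surfaces cross or the "
            "epicardium does not lie outside the endocardium")
    if np.any(t <= 0):
        raise GeometryError("non-positive wall thickness: surfaces cross")
    return t, centers


def wall_thickness_of_mesh(mesh: VolumeMesh):
    """Thickness samples for a generated LV mesh (uses its surface tags)."""
    endo = (mesh.nodes, mesh.surface_tags["endocardium"])
    epi = (mesh.nodes, mesh.surface_tags["epicardium"])
    return wall_thickness_map(endo, epi, mesh)


def _ray_cast(origins, directions, nodes, faces, chunk=512) -> np.ndarray:
    """Smallest positive hit distance per ray (Moller-Trumbore), inf if none."""
    v0 = nodes[faces[:, 0]]
    e1 = nodes[faces[:, 1]] - v0
    e2 = nodes[faces[:, 2]] - v0
    out = np.full(len(origins), np.inf)
    for lo in range(0, len(origins), chunk):
        o = origins[lo:lo + chunk]
        d = directions[lo:lo + chunk]
        h = np.cross(d[:, None, :], e2[None, :, :])
        a = np.einsum("tj,ptj->pt", e1, h)
        near_par = np.abs(a) < 1e-12
        a = np.where(near_par, 1.0, a)
        s = o[:, None, :] - v0[None, :, :]
        u = np.einsum("ptj,ptj->pt", s, h) / a
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("pj,ptj->pt", d, q) / a
        t = np.einsum("tj,ptj->pt", e2, q) / a
        eps = 1e-9
        ok = (~near_par) & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) \
            & (t > 1e-9)
        t = np.where(ok, t, np.inf)
        out[lo:lo + chunk] = t.min(axis=1)
    return out


# ---------------------------------------------------------------------------
# aortic root and leaflets (surface construction only)

@dataclass(frozen=True)
class LeafletSpec:
    """Parametric aortic leaflet: root radius R, height H, log-guide shape
    parameters a (belly sag fraction) and k (log-curve steepness)."""
    R: float = 12.5                 # mm
    H: float = 14.0                 # mm
    a: float = 0.2
    k: float = 2.0
    coapt_fraction: float = 0.8     # free-edge centre height / H

    def validate(self) -> None:
        problems = []
        if self.R <= 0 or self.H <= 0:
            problems.append("R and H must be positive")
        if self.k <= -1 or self.k == 0:
            problems.append("k must be > -1 and nonzero")
        if not 0 <= self.a <= 0.6:
            problems.append("belly sag a outside the fold-free range [0, 0.6]")
        if problems:
            raise GeometryError("; ".join(problems))


@dataclass
class SurfaceMesh:
    nodes: np.ndarray
    faces: np.ndarray


def _log_guide(v: np.ndarray, k: float) -> np.ndarray:
    """z(rho) = ln(1 + k rho) / ln(1 + k): monotone 0 -> 1 guide curve."""
    return np.log1p(k * v) / np.log1p(k)


def build_aortic_root(spec: LeafletSpec, n_u: int = 24, n_v: int = 16
                      ) -> dict[str, SurfaceMesh]:
    """Three congruent leaflet surfaces (120-degree sectors) + root wall.

    The attachment curve lies exactly on the radius-R root cylinder with
    commissures at z = H and belly at z = 0; the surface sweeps from the
    attachment to the free edge following the logarithmic guide curve,
    with belly sag controlled by the shape factor ``a``.
    """
    spec.validate()
    u = np.linspace(0.0, 1.0, n_u + 1)
    v = np.linspace(0.0, 1.0, n_v + 1)
    U, V = np.meshgrid(u, v, indexing="ij")
    phi = (U - 0.5) * (2 * np.pi / 3)

    attach = np.stack([spec.R * np.cos(phi), spec.R * np.sin(phi),
                       spec.H * (2 * U - 1) ** 2], axis=-1)
    centre = np.array([0.0, 0.0, spec.coapt_fraction * spec.H])
    comm = np.stack([spec.R * np.cos(np.where(U < 0.5, -np.pi / 3, np.pi / 3)),
                     spec.R * np.sin(np.where(U < 0.5, -np.pi / 3, np.pi / 3)),
                     np.full_like(U, spec.H)], axis=-1)
    m = np.abs(2 * U - 1)[..., None]
    free_edge = m * comm + (1 - m) * centre

    g = _log_guide(V, spec.k)[..., None]
    P = attach + g * (free_edge - attach)
    P[..., 2] -= spec.a * spec.H * np.sin(np.pi * V) * np.sin(np.pi * U)

    nodes = P.reshape(-1, 3)
    faces = _quad_grid_faces(n_u + 1, n_v + 1)
    leaf1 = SurfaceMesh(nodes, faces)
    _check_leaflet(leaf1, spec)

    out = {"leaflet_1": leaf1}
    for i, ang in enumerate((2 * np.pi / 3, 4 * np.pi / 3), start=2):
        Rz = np.array([[np.cos(ang), -np.sin(ang), 0],
                       [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        out[f"leaflet_{i}"] = SurfaceMesh(nodes @ Rz.T, faces.copy())

    nth, nz = 48, 8
    th = np.linspace(0, 2 * np.pi, nth + 1)[:-1]
    zz = np.linspace(-0.3 * spec.H, 1.2 * spec.H, nz + 1)
    TH, ZZ = np.meshgrid(np.append(th, th[0]), zz, indexing="ij")
    wall_nodes = np.stack([spec.R * np.cos(TH), spec.R * np.sin(TH), ZZ],
                          axis=-1).reshape(-1, 3)
    out["root_wall"] = SurfaceMesh(wall_nodes, _quad_grid_faces(nth + 1, nz + 1))
    return out


def _quad_grid_faces(n0: int, n1: int) -> np.ndarray:
    idx = np.arange(n0 * n1).reshape(n0, n1)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    return np.concatenate([np.stack([a, b, c], 1), np.stack([a, c, d], 1)])


def _check_leaflet(leaf: SurfaceMesh, spec: LeafletSpec) -> None:
    phi = np.arctan2(leaf.nodes[:, 1], leaf.nodes[:, 0])
    interior = np.hypot(leaf.nodes[:, 0], leaf.nodes[:, 1]) > 1e-9
    if np.any(np.abs(phi[interior]) > np.pi / 3 + 1e-6):
        raise GeometryError("leaflet escapes its 120-degree sector "
                            "(self-intersecting configuration)")
    if leaf.nodes[:, 2].min() < -0.75 * spec.H:
        raise GeometryError("leaflet belly sags below the root "
                            "(self-intersecting configuration)")


def free_edge_arc_length(leaf: SurfaceMesh, n_u: int = 24, n_v: int = 16) -> float:
    P = leaf.nodes.reshape(n_u + 1, n_v + 1, 3)
    edge = P[:, -1, :]
    return float(np.linalg.norm(np.diff(edge, axis=0), axis=1).sum())
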