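"""LV geometry generation: printed case dimensions, thickness maps,
cavity volumes, refinement behaviour, and the parametric aortic root."""

import numpy as np
import pytest

from cardiomefi.geometry import (CASES, LVCaseSpec, LeafletSpec,
                                 MeshResolution, build_aortic_root,
                                 build_lv_geometry, free_edge_arc_length,
                                 long_axis_length, thickness_of_theta,
                                 wall_thickness_map, wall_thickness_of_mesh,
                                 GeometryError)
from cardiomefi.mesh import cavity_volume, enclosed_volume_mm3
from cardiomefi.shapes import make_annulus_mesh, make_box_mesh


# ---------------------------------------------------------------------------
# cavity volume primitive

def test_unit_cube_volume_is_a_microliter():
    m = make_box_mesh((1.0, 1.0, 1.0), (2, 2, 2))
    vol = enclosed_volume_mm3(m.nodes, m.boundary_faces()) / 1000.0
    assert vol == pytest.approx(0.001, rel=1e-12)


def test_hemisphere_volume_matches_analytic():
    # hemisphere r=10 closed by the equatorial disk: (2/3) pi 1000 mm^3
    n_t, n_p = 96, 48
    th = np.linspace(0, 2 * np.pi, n_t + 1)[:-1]
    ph = np.linspace(0, np.pi / 2, n_p + 1)
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    r = 10.0
    pts = np.stack([r * np.cos(TH) * np.cos(PH), r * np.sin(TH) * np.cos(PH),
                    r * np.sin(PH)], axis=-1)
    # collapse the pole ring and fan the equator to the origin
    nodes = [pts[:, :-1].reshape(-1, 3), np.array([[0, 0, r], [0, 0, 0.0]])]
    nodes = np.concatenate(nodes)
    pole, center = len(nodes) - 2, len(nodes) - 1
    idx = np.arange(n_t * n_p).reshape(n_t, n_p)
    faces = []
    for i in range(n_t):
        j = (i + 1) % n_t
        for k in range(n_p - 1):
            faces += [[idx[i, k], idx[j, k], idx[j, k + 1]],
                      [idx[i, k], idx[j, k + 1], idx[i, k + 1]]]
        faces += [[idx[i, n_p - 1], idx[j, n_p - 1], pole],
                  [idx[j, 0], idx[i, 0], center]]
    vol = enclosed_volume_mm3(nodes, np.array(faces)) / 1000.0
    assert vol == pytest.approx(2 / 3 * np.pi, rel=2e-3)


# ---------------------------------------------------------------------------
# case builds

@pytest.mark.parametrize("cid", [1, 2, 3, 4, 5])
def test_case_builds_match_printed_dimensions(cid):
    spec = CASES[cid]
    mesh = build_lv_geometry(spec, "coarse")
    mesh.validate()
    assert cavity_volume(mesh) == pytest.approx(spec.edv, rel=0.01)
    assert long_axis_length(mesh) == pytest.approx(spec.long_axis, rel=0.005)


@pytest.mark.parametrize("cid", [1, 2, 3, 4, 5])
def test_thickness_map_within_printed_bounds(cid):
    wtmax, wtmin, wtavg = CASES[cid].thickness_spec
    mesh = build_lv_geometry(CASES[cid], "coarse")
    t, _ = wall_thickness_of_mesh(mesh)
    assert t.min() >= wtmin * 0.9
    assert t.max() <= wtmax * 1.1
    assert t.min() > 0


def test_case2_mean_thickness_matches_printed_average():
    mesh = build_lv_geometry(CASES[2], "coarse")
    t, _ = wall_thickness_of_mesh(mesh)
    assert t.mean() == pytest.approx(9.3, rel=0.05)


def test_cavity_volume_agrees_with_voxel_count():
    """Divergence-theorem volume vs a voxelized inside/outside count on the
    same closed triangulated endocardial surface."""
    from cardiomefi.mesh import close_surface_with_cap
    mesh = build_lv_geometry(CASES[1], "coarse")
    nodes, faces = close_surface_with_cap(
        mesh.nodes, mesh.surface_tags["endocardium"])
    v_div = enclosed_volume_mm3(nodes, faces)

    lo = nodes.min(axis=0) - 1.0
    hi = nodes.max(axis=0) + 1.0
    h = 1.2
    grids = [np.arange(a + h / 2, b, h) for a, b in zip(lo, hi)]
    X, Y, Z = np.meshgrid(*grids, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    inside = _inside_by_ray_parity(pts, nodes, faces)
    v_mc = inside.sum() * h ** 3
    assert v_mc == pytest.approx(v_div, rel=0.005)


def _inside_by_ray_parity(pts, nodes, faces, chunk=2000):
    rng = np.random.default_rng(7)
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    v0 = nodes[faces[:, 0]]
    e1 = nodes[faces[:, 1]] - v0
    e2 = nodes[faces[:, 2]] - v0
    h = np.cross(d, e2)
    a = np.einsum("tj,tj->t", e1, h)
    ok_t = np.abs(a) > 1e-12
    inside = np.zeros(len(pts), dtype=bool)
    for lo_i in range(0, len(pts), chunk):
        p = pts[lo_i:lo_i + chunk]
        s = p[:, None, :] - v0[None, :, :]
        u = np.einsum("ptj,tj->pt", s, h) / a
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("ptj,j->pt", q, d) / a
        t = np.einsum("ptj,tj->pt", q, e2) / a
        hit = ok_t & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
        inside[lo_i:lo_i + chunk] = hit.sum(axis=1) % 2 == 1
    return inside


def test_refinement_converges_monotonically():
    vols = []
    for res in (MeshResolution(8, 6, 1), MeshResolution(16, 12, 2),
                MeshResolution(32, 24, 4)):
        mesh = build_lv_geometry(CASES[1], res, volume_tol=1e9)  # no recal
        vols.append(cavity_volume(mesh))
    d1, d2 = abs(vols[1] - vols[0]), abs(vols[2] - vols[1])
    assert d2 < d1


def test_infeasible_case_is_rejected():
    bad = LVCaseSpec(1, edv=-5.0, long_axis=74.2, lvid=54.4,
                     thickness_spec=(8.4, 3.3, 6.2))
    with pytest.raises(GeometryError):
        build_lv_geometry(bad)
    with pytest.raises(GeometryError):
        LVCaseSpec(1, 117.3, 74.2, 54.4, (3.3, 8.4, 6.2)).validate()


# ---------------------------------------------------------------------------
# wall thickness measurement

def test_concentric_circles_give_constant_thickness():
    m = make_annulus_mesh(20.0, 27.0, 6.0, nr=3, ntheta=64, nz=3)
    t, _ = wall_thickness_map((m.nodes, m.surface_tags["endocardium"]),
                              (m.nodes, m.surface_tags["epicardium"]))
    assert t == pytest.approx(7.0, rel=0.01)


def test_coaxial_ellipse_thickness_matches_ray_oracle():
    """Extruded coaxial ellipses endo (20,15) / epi (26,21): the measured
    thickness must match a dense independent 2D normal-ray oracle."""
    def ellipse_surface(a, b, n=256, H=4.0, nz=4):
        th = np.linspace(0, 2 * np.pi, n + 1)[:-1]
        zs = np.linspace(0, H, nz + 1)
        nodes = np.array([[a * np.cos(t), b * np.sin(t), z]
                          for z in zs for t in th])
        faces = []
        for k in range(nz):
            for i in range(n):
                j = (i + 1) % n
                o0, o1 = k * n, (k + 1) * n
                faces += [[o0 + i, o0 + j, o1 + j], [o0 + i, o1 + j, o1 + i]]
        return nodes, np.array(faces)

    endo = ellipse_surface(20.0, 15.0)
    epi = ellipse_surface(26.0, 21.0)
    t, centers = wall_thickness_map(endo, epi)

    # 2D oracle: walk along the outward ellipse normal until hitting the
    # outer ellipse (dense sampling + root bracketing)
    ang = np.arctan2(centers[:, 1] / 15.0, centers[:, 0] / 20.0)
    t_ref = np.empty_like(t)
    for i, th in enumerate(ang):
        p = np.array([20.0 * np.cos(th), 15.0 * np.sin(th)])
        nvec = np.array([np.cos(th) / 20.0, np.sin(th) / 15.0])
        nvec /= np.linalg.norm(nvec)
        ss = np.linspace(0.0, 15.0, 4000)
        q = p[None, :] + ss[:, None] * nvec[None, :]
        f = (q[:, 0] / 26.0) ** 2 + (q[:, 1] / 21.0) ** 2 - 1.0
        t_ref[i] = ss[np.argmin(np.abs(f))]
    assert np.max(np.abs(t - t_ref)) < 0.05

    # on the major axis the gap is 26 - 20 = 6 mm
    major = np.abs(np.cos(ang)) > 0.999
    assert t[major] == pytest.approx(6.0, abs=0.02)


def test_crossing_surfaces_rejected():
    m = make_annulus_mesh(20.0, 27.0, 6.0, nr=3, ntheta=32, nz=2)
    with pytest.raises(GeometryError):
        # swapped surfaces: the "epi" lies inside, normal projection fails
        wall_thickness_map((m.nodes, m.surface_tags["epicardium"]),
                           (m.nodes, m.surface_tags["endocardium"]))


def test_thickness_fourier_hits_printed_extremes():
    th = np.linspace(0, 2 * np.pi, 721)
    t = thickness_of_theta(th, (8.4, 3.3, 6.2))
    assert t[0] == pytest.approx(8.4, abs=1e-12)
    assert t[360] == pytest.approx(3.3, abs=1e-12)
    assert np.trapezoid(t[:-1], th[:-1]) / (2 * np.pi - th[1]) == \
        pytest.approx(6.2, rel=1e-3)


# ---------------------------------------------------------------------------
# aortic root

def test_leaflets_congruent_under_120_degree_rotation():
    root = build_aortic_root(LeafletSpec())
    ang = 2 * np.pi / 3
    Rz = np.array([[np.cos(ang), -np.sin(ang), 0],
                   [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
    err = np.abs(root["leaflet_1"].nodes @ Rz.T - root["leaflet_2"].nodes)
    assert err.max() < 1e-9


def test_attachment_curve_lies_on_root_cylinder():
    spec = LeafletSpec(R=12.5)
    root = build_aortic_root(spec, n_u=24, n_v=16)
    att = root["leaflet_1"].nodes.reshape(25, 17, 3)[:, 0, :]
    r = np.hypot(att[:, 0], att[:, 1])
    assert np.abs(r - spec.R).max() < 1e-6


def test_free_edge_lengthens_with_leaflet_height():
    lengths = [free_edge_arc_length(
        build_aortic_root(LeafletSpec(H=h))["leaflet_1"])
        for h in (10.0, 12.0, 14.0, 16.0)]
    assert np.all(np.diff(lengths) > 0)


def test_bad_leaflet_parameters_rejected():
    with pytest.raises(GeometryError):
        build_aortic_root(LeafletSpec(a=0.9))   # belly sag out of range
    with pytest.raises(GeometryError):
        build_aortic_root(LeafletSpec(R=-1.0))
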