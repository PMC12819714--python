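"""Structured benchmark meshes (slab, annulus, spherical shell).

These synthetic shapes back the verification suite: the slab and annulus
have closed-form harmonic/transmural fields, and the spherical shell has a
classical inflation solution.  The LV generator reuses the same
hexahedron-to-tetrahedron core.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

from .mesh import VolumeMesh

_PERMS = list(permutations(range(3)))


def hex_grid_to_tets(grid: np.ndarray) -> np.ndarray:
    """Kuhn (Freudenthal) subdivision of a structured hex grid into tets.

    ``grid[i, j, k]`` holds global node ids; repeated ids express collapsed
    (degenerate) cells, e.g. at a pole.  The subdivision is conforming:
    every shared quad face receives the same diagonal from both sides.
    Degenerate tets (repeated ids) are dropped.
    """
    n0, n1, n2 = grid.shape

    def corner(d):
        return grid[d[0]:n0 - 1 + d[0], d[1]:n1 - 1 + d[1], d[2]:n2 - 1 + d[2]]

    tets = []
    for p in _PERMS:
        c = [(0, 0, 0)]
        for ax in p:
            nxt = list(c[-1])
            nxt[ax] += 1
            c.append(tuple(nxt))
        tets.append(np.stack([corner(d).ravel() for d in c], axis=1))
    tets = np.concatenate(tets)
    distinct = (
        (tets[:, 0] != tets[:, 1]) & (tets[:, 0] != tets[:, 2])
        & (tets[:, 0] != tets[:, 3]) & (tets[:, 1] != tets[:, 2])
        & (tets[:, 1] != tets[:, 3]) & (tets[:, 2] != tets[:, 3])
    )
    return tets[distinct]


def _grid_surface_faces(grid: np.ndarray, axis: int, end: int) -> np.ndarray:
    """Triangulated boundary faces of one side of the grid (Kuhn-compatible).

    The quad (s, t) -> (s+1, t+1) diagonal matches the volumetric subdivision.
    """
    face = np.take(grid, -1 if end else 0, axis=axis)
    a = face[:-1, :-1].ravel()
    b = face[1:, :-1].ravel()
    c = face[1:, 1:].ravel()
    d = face[:-1, 1:].ravel()
    tris = np.concatenate([np.stack([a, b, c], 1), np.stack([a, c, d], 1)])
    keep = (tris[:, 0] != tris[:, 1]) & (tris[:, 1] != tris[:, 2]) \
        & (tris[:, 0] != tris[:, 2])
    return tris[keep]


def mesh_from_grid(nodes: np.ndarray, grid: np.ndarray,
                   face_tags: dict[str, tuple[int, int]] | None = None,
                   wrap_axis: int | None = None) -> VolumeMesh:
    """Build a :class:`VolumeMesh` from grid node ids plus side tags.

    ``face_tags`` maps a tag name to ``(axis, end)``; ``wrap_axis`` marks a
    periodic direction whose two sides are interior (no tags there).
    """
    tets = hex_grid_to_tets(grid)
    mesh = VolumeMesh(nodes=np.asarray(nodes, float), tets=tets)
    mesh.orient_positive()
    if face_tags:
        for tag, (axis, end) in face_tags.items():
            if axis == wrap_axis:
                continue
            faces = _grid_surface_faces(grid, axis, end)
            if tag in mesh.surface_tags:
                faces = np.vstack([mesh.surface_tags[tag], faces])
            mesh.surface_tags[tag] = faces
    return mesh


def make_box_mesh(lengths=(1.0, 1.0, 1.0), divisions=(4, 4, 4),
                  tag_names: dict[str, str] | None = None) -> VolumeMesh:
    """Axis-aligned box with sides tagged x0/x1/y0/y1/z0/z1 (renamable)."""
    nx, ny, nz = divisions
    xs = [np.linspace(0, L, n + 1) for L, n in zip(lengths, (nx, ny, nz))]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    grid = np.arange(len(nodes)).reshape(nx + 1, ny + 1, nz + 1)
    tags = {"x0": (0, 0), "x1": (0, 1), "y0": (1, 0),
            "y1": (1, 1), "z0": (2, 0), "z1": (2, 1)}
    mesh = mesh_from_grid(nodes, grid, tags)
    if tag_names:
        mesh.surface_tags = {tag_names.get(k, k): v
                             for k, v in mesh.surface_tags.items()}
    return mesh


def make_annulus_mesh(r_in=20.0, r_out=27.0, height=10.0,
                      nr=4, ntheta=32, nz=4) -> VolumeMesh:
    """Cylindrical annulus; inner surface tagged ``endocardium``, outer
    ``epicardium``, both flat ends ``base``."""
    r = np.linspace(r_in, r_out, nr + 1)
    th = np.linspace(0, 2 * np.pi, ntheta + 1)[:-1]
    z = np.linspace(0, height, nz + 1)
    R, T, Z = np.meshgrid(r, th, z, indexing="ij")
    nodes = np.stack([(R * np.cos(T)).ravel(), (R * np.sin(T)).ravel(),
                      Z.ravel()], axis=1)
    ids = np.arange(len(nodes)).reshape(nr + 1, ntheta, nz + 1)
    grid = np.concatenate([ids, ids[:, :1]], axis=1)          # wrap theta
    mesh = mesh_from_grid(
        nodes, grid,
        {"endocardium": (0, 0), "epicardium": (0, 1),
         "base": (2, 0), "base_top": (2, 1)},
        wrap_axis=1)
    mesh.surface_tags["base"] = np.vstack([mesh.surface_tags["base"],
                                           mesh.surface_tags.pop("base_top")])
    return mesh


def make_spherical_shell_patch(r_in=10.0, r_out=13.0, nr=3, nang=8) -> VolumeMesh:
    """A curvilinear patch of a thick spherical shell for inflation benchmarks.

    The patch is the gnomonic image of one quarter of a cube face, so all
    four cut faces are planes through the sphere centre.  Under internal
    pressure the exact solution is purely radial, hence zero normal
    displacement on those planes reproduces the full-sphere response.
    Tags: ``inner``, ``outer``, ``cut_u0``, ``cut_u1``, ``cut_v0``,
    ``cut_v1``; plane normals come from :func:`shell_patch_cut_normals`.
    """
    u = np.linspace(0, 1, nang + 1)
    v = np.linspace(0, 1, nang + 1)
    r = np.linspace(r_in, r_out, nr + 1)
    U, V, R = np.meshgrid(u, v, r, indexing="ij")
    norm = np.sqrt(U ** 2 + V ** 2 + 1.0)
    nodes = np.stack([(R * U / norm).ravel(), (R * V / norm).ravel(),
                      (R / norm).ravel()], axis=1)
    grid = np.arange(len(nodes)).reshape(nang + 1, nang + 1, nr + 1)
    return mesh_from_grid(
        nodes, grid,
        {"cut_u0": (0, 0), "cut_u1": (0, 1), "cut_v0": (1, 0),
         "cut_v1": (1, 1), "inner": (2, 0), "outer": (2, 1)})


def shell_patch_cut_normals() -> dict[str, np.ndarray]:
    """Unit normals of the four planar cuts of the shell patch."""
    s = 1.0 / np.sqrt(2.0)
    return {
        "cut_u0": np.array([1.0, 0.0, 0.0]),
        "cut_u1": np.array([s, 0.0, -s]),
        "cut_v0": np.array([0.0, 1.0, 0.0]),
        "cut_v1": np.array([0.0, s, -s]),
    }
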