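"""Tagged tetrahedral volume meshes and basic geometric queries.

The :class:`VolumeMesh` container is shared by all field solvers.  Boundary
facets carry string tags (``endocardium``, ``epicardium``, ``base``,
``lvot_outlet``); element sets carry region tags (``apex_cylinder``).
Node numbering is 0-based; coordinates are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MeshError(ValueError):
    pass


@dataclass
class VolumeMesh:
    nodes: np.ndarray               # (N, 3) float, mm
    tets: np.ndarray                # (E, 4) int, positively oriented
    surface_tags: dict = field(default_factory=dict)   # tag -> (F, 3) int facets
    region_tags: dict = field(default_factory=dict)    # tag -> (k,) int element ids

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def element_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        d1, d2, d3 = x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]
        return np.einsum("ij,ij->i", np.cross(d1, d2), d3) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def orient_positive(self) -> None:
        """Swap local nodes 1<->2 of any negatively oriented tet, in place."""
        vol = self.element_volumes()
        flip = vol < 0
        self.tets[flip, 1], self.tets[flip, 2] = (
            self.tets[flip, 2].copy(),
            self.tets[flip, 1].copy(),
        )

    def surface_nodes(self, tag: str) -> np.ndarray:
        if tag not in self.surface_tags:
            raise MeshError(f"mesh has no surface tag {tag!r}; "
                            f"present: {sorted(self.surface_tags)}")
        return np.unique(self.surface_tags[tag])

    def boundary_faces(self) -> np.ndarray:
        """All boundary facets (faces belonging to exactly one tet)."""
        faces = _tet_faces(self.tets)
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True,
                                   return_counts=True)
        return faces[idx[counts == 1]]

    def validate(self) -> None:
        """Raise MeshError on inverted tets or untagged/doubly tagged facets."""
        if np.any(self.element_volumes() <= 0):
            bad = int(np.argmin(self.element_volumes()))
            raise MeshError(f"non-positive tet volume (element {bad})")
        bnd = {tuple(f) for f in np.sort(self.boundary_faces(), axis=1)}
        tagged: dict[tuple, str] = {}
        for tag, faces in self.surface_tags.items():
            for f in np.sort(faces, axis=1):
                t = tuple(f)
                if t in tagged and tagged[t] != tag:
                    raise MeshError(f"facet {t} tagged both {tagged[t]!r} and {tag!r}")
                tagged[t] = tag
        missing = bnd - set(tagged)
        if missing:
            raise MeshError(f"{len(missing)} boundary facets carry no tag")


def _tet_faces(tets: np.ndarray) -> np.ndarray:
    """Outward-ordered faces of each tet, (4E, 3)."""
    t = tets
    return np.concatenate([
        t[:, [1, 2, 3]], t[:, [0, 3, 2]], t[:, [0, 1, 3]], t[:, [0, 2, 1]],
    ])


def surface_area_vectors(nodes: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-facet area-weighted normal, half the edge cross product."""
    x = nodes[faces]
    return 0.5 * np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])


def enclosed_volume_mm3(nodes: np.ndarray, faces: np.ndarray) -> float:
    """Divergence-theorem volume of a closed triangulated surface (mm^3).

    Orientation-independent up to sign; the absolute value is returned.
    Raises MeshError for an open surface (any edge used an odd number of
    times, i.e. the surface does not close up).
    """
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    if np.any(counts % 2):
        raise MeshError("surface is not closed (dangling edges found)")
    av = surface_area_vectors(nodes, faces)
    centers = nodes[faces].mean(axis=1)
    return abs(np.einsum("ij,ij->", centers, av)) / 3.0


def cavity_volume(mesh_or_nodes, faces: np.ndarray | None = None,
                  cap_tag: str = "base") -> float:
    """Endocardial cavity volume in mL.

    Accepts either a :class:`VolumeMesh` with an ``endocardium`` surface tag
    (the basal opening is capped with a triangle fan to the rim centroid)
    or an explicit closed surface ``(nodes, faces)``.
    """
    if faces is not None:
        return enclosed_volume_mm3(np.asarray(mesh_or_nodes), faces) / 1000.0

    mesh: VolumeMesh = mesh_or_nodes
    endo = mesh.surface_tags.get("endocardium")
    if endo is None:
        raise MeshError("cavity_volume needs an 'endocardium' surface tag")
    nodes, faces_closed = close_surface_with_cap(mesh.nodes, endo)
    return enclosed_volume_mm3(nodes, faces_closed) / 1000.0


def close_surface_with_cap(nodes: np.ndarray, faces: np.ndarray):
    """Close an open triangulated surface with a fan over its rim centroid.

    Returns (augmented nodes, closed faces).  The rim must be a single loop.
    """
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True,
                                  return_counts=True)
    rim_edges = edges[np.isin(inv, np.where(counts == 1)[0])]
    if len(rim_edges) == 0:
        return nodes, faces
    centroid = nodes[np.unique(rim_edges)].mean(axis=0)
    new_nodes = np.vstack([nodes, centroid[None, :]])
    c = len(nodes)
    # fan oriented opposite to the rim edge so normals stay consistent
    cap = np.column_stack([rim_edges[:, 1], rim_edges[:, 0],
                           np.full(len(rim_edges), c)])
    return new_nodes, np.vstack([faces, cap])


def point_triangle_distance(points: np.ndarray, tri_nodes: np.ndarray,
                            tris: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Exact minimal Euclidean distance from each point to a triangle set.

    Brute-force but fully vectorized (points chunked x all triangles);
    adequate for the desk-scale meshes used here.
    """
    a = tri_nodes[tris[:, 0]]
    ab = tri_nodes[tris[:, 1]] - a
    ac = tri_nodes[tris[:, 2]] - a
    out = np.empty(len(points))
    for lo in range(0, len(points), chunk):
        p = points[lo:lo + chunk]
        out[lo:lo + chunk] = _chunk_dist(p, a, ab, ac)
    return out


def _chunk_dist(p, a, ab, ac):
    # closest point on each triangle via the standard region decomposition
    ap = p[:, None, :] - a[None, :, :]               # (P, T, 3)
    d1 = np.einsum("tj,ptj->pt", ab, ap)
    d2 = np.einsum("tj,ptj->pt", ac, ap)
    bp = ap - ab[None, :, :]
    d3 = np.einsum("tj,ptj->pt", ab, bp)
    d4 = np.einsum("tj,ptj->pt", ac, bp)
    cp = ap - ac[None, :, :]
    d5 = np.einsum("tj,ptj->pt", ab, cp)
    d6 = np.einsum("tj,ptj->pt", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    denom_bc = (d4 - d3) + (d5 - d6)
    denom_bc = np.where(denom_bc == 0, 1.0, denom_bc)
    v_edge_bc = np.clip((d4 - d3) / denom_bc, 0.0, 1.0)

    aa = np.einsum("tj,tj->t", ab, ab)[None, :]
    cc = np.einsum("tj,tj->t", ac, ac)[None, :]
    v_ab = np.clip(np.divide(d1, aa, out=np.zeros_like(d1), where=aa > 0), 0, 1)
    w_ac = np.clip(np.divide(d2, cc, out=np.zeros_like(d2), where=cc > 0), 0, 1)

    det = va + vb + vc
    det = np.where(det == 0, 1.0, det)
    v_in = vb / det
    w_in = vc / det

    # candidate closest points: interior, edge AB, edge AC, edge BC
    def closest(v, w):
        return a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]

    cand = np.stack([
        closest(v_in, w_in),
        closest(v_ab, np.zeros_like(v_ab)),
        closest(np.zeros_like(w_ac), w_ac),
        closest(1.0 - v_edge_bc, v_edge_bc),
    ])                                               # (4, P, T, 3)
    d = np.linalg.norm(cand - p[None, :, None, :], axis=-1)
    inside = (v_in >= 0) & (w_in >= 0) & (v_in + w_in <= 1)
    d[0] = np.where(inside, d[0], np.inf)
    return d.min(axis=(0, 2))
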