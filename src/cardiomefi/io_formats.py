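"""Mesh and configuration I/O.

Meshes round-trip through ASCII VTU (XML unstructured grid) with surface
and region tags carried in FieldData so nothing is lost; surfaces export
to ASCII STL; simple Gmsh v2.2 ASCII tet meshes with physical groups can
be imported.  Every mesh file records its length unit ("mm" by default)
and coordinates are converted on read.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import VolumeMesh
from .units import to_canonical

VTK_TET = 10


class FormatError(ValueError):
    pass


def _fmt_array(a: np.ndarray) -> str:
    a = np.asarray(a)
    if a.dtype.kind == "f":
        return " ".join(repr(float(x)) for x in a.ravel())
    return " ".join(str(int(x)) for x in a.ravel())


def write_mesh(mesh: VolumeMesh, path, length_unit: str = "mm",
               point_data: dict | None = None,
               cell_data: dict | None = None) -> None:
    """Write a tagged tet mesh (plus optional fields) as ASCII VTU."""
    path = Path(path)
    if path.suffix.lower() != ".vtu":
        raise FormatError(f"write_mesh writes VTU files, got {path.suffix!r}")
    n, e = mesh.n_nodes, mesh.n_elements
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    ug = ET.SubElement(root, "UnstructuredGrid")

    fd = ET.SubElement(ug, "FieldData")
    unit_arr = ET.SubElement(fd, "DataArray", type="String",
                             Name="length_unit", NumberOfTuples="1",
                             format="ascii")
    unit_arr.text = length_unit
    for tag, faces in mesh.surface_tags.items():
        da = ET.SubElement(fd, "DataArray", type="Int64",
                           Name=f"surface_tag:{tag}", format="ascii",
                           NumberOfTuples=str(faces.size))
        da.text = _fmt_array(faces)
    for tag, els in mesh.region_tags.items():
        da = ET.SubElement(fd, "DataArray", type="Int64",
                           Name=f"region_tag:{tag}", format="ascii",
                           NumberOfTuples=str(np.size(els)))
        da.text = _fmt_array(np.asarray(els))

    piece = ET.SubElement(ug, "Piece", NumberOfPoints=str(n),
                          NumberOfCells=str(e))
    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(pts, "DataArray", type="Float64",
                       NumberOfComponents="3", format="ascii")
    da.text = _fmt_array(mesh.nodes)

    cells = ET.SubElement(piece, "Cells")
    for name, arr in (("connectivity", mesh.tets.ravel()),
                      ("offsets", 4 * np.arange(1, e + 1)),
                      ("types", np.full(e, VTK_TET))):
        da = ET.SubElement(cells, "DataArray", type="Int64", Name=name,
                           format="ascii")
        da.text = _fmt_array(arr)

    for parent_name, data, ncomp_of in (("PointData", point_data, n),
                                        ("CellData", cell_data, e)):
        if not data:
            continue
        parent = ET.SubElement(piece, parent_name)
        for name, arr in data.items():
            arr = np.asarray(arr, float)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            da = ET.SubElement(parent, "DataArray", type="Float64",
                               Name=name, NumberOfComponents=str(ncomp),
                               format="ascii")
            da.text = _fmt_array(arr)
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="ascii")


def read_mesh(path):
    """Read VTU (tags + fields) or Gmsh v2.2 MSH; returns
    (VolumeMesh, point_data, cell_data)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".vtu":
        return _read_vtu(path)
    if suffix == ".msh":
        return _read_msh(path)
    if suffix == ".stl":
        raise FormatError("STL holds an untagged surface, not a tagged "
                          "volume mesh; use read_stl for surfaces")
    raise FormatError(f"unsupported mesh format {suffix!r} "
                      "(supported: .vtu, .msh)")


def _read_vtu(path):
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise FormatError("no <Piece> in VTU file")
    unit = "mm"
    surface_tags, region_tags = {}, {}
    fd = root.find(".//FieldData")
    if fd is not None:
        for da in fd.findall("DataArray"):
            name = da.get("Name", "")
            if name == "length_unit":
                unit = (da.text or "mm").strip()
            elif name.startswith("surface_tag:"):
                faces = np.fromstring(da.text, sep=" ", dtype=int)
                surface_tags[name.split(":", 1)[1]] = faces.reshape(-1, 3)
            elif name.startswith("region_tag:"):
                region_tags[name.split(":", 1)[1]] = \
                    np.fromstring(da.text, sep=" ", dtype=int)

    pts = piece.find("Points/DataArray")
    nodes = np.fromstring(pts.text, sep=" ").reshape(-1, 3)
    nodes = to_canonical(1.0, unit) * nodes

    cells = {da.get("Name"): da for da in piece.findall("Cells/DataArray")}
    conn = np.fromstring(cells["connectivity"].text, sep=" ", dtype=int)
    types = np.fromstring(cells["types"].text, sep=" ", dtype=int)
    if np.any(types != VTK_TET):
        raise FormatError("only tetrahedral VTU meshes are supported")
    tets = conn.reshape(-1, 4)

    def read_fields(parent):
        out = {}
        node = piece.find(parent)
        if node is None:
            return out
        for da in node.findall("DataArray"):
            ncomp = int(da.get("NumberOfComponents", "1"))
            arr = np.fromstring(da.text, sep=" ")
            out[da.get("Name")] = arr if ncomp == 1 else arr.reshape(-1, ncomp)
        return out

    mesh = VolumeMesh(nodes=nodes, tets=tets, surface_tags=surface_tags,
                      region_tags=region_tags)
    return mesh, read_fields("PointData"), read_fields("CellData")


def _read_msh(path):
    """Minimal Gmsh v2.2 ASCII reader: tets + physical-group triangles."""
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    names, nodes, tets, tris = {}, None, [], {}
    for line in it:
        if line.startswith("$MeshFormat"):
            ver = next(it).split()[0]
            if not ver.startswith("2."):
                raise FormatError(f"only MSH v2.x supported, got {ver}")
        elif line.startswith("$PhysicalNames"):
            k = int(next(it))
            for _ in range(k):
                dim, tag, name = next(it).split(maxsplit=2)
                names[int(tag)] = name.strip().strip('"')
        elif line.startswith("$Nodes"):
            k = int(next(it))
            nodes = np.array([next(it).split()[1:4] for _ in range(k)],
                             dtype=float)
        elif line.startswith("$Elements"):
            k = int(next(it))
            for _ in range(k):
                parts = next(it).split()
                etype, ntags = int(parts[1]), int(parts[2])
                phys = int(parts[3]) if ntags else 0
                conn = [int(v) - 1 for v in parts[3 + ntags:]]
                if etype == 4:
                    tets.append(conn)
                elif etype == 2:
                    tris.setdefault(names.get(phys, str(phys)),
                                    []).append(conn)
    if nodes is None or not tets:
        raise FormatError("MSH file holds no tetrahedra")
    mesh = VolumeMesh(nodes=nodes,
                      tets=np.array(tets, dtype=int),
                      surface_tags={k: np.array(v, dtype=int)
                                    for k, v in tris.items()})
    mesh.orient_positive()
    return mesh, {}, {}


def run_manifest(config: dict, input_files=(), seed: int | None = None) -> dict:
    """Provenance record sufficient to re-execute a run bit-for-bit:
    configuration hash, code version, input digests and seeds."""
    import hashlib
    import json as _json

    from . import __version__

    cfg_text = _json.dumps(config, sort_keys=True, default=str)
    digests = {}
    for f in input_files:
        p = Path(f)
        digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return {
        "config": config,
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "code_version": __version__,
        "input_digests": digests,
        "seed": seed,
    }


def write_manifest(path, config: dict, input_files=(),
                   seed: int | None = None) -> None:
    import json as _json
    Path(path).write_text(_json.dumps(
        run_manifest(config, input_files, seed), indent=2, default=str))


def write_stl(nodes: np.ndarray, faces: np.ndarray, path,
              name: str = "surface") -> None:
    """ASCII STL export of a triangulated surface."""
    x = np.asarray(nodes, float)[np.asarray(faces, int)]
    n = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)
    with open(path, "w") as fh:
        fh.write(f"solid {name}\n")
        for tri, nv in zip(x, n):
            fh.write(f"  facet normal {nv[0]:.9e} {nv[1]:.9e} {nv[2]:.9e}\n")
            fh.write("    outer loop\n")
            for v in tri:
                fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write(f"endsolid {name}\n")


def read_stl(path):
    """Read an ASCII STL surface; returns (nodes, faces) with vertices
    merged exactly."""
    verts = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if parts and parts[0] == "vertex":
            verts.append([float(v) for v in parts[1:4]])
    v = np.array(verts).reshape(-1, 3, 3)
    flat = v.reshape(-1, 3)
    uniq, inv = np.unique(flat, axis=0, return_inverse=True)
    return uniq, inv.reshape(-1, 3)
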