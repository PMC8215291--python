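"""Reading and writing triangulated surfaces: OFF, ascii PLY, ascii VTP.

OFF carries geometry only; PLY carries geometry plus per-vertex scalar
properties (vector fields are split into ``name_0/_1/_2`` columns and
reassembled on read); VTP (VTK XML PolyData) carries PointData and
CellData arrays with 1 or 3 components.  All floats are written with
``repr`` so values round-trip bit-identically through these ascii formats.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import SurfaceMesh

__all__ = ["read_surface", "write_surface", "MeshIOError", "MeshFormatError"]

_FORMATS = ("off", "ply", "vtp")


class MeshIOError(IOError):
    """The file could not be read or written."""


class MeshFormatError(ValueError):
    """The file content violates the expected surface format."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported surface format {fmt!r} "
                              f"(supported: {', '.join(_FORMATS)})")
    return fmt


def read_surface(path, fmt: str | None = None) -> SurfaceMesh:
    """Read a triangulated surface, preserving named per-vertex fields."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    try:
        text = path.read_text()
    except OSError as exc:
        raise MeshIOError(f"cannot read surface file {path}: {exc}") from exc
    try:
        return {"off": _read_off, "ply": _read_ply, "vtp": _read_vtp}[fmt](text)
    except MeshFormatError as exc:
        raise MeshFormatError(f"{path}: {exc}") from exc


def write_surface(mesh: SurfaceMesh, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    text = {"off": _write_off, "ply": _write_ply, "vtp": _write_vtp}[fmt](mesh)
    try:
        path.write_text(text)
    except OSError as exc:
        raise MeshIOError(f"cannot write surface file {path}: {exc}") from exc


def _fmt_floats(row) -> str:
    return " ".join(repr(float(x)) for x in row)


# ---------------------------------------------------------------- OFF

def _write_off(mesh: SurfaceMesh) -> str:
    lines = ["OFF", f"{mesh.n_vertices} {mesh.n_triangles} 0"]
    lines += [_fmt_floats(v) for v in mesh.vertices]
    lines += [f"3 {t[0]} {t[1]} {t[2]}" for t in mesh.triangles]
    return "\n".join(lines) + "\n"


def _read_off(text: str) -> SurfaceMesh:
    tokens = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise MeshFormatError("missing OFF header")
    it = iter(tokens[1:])
    try:
        nv, nf, _ne = int(next(it)), int(next(it)), int(next(it))
        verts = np.array([float(next(it)) for _ in range(3 * nv)]).reshape(nv, 3)
        tris = []
        for _ in range(nf):
            k = int(next(it))
            idx = [int(next(it)) for _ in range(k)]
            if k != 3:
                raise MeshFormatError(f"non-triangular cell with {k} vertices")
            tris.append(idx)
    except StopIteration:
        raise MeshFormatError("truncated OFF file") from None
    return SurfaceMesh(verts, np.array(tris, dtype=np.int64).reshape(-1, 3))


# ---------------------------------------------------------------- PLY

def _split_vector_fields(vertex_data: dict) -> dict:
    """Flatten (n, 3) fields into three scalar columns name_0/_1/_2."""
    out = {}
    for name, arr in vertex_data.items():
        arr = np.asarray(arr)
        if arr.ndim == 1:
            out[name] = arr
        elif arr.ndim == 2 and arr.shape[1] == 3:
            for k in range(3):
                out[f"{name}_{k}"] = arr[:, k]
        else:
            raise MeshFormatError(f"field {name!r} must be (n,) or (n, 3)")
    return out


def _rejoin_vector_fields(columns: dict) -> dict:
    out = dict(columns)
    bases = {}
    for name in columns:
        m = re.fullmatch(r"(.*)_([012])", name)
        if m:
            bases.setdefault(m.group(1), set()).add(int(m.group(2)))
    for base, comps in bases.items():
        if comps == {0, 1, 2} and base not in columns:
            out[base] = np.stack([out.pop(f"{base}_{k}") for k in range(3)], axis=1)
    return out


def _write_ply(mesh: SurfaceMesh) -> str:
    cols = _split_vector_fields(mesh.vertex_data)
    header = ["ply", "format ascii 1.0",
              f"element vertex {mesh.n_vertices}",
              "property double x", "property double y", "property double z"]
    header += [f"property double {name}" for name in cols]
    header += [f"element face {mesh.n_triangles}",
               "property list uchar int vertex_indices", "end_header"]
    mat = np.column_stack([mesh.vertices] + [np.asarray(c, float) for c in cols.values()]) \
        if cols else mesh.vertices
    lines = header + [_fmt_floats(row) for row in mat]
    lines += [f"3 {t[0]} {t[1]} {t[2]}" for t in mesh.triangles]
    return "\n".join(lines) + "\n"


def _read_ply(text: str) -> SurfaceMesh:
    lines = text.splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshFormatError("missing ply header")
    i, nv, nf = 1, None, None
    vprops: list[str] = []
    element = None
    while i < len(lines):
        parts = lines[i].split()
        i += 1
        if not parts:
            continue
        if parts[0] == "format":
            if parts[1] != "ascii":
                raise MeshFormatError("only ascii PLY is supported")
        elif parts[0] == "element":
            element = parts[1]
            if element == "vertex":
                nv = int(parts[2])
            elif element == "face":
                nf = int(parts[2])
        elif parts[0] == "property" and element == "vertex":
            if parts[1] == "list":
                raise MeshFormatError("list property on vertices unsupported")
            vprops.append(parts[-1])
        elif parts[0] == "end_header":
            break
    if nv is None or nf is None:
        raise MeshFormatError("ply header missing vertex or face element")
    if vprops[:3] != ["x", "y", "z"]:
        raise MeshFormatError("vertex properties must start with x y z")
    body = lines[i:]
    if len(body) < nv + nf:
        raise MeshFormatError("truncated ply body")
    vmat = np.array([[float(x) for x in body[j].split()] for j in range(nv)])
    if vmat.shape[1] != len(vprops):
        raise MeshFormatError("vertex row width does not match declared properties")
    tris = []
    for j in range(nv, nv + nf):
        parts = [int(x) for x in body[j].split()]
        if parts[0] != 3 or len(parts) != 4:
            raise MeshFormatError(f"non-triangular cell with {parts[0]} vertices")
        tris.append(parts[1:])
    columns = {name: vmat[:, 3 + k] for k, name in enumerate(vprops[3:])}
    return SurfaceMesh(vmat[:, :3], np.array(tris, np.int64).reshape(-1, 3),
                       vertex_data=_rejoin_vector_fields(columns))


# ---------------------------------------------------------------- VTP

def _data_array(name: str | None, arr: np.ndarray) -> ET.Element:
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        vtype, fmt = "Int64", lambda x: str(int(x))
    else:
        vtype, fmt = "Float64", lambda x: repr(float(x))
    el = ET.Element("DataArray", {"type": vtype, "format": "ascii"})
    if name is not None:
        el.set("Name", name)
    ncomp = 1 if arr.ndim == 1 else arr.shape[1]
    if ncomp != 1:
        el.set("NumberOfComponents", str(ncomp))
    el.text = "\n" + "\n".join(" ".join(fmt(x) for x in np.atleast_1d(row))
                               for row in arr) + "\n"
    return el


def _write_vtp(mesh: SurfaceMesh) -> str:
    root = ET.Element("VTKFile", {"type": "PolyData", "version": "1.0",
                                  "byte_order": "LittleEndian"})
    poly = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(poly, "Piece", {
        "NumberOfPoints": str(mesh.n_vertices),
        "NumberOfVerts": "0", "NumberOfLines": "0", "NumberOfStrips": "0",
        "NumberOfPolys": str(mesh.n_triangles)})
    pts = ET.SubElement(piece, "Points")
    pts.append(_data_array(None, mesh.vertices.reshape(-1, 3)))
    pts[0].set("NumberOfComponents", "3")
    pdata = ET.SubElement(piece, "PointData")
    for name, arr in mesh.vertex_data.items():
        pdata.append(_data_array(name, np.asarray(arr)))
    cdata = ET.SubElement(piece, "CellData")
    for name, arr in mesh.triangle_data.items():
        cdata.append(_data_array(name, np.asarray(arr)))
    polys = ET.SubElement(piece, "Polys")
    conn = _data_array("connectivity", mesh.triangles.ravel())
    offs = _data_array("offsets", 3 * (np.arange(mesh.n_triangles, dtype=np.int64) + 1))
    polys.append(conn)
    polys.append(offs)
    ET.indent(root)
    return ET.tostring(root, encoding="unicode") + "\n"


def _parse_array(el: ET.Element) -> np.ndarray:
    text = el.text or ""
    dtype = np.int64 if el.get("type", "").startswith(("Int", "UInt")) else np.float64
    flat = np.array(text.split(), dtype=dtype)
    ncomp = int(el.get("NumberOfComponents", "1"))
    return flat.reshape(-1, ncomp) if ncomp > 1 else flat


def _read_vtp(text: str) -> SurfaceMesh:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise MeshFormatError(f"invalid XML: {exc}") from exc
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise MeshFormatError("no PolyData Piece element")
    pts_el = piece.find("./Points/DataArray")
    if pts_el is None:
        raise MeshFormatError("no Points array")
    verts = _parse_array(pts_el).reshape(-1, 3)
    polys = piece.find("Polys")
    conn = offs = None
    if polys is not None:
        for el in polys.findall("DataArray"):
            if el.get("Name") == "connectivity":
                conn = _parse_array(el).ravel()
            elif el.get("Name") == "offsets":
                offs = _parse_array(el).ravel()
    if conn is None or offs is None:
        raise MeshFormatError("missing Polys connectivity/offsets")
    sizes = np.diff(np.concatenate([[0], offs]))
    if sizes.size and not np.all(sizes == 3):
        bad = int(sizes[sizes != 3][0])
        raise MeshFormatError(f"non-triangular cell with {bad} vertices")
    tris = conn.reshape(-1, 3).astype(np.int64)
    vertex_data = {}
    pd = piece.find("PointData")
    if pd is not None:
        for el in pd.findall("DataArray"):
            vertex_data[el.get("Name")] = _parse_array(el)
    triangle_data = {}
    cd = piece.find("CellData")
    if cd is not None:
        for el in cd.findall("DataArray"):
            triangle_data[el.get("Name")] = _parse_array(el)
    return SurfaceMesh(verts, tris, vertex_data=vertex_data,
                       triangle_data=triangle_data)
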