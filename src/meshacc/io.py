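"""Readers and writers for the mesh formats facial scanners emit.

Supported dialects
------------------
* OBJ — ``v``/``f`` records; polygonal faces are fan-triangulated from the
  first vertex; 1-based and negative (relative) indices handled.
* STL — ASCII ``solid``/``facet`` blocks and the binary layout (80-byte
  header + uint32 count + 50 bytes per triangle, little-endian float32).
  STL stores a triangle soup, so the reader merges exactly-coincident
  vertices in first-occurrence order to recover shared connectivity.
* PLY — ``ascii`` and ``binary_little_endian``; vertex properties x/y/z as
  float or double plus optional uchar red/green/blue(/alpha); one face
  element with an index-list property. The writer emits double-precision
  coordinates so round-trips preserve millimetre coordinates to well below
  1e-6 mm.

Landmark files are plain text, one ``name x y z`` record per line (mm),
``#`` starts a comment.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .mesh import LandmarkSet, MeshValidationError, TriangleMesh

__all__ = [
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
]


class MeshFormatError(ValueError):
    """A file does not parse under the named dialect."""


_EXT_FORMAT = {".obj": "obj", ".stl": "stl", ".ply": "ply"}


def _resolve_format(path: Path, format: str) -> str:
    if format != "auto":
        return format
    try:
        return _EXT_FORMAT[path.suffix.lower()]
    except KeyError:
        raise MeshFormatError(
            f"cannot infer mesh format from suffix {path.suffix!r} of {path}"
        ) from None


def read_mesh(path, format: str = "auto") -> TriangleMesh:
    """Read a triangle mesh from ``path``.

    ``format`` is one of ``obj``, ``stl``, ``ply`` or ``auto`` (by suffix).
    The result always satisfies the TriangleMesh invariants; a malformed
    file raises :class:`MeshFormatError` naming the offending line/record.
    """
    path = Path(path)
    fmt = _resolve_format(path, format)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    reader = {"obj": _read_obj, "stl": _read_stl, "ply": _read_ply}[fmt]
    vertices, triangles, colors = reader(path)
    try:
        return TriangleMesh(vertices, triangles, colors)
    except MeshValidationError as e:
        raise MeshFormatError(f"{path}: parsed mesh is invalid: {e}") from e


def write_mesh(mesh: TriangleMesh, path, format: str = "auto") -> None:
    """Write ``mesh`` to ``path``.

    ``stl`` selects binary STL; ``stl_ascii`` the text variant. PLY defaults
    to binary_little_endian; ``ply_ascii`` writes text. Per-vertex colors are
    emitted for PLY only.
    """
    path = Path(path)
    fmt = format
    if fmt == "auto":
        fmt = _resolve_format(path, "auto")
    writer = {
        "obj": _write_obj,
        "stl": _write_stl_binary,
        "stl_ascii": _write_stl_ascii,
        "ply": lambda m, p: _write_ply(m, p, binary=True),
        "ply_ascii": lambda m, p: _write_ply(m, p, binary=False),
    }
    try:
        writer[fmt](mesh, path)
    except KeyError:
        raise MeshFormatError(f"unknown mesh format {fmt!r}") from None


# --------------------------------------------------------------------------
# OBJ
# --------------------------------------------------------------------------

def _read_obj(path: Path):
    vertices: list[list[float]] = []
    triangles: list[tuple[int, int, int]] = []
    with open(path, "r", errors="replace") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise MeshFormatError(f"{path}:{lineno}: vertex record needs 3 coordinates")
                try:
                    vertices.append([float(x) for x in parts[1:4]])
                except ValueError:
                    raise MeshFormatError(f"{path}:{lineno}: non-numeric vertex coordinate") from None
            elif tag == "f":
                if len(parts) < 4:
                    raise MeshFormatError(f"{path}:{lineno}: face record needs >= 3 indices")
                idx = []
                for token in parts[1:]:
                    head = token.split("/", 1)[0]
                    try:
                        i = int(head)
                    except ValueError:
                        raise MeshFormatError(f"{path}:{lineno}: non-integer face index {token!r}") from None
                    if i == 0:
                        raise MeshFormatError(f"{path}:{lineno}: OBJ indices are 1-based, got 0")
                    idx.append(i - 1 if i > 0 else len(vertices) + i)
                for k in idx:
                    if not 0 <= k < len(vertices):
                        raise MeshFormatError(f"{path}:{lineno}: face index {k + 1} out of range")
                # fan triangulation from the first face vertex
                for k in range(1, len(idx) - 1):
                    triangles.append((idx[0], idx[k], idx[k + 1]))
            # other records (vn, vt, o, g, s, mtllib, usemtl, ...) are ignored
    return np.asarray(vertices, dtype=np.float64), np.asarray(triangles, dtype=np.int64), None


def _write_obj(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for t in mesh.triangles:
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")


# --------------------------------------------------------------------------
# STL
# --------------------------------------------------------------------------

def _stl_is_ascii(path: Path) -> bool:
    with open(path, "rb") as fh:
        head = fh.read(512)
    if not head.lstrip().lower().startswith(b"solid"):
        return False
    # a binary file may still begin with 'solid'; require a 'facet' token
    return b"facet" in head or len(head) < 84


def _read_stl(path: Path):
    if _stl_is_ascii(path):
        soup = _read_stl_ascii(path)
    else:
        soup = _read_stl_binary(path)
    return _merge_soup(soup)


def _read_stl_ascii(path: Path) -> np.ndarray:
    tris: list[list[float]] = []
    current: list[list[float]] = []
    with open(path, "r", errors="replace") as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts:
                continue
            if parts[0].lower() == "vertex":
                if len(parts) < 4:
                    raise MeshFormatError(f"{path}:{lineno}: STL vertex record needs 3 coordinates")
                try:
                    current.append([float(x) for x in parts[1:4]])
                except ValueError:
                    raise MeshFormatError(f"{path}:{lineno}: non-numeric STL vertex coordinate") from None
            elif parts[0].lower() == "endfacet":
                if len(current) != 3:
                    raise MeshFormatError(f"{path}:{lineno}: facet has {len(current)} vertices, expected 3")
                tris.append([c for v in current for c in v])
                current = []
    if not tris:
        raise MeshFormatError(f"{path}: no facets found in ASCII STL")
    return np.asarray(tris, dtype=np.float64).reshape(-1, 3, 3)


def _read_stl_binary(path: Path) -> np.ndarray:
    data = path.read_bytes()
    if len(data) < 84:
        raise MeshFormatError(f"{path}: binary STL shorter than the 84-byte header")
    (n,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * n
    if len(data) < expected:
        raise MeshFormatError(
            f"{path}: binary STL truncated: header promises {n} triangles ({expected} bytes), file has {len(data)}"
        )
    rec = np.frombuffer(data, dtype=np.uint8, count=50 * n, offset=84).reshape(n, 50)
    coords = rec[:, 12:48].copy().view("<f4").reshape(n, 3, 3)
    return coords.astype(np.float64)


def _merge_soup(soup: np.ndarray):
    """Merge exactly-equal corner coordinates of a triangle soup into an
    indexed mesh, preserving first-occurrence vertex order."""
    flat = soup.reshape(-1, 3)
    _, first, inverse = np.unique(flat, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    vertices = flat[np.sort(first)]
    triangles = rank[inverse].reshape(-1, 3)
    return vertices, triangles.astype(np.int64), None


def _write_stl_ascii(mesh: TriangleMesh, path: Path) -> None:
    a, b, c = mesh.triangle_corners()
    normals = mesh.face_normals()
    with open(path, "w") as fh:
        fh.write("solid meshacc\n")
        for n, pa, pb, pc in zip(normals, a, b, c):
            fh.write(f"facet normal {float(n[0])!r} {float(n[1])!r} {float(n[2])!r}\n outer loop\n")
            for p in (pa, pb, pc):
                fh.write(f"  vertex {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
            fh.write(" endloop\nendfacet\n")
        fh.write("endsolid meshacc\n")


def _write_stl_binary(mesh: TriangleMesh, path: Path) -> None:
    n = mesh.n_triangles
    rec = np.zeros((n, 50), dtype=np.uint8)
    block = np.empty((n, 12), dtype="<f4")
    block[:, 0:3] = mesh.face_normals()
    a, b, c = mesh.triangle_corners()
    block[:, 3:6], block[:, 6:9], block[:, 9:12] = a, b, c
    rec[:, 0:48] = block.view(np.uint8).reshape(n, 48)
    with open(path, "wb") as fh:
        fh.write(b"meshacc binary STL".ljust(80, b" "))
        fh.write(struct.pack("<I", n))
        fh.write(rec.tobytes())


# --------------------------------------------------------------------------
# PLY
# --------------------------------------------------------------------------

_PLY_SIZES = {
    "char": "b", "int8": "b", "uchar": "B", "uint8": "B",
    "short": "h", "int16": "h", "ushort": "H", "uint16": "H",
    "int": "i", "int32": "i", "uint": "I", "uint32": "I",
    "float": "f", "float32": "f", "double": "d", "float64": "d",
}


def _read_ply(path: Path):
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise MeshFormatError(f"{path}:1: not a PLY file (missing 'ply' magic)")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str, str | None]]]] = []
        lineno = 1
        while True:
            line = fh.readline()
            lineno += 1
            if not line:
                raise MeshFormatError(f"{path}: PLY header ends without end_header")
            parts = line.decode("ascii", errors="replace").split()
            if not parts or parts[0] == "comment":
                continue
            if parts[0] == "format":
                if parts[1] not in ("ascii", "binary_little_endian"):
                    raise MeshFormatError(f"{path}:{lineno}: unsupported PLY format {parts[1]!r}")
                fmt = parts[1]
            elif parts[0] == "element":
                elements.append((parts[1], int(parts[2]), []))
            elif parts[0] == "property":
                if not elements:
                    raise MeshFormatError(f"{path}:{lineno}: property before any element")
                if parts[1] == "list":
                    elements[-1][2].append((parts[4], parts[3], parts[2]))
                else:
                    elements[-1][2].append((parts[2], parts[1], None))
            elif parts[0] == "end_header":
                break
            else:
                raise MeshFormatError(f"{path}:{lineno}: unknown PLY header record {parts[0]!r}")
        if fmt is None:
            raise MeshFormatError(f"{path}: PLY header missing format record")
        body = fh.read()

    vertices = triangles = colors = None
    if fmt == "ascii":
        tokens = body.split()
        pos = 0
        for name, count, props in elements:
            if name == "vertex":
                width = len(props)
                arr = np.asarray(tokens[pos:pos + count * width], dtype=np.float64).reshape(count, width)
                pos += count * width
                cols = {p[0]: i for i, p in enumerate(props)}
                vertices, colors = _ply_vertex_columns(arr, cols, path)
            elif name == "face":
                tri = []
                for _ in range(count):
                    k = int(tokens[pos]); pos += 1
                    poly = [int(t) for t in tokens[pos:pos + k]]; pos += k
                    for j in range(1, k - 1):
                        tri.append((poly[0], poly[j], poly[j + 1]))
                triangles = np.asarray(tri, dtype=np.int64)
            else:
                pos += count * len(props)  # skip unknown fixed-width element
    else:
        offset = 0
        for name, count, props in elements:
            if any(p[2] is not None for p in props):  # list property: per-row parse
                if name != "face":
                    raise MeshFormatError(f"{path}: unsupported list property in element {name!r}")
                tri = []
                for r in range(count):
                    cfmt = _PLY_SIZES[props[0][2]]  # list-count type
                    (k,) = struct.unpack_from("<" + cfmt, body, offset)
                    offset += struct.calcsize(cfmt)
                    ifmt = _PLY_SIZES[props[0][1]]  # per-index type
                    poly = struct.unpack_from("<" + ifmt * k, body, offset)
                    offset += struct.calcsize(ifmt) * k
                    for j in range(1, k - 1):
                        tri.append((poly[0], poly[j], poly[j + 1]))
                triangles = np.asarray(tri, dtype=np.int64)
            else:
                dtype = np.dtype([(p[0], "<" + _PLY_SIZES[p[1]]) for p in props])
                arr = np.frombuffer(body, dtype=dtype, count=count, offset=offset)
                offset += dtype.itemsize * count
                if name == "vertex":
                    table = np.column_stack([arr[p[0]].astype(np.float64) for p in props])
                    cols = {p[0]: i for i, p in enumerate(props)}
                    vertices, colors = _ply_vertex_columns(table, cols, path)
    if vertices is None or triangles is None:
        raise MeshFormatError(f"{path}: PLY file lacks vertex or face element")
    return vertices, triangles, colors


def _ply_vertex_columns(arr: np.ndarray, cols: dict[str, int], path: Path):
    try:
        xyz = arr[:, [cols["x"], cols["y"], cols["z"]]]
    except KeyError as e:
        raise MeshFormatError(f"{path}: PLY vertex element missing coordinate property {e}") from None
    colors = None
    if all(c in cols for c in ("red", "green", "blue")):
        colors = arr[:, [cols["red"], cols["green"], cols["blue"]]].astype(np.uint8)
    return xyz, colors


def _write_ply(mesh: TriangleMesh, path: Path, binary: bool) -> None:
    has_color = mesh.colors is not None
    header = ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"element vertex {mesh.n_vertices}",
              "property double x", "property double y", "property double z"]
    if has_color:
        header += ["property uchar red", "property uchar green", "property uchar blue"]
    header += [f"element face {mesh.n_triangles}",
               "property list uchar int vertex_indices", "end_header"]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fields = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
            if has_color:
                fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
            varr = np.zeros(mesh.n_vertices, dtype=np.dtype(fields))
            varr["x"], varr["y"], varr["z"] = mesh.vertices.T
            if has_color:
                varr["red"], varr["green"], varr["blue"] = mesh.colors.T
            fh.write(varr.tobytes())
            farr = np.zeros(mesh.n_triangles, dtype=np.dtype([("n", "u1"), ("i", "<i4", (3,))]))
            farr["n"] = 3
            farr["i"] = mesh.triangles
            fh.write(farr.tobytes())
        else:
            lines = []
            for i, v in enumerate(mesh.vertices):
                row = f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}"
                if has_color:
                    c = mesh.colors[i]
                    row += f" {c[0]} {c[1]} {c[2]}"
                lines.append(row)
            for t in mesh.triangles:
                lines.append(f"3 {t[0]} {t[1]} {t[2]}")
            fh.write(("\n".join(lines) + "\n").encode("ascii"))


# --------------------------------------------------------------------------
# Landmarks
# --------------------------------------------------------------------------

def read_landmarks(path) -> LandmarkSet:
    """Read a ``name x y z`` landmark file (mm, ``#`` comments)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"landmark file not found: {path}")
    items: list[tuple[str, list[float]]] = []
    seen: set[str] = set()
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise MeshFormatError(
                    f"{path}:{lineno}: expected 'name x y z', got {len(parts)} fields"
                )
            name = parts[0]
            if name in seen:
                raise MeshFormatError(f"{path}:{lineno}: duplicate landmark name {name!r}")
            seen.add(name)
            try:
                xyz = [float(x) for x in parts[1:]]
            except ValueError:
                raise MeshFormatError(f"{path}:{lineno}: non-numeric coordinate") from None
            items.append((name, xyz))
    if not items:
        raise MeshFormatError(f"{path}: landmark file contains no landmarks")
    return LandmarkSet(items)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# landmark x y z (mm)\n")
        for name, p in landmarks:
            fh.write(f"{name} {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
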