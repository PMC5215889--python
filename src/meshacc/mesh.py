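"""Core geometric containers: triangle meshes, point clouds and named landmarks.

All coordinates are in millimetres throughout the package; there is no unit
negotiation. Triangle indices are 0-based internally regardless of the file
dialect they came from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "TriangleMesh",
    "PointCloud",
    "LandmarkSet",
    "MeshValidationError",
    "ValidationIssue",
    "validate_mesh",
]


class MeshValidationError(ValueError):
    """Raised when a mesh or landmark set violates a structural invariant."""


@dataclass(frozen=True)
class ValidationIssue:
    """A single structural problem found in a mesh (reported, never repaired)."""

    kind: str  # 'nan_coordinate' | 'index_out_of_range' | 'degenerate_triangle' | 'unreferenced_vertex'
    index: int  # vertex or triangle index the issue refers to
    detail: str


class TriangleMesh:
    """An indexed triangle surface in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    triangles : (m, 3) int array
        Vertex-index triples, 0-based.
    colors : (n, 3) uint8 array, optional
        Per-vertex RGB colors (used by deviation color maps).
    validate : bool
        When true (default), enforce the structural invariants: finite
        coordinates, in-range indices, no repeated index within a triangle,
        at least one vertex and one triangle.
    """

    __slots__ = ("vertices", "triangles", "colors")

    def __init__(self, vertices, triangles, colors=None, validate: bool = True):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.ascontiguousarray(triangles, dtype=np.int64).reshape(-1, 3)
        self.colors = None
        if colors is not None:
            colors = np.ascontiguousarray(colors, dtype=np.uint8).reshape(-1, 3)
            if len(colors) != len(self.vertices):
                raise MeshValidationError(
                    f"colors length {len(colors)} != vertex count {len(self.vertices)}"
                )
            self.colors = colors
        if validate:
            self._check()

    def _check(self) -> None:
        if len(self.vertices) < 1 or len(self.triangles) < 1:
            raise MeshValidationError("mesh must have at least one vertex and one triangle")
        if not np.isfinite(self.vertices).all():
            raise MeshValidationError("mesh has non-finite vertex coordinates")
        t = self.triangles
        if t.min() < 0 or t.max() >= len(self.vertices):
            raise MeshValidationError(
                f"triangle index out of range [0, {len(self.vertices)})"
            )
        if ((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])).any():
            raise MeshValidationError("triangle with repeated vertex index")

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_corners(self):
        """Return the (m,3) corner coordinate arrays (a, b, c)."""
        v, t = self.vertices, self.triangles
        return v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        a, b, c = self.triangle_corners()
        n = np.cross(b - a, c - a)
        if normalize:
            ln = np.linalg.norm(n, axis=1, keepdims=True)
            ln[ln == 0.0] = 1.0
            n = n / ln
        return n

    def triangle_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(normalize=False), axis=1)

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def diameter(self) -> float:
        """Largest inter-vertex distance (mm); rotation invariant."""
        pts = self.vertices
        if len(pts) > 4:
            try:
                from scipy.spatial import ConvexHull

                pts = pts[ConvexHull(pts).vertices]
            except Exception:  # degenerate (flat/collinear) clouds
                pass
        d2 = ((pts[:, None] - pts[None]) ** 2).sum(-1)
        return float(np.sqrt(d2.max()))

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            None if self.colors is None else self.colors.copy(),
            validate=False,
        )

    def with_colors(self, colors) -> "TriangleMesh":
        return TriangleMesh(self.vertices, self.triangles, colors, validate=False)

    def submesh(self, vertex_mask: np.ndarray) -> "TriangleMesh":
        """Keep the vertices selected by ``vertex_mask``; drop every triangle
        touching a dropped vertex, then compact the vertex array."""
        vertex_mask = np.asarray(vertex_mask, dtype=bool)
        keep_tri = vertex_mask[self.triangles].all(axis=1)
        tris = self.triangles[keep_tri]
        used = np.zeros(len(self.vertices), dtype=bool)
        used[tris.ravel()] = True
        remap = np.cumsum(used) - 1
        colors = None if self.colors is None else self.colors[used]
        return TriangleMesh(self.vertices[used], remap[tris], colors, validate=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TriangleMesh({self.n_vertices} vertices, {self.n_triangles} triangles)"


class PointCloud:
    """An unstructured set of 3D points in millimetres."""

    __slots__ = ("points",)

    def __init__(self, points, validate: bool = True):
        self.points = np.ascontiguousarray(points, dtype=np.float64).reshape(-1, 3)
        if validate:
            if len(self.points) < 1:
                raise MeshValidationError("point cloud must have at least one point")
            if not np.isfinite(self.points).all():
                raise MeshValidationError("point cloud has non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)


class LandmarkSet:
    """An ordered mapping of anatomical landmark names to 3D points (mm).

    Two landmark sets *correspond* iff they carry the identical ordered name
    list; registration refuses anything else.
    """

    __slots__ = ("_names", "_points")

    def __init__(self, items: Mapping[str, np.ndarray] | list[tuple[str, np.ndarray]]):
        pairs = list(items.items()) if isinstance(items, Mapping) else list(items)
        names = [str(n) for n, _ in pairs]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise MeshValidationError(f"duplicate landmark name(s): {', '.join(dup)}")
        pts = np.asarray([p for _, p in pairs], dtype=np.float64).reshape(-1, 3)
        if len(pts) and not np.isfinite(pts).all():
            raise MeshValidationError("landmark set has non-finite coordinates")
        self._names = names
        self._points = pts

    @property
    def names(self) -> list[str]:
        return list(self._names)

    @property
    def points(self) -> np.ndarray:
        return self._points.copy()

    def __len__(self) -> int:
        return len(self._names)

    def __contains__(self, name: str) -> bool:
        return name in self._names

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self._points[self._names.index(name)].copy()
        except ValueError:
            raise KeyError(name) from None

    def __iter__(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(zip(self._names, self._points))

    def corresponds_to(self, other: "LandmarkSet") -> bool:
        return self._names == other._names

    def subset(self, names: list[str]) -> "LandmarkSet":
        return LandmarkSet([(n, self[n]) for n in names])

    def transformed(self, transform) -> "LandmarkSet":
        pts = transform.apply(self._points)
        return LandmarkSet(list(zip(self._names, pts)))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LandmarkSet)
            and self._names == other._names
            and np.array_equal(self._points, other._points)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"LandmarkSet({self._names!r})"


def validate_mesh(mesh: TriangleMesh) -> list[ValidationIssue]:
    """Audit a mesh and report structural issues without repairing anything.

    Checks: non-finite coordinates, triangle indices out of range, degenerate
    (zero-area) triangles, and vertices referenced by no triangle.
    """
    issues: list[ValidationIssue] = []
    bad = ~np.isfinite(mesh.vertices).all(axis=1)
    for i in np.flatnonzero(bad):
        issues.append(ValidationIssue("nan_coordinate", int(i), f"vertex {i} has a non-finite coordinate"))
    t = mesh.triangles
    out = (t < 0) | (t >= len(mesh.vertices))
    for i in np.flatnonzero(out.any(axis=1)):
        issues.append(
            ValidationIssue("index_out_of_range", int(i), f"triangle {i} references index outside [0, {len(mesh.vertices)})")
        )
    ok_rows = ~out.any(axis=1) & ~bad[np.clip(t, 0, len(mesh.vertices) - 1)].any(axis=1)
    if ok_rows.any():
        v = mesh.vertices
        rows = np.flatnonzero(ok_rows)
        a, b, c = v[t[rows, 0]], v[t[rows, 1]], v[t[rows, 2]]
        areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
        for i, ar in zip(rows, areas):
            if ar <= 1e-12:
                issues.append(ValidationIssue("degenerate_triangle", int(i), f"triangle {i} has zero area"))
    referenced = np.zeros(len(mesh.vertices), dtype=bool)
    inb = t[(t >= 0) & (t < len(mesh.vertices))]
    referenced[inb.ravel()] = True
    for i in np.flatnonzero(~referenced):
        issues.append(ValidationIssue("unreferenced_vertex", int(i), f"vertex {i} is referenced by no triangle"))
    return issues
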