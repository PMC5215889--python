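"""Trim registered scans to a shared boundary and split faces into thirds.

The facial thirds are cut by two planes normal to the vertical (Y) axis of
the natural head position (NHP) frame, one through glabella and one through
subnasale: *upper* above the glabella plane, *middle* between the planes,
*lower* below the subnasale plane. Triangles straddling a cutting plane are
split exactly at the edge-plane intersections, so the three parts' areas sum
to the whole to floating-point accuracy and a part's RMS does not depend on
the input triangulation. Vertices lying exactly on a cutting plane belong to
the part above it (closed-below convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import MeshIndex
from .mesh import LandmarkSet, TriangleMesh

__all__ = [
    "NHPFrame",
    "DegenerateFrameError",
    "InvalidPlaneError",
    "OverTrimError",
    "TrimBoundary",
    "build_nhp_frame",
    "split_mesh_by_plane",
    "split_thirds",
    "trim_common",
    "PARTITION_LABELS",
]

PARTITION_LABELS = ("upper", "middle", "lower")


class DegenerateFrameError(ValueError):
    """Landmarks do not span a usable head frame."""


class InvalidPlaneError(ValueError):
    """Cutting planes are ordered impossibly (glabella at/below subnasale)."""


class OverTrimError(RuntimeError):
    """Trimming removed an entire mesh."""


@dataclass(frozen=True)
class NHPFrame:
    """Natural-head-position surrogate frame.

    ``axes`` rows are the unit X (subject's right -> left), Y (inferior ->
    superior) and Z (posterior -> anterior) directions in world coordinates;
    ``origin`` is conventionally at subnasale.
    """

    origin: np.ndarray
    axes: np.ndarray  # (3, 3), rows X, Y, Z

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        axes = np.asarray(self.axes, dtype=np.float64).reshape(3, 3)
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise DegenerateFrameError("frame axes are not orthonormal")
        if np.linalg.det(axes) < 0:
            raise DegenerateFrameError("frame axes are not right-handed")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    @property
    def x_axis(self) -> np.ndarray:
        return self.axes[0]

    @property
    def y_axis(self) -> np.ndarray:
        return self.axes[1]

    @property
    def z_axis(self) -> np.ndarray:
        return self.axes[2]

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=np.float64) - self.origin) @ self.axes.T

    def from_local(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.axes + self.origin

    def height_of(self, point) -> float:
        """Signed Y (vertical) coordinate of a world point in this frame."""
        return float((np.asarray(point, dtype=np.float64) - self.origin) @ self.y_axis)


def build_nhp_frame(landmarks: LandmarkSet) -> NHPFrame:
    """Derive a surrogate NHP frame from landmarks.

    X is the unit inter-exocanthion direction (right -> left), Y the
    component of the subnasale->glabella direction orthogonal to X, Z their
    cross product; origin at subnasale.
    """
    for name in ("exocanthion_r", "exocanthion_l", "glabella", "subnasale"):
        if name not in landmarks:
            raise DegenerateFrameError(f"frame landmark {name!r} missing")
    x = landmarks["exocanthion_l"] - landmarks["exocanthion_r"]
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise DegenerateFrameError("exocanthion landmarks coincide")
    x = x / nx
    g = landmarks["glabella"] - landmarks["subnasale"]
    y = g - (g @ x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise DegenerateFrameError("glabella-subnasale direction is collinear with the lateral axis")
    y = y / ny
    z = np.cross(x, y)
    return NHPFrame(origin=landmarks["subnasale"], axes=np.stack([x, y, z]))


# --------------------------------------------------------------------------
# Exact plane splitting
# --------------------------------------------------------------------------

def split_mesh_by_plane(
    mesh: TriangleMesh, point, normal, eps: float = 1e-9
) -> tuple[TriangleMesh, TriangleMesh]:
    """Split a mesh exactly at a plane into (above, below) halves.

    "Above" is the side the normal points to and, by the closed-below
    convention, includes everything on the plane itself. Crossing triangles
    are clipped at the exact edge-plane intersections; intersection vertices
    are shared between adjacent triangles, so the halves' areas sum to the
    input area. Either half may come back empty (0 triangles).
    """
    point = np.asarray(point, dtype=np.float64).reshape(3)
    n = np.asarray(normal, dtype=np.float64).reshape(3)
    ln = np.linalg.norm(n)
    if ln < 1e-12:
        raise InvalidPlaneError("plane normal must be non-zero")
    n = n / ln

    v = mesh.vertices
    s = (v - point) @ n
    s = np.where(np.abs(s) <= eps, 0.0, s)

    tri_s = s[mesh.triangles]
    all_above = (tri_s >= 0.0).all(axis=1)
    all_below = (tri_s <= 0.0).all(axis=1) & ~all_above

    verts = [v]
    extra: list[np.ndarray] = []
    cut_cache: dict[tuple[int, int], int] = {}
    above_faces = list(mesh.triangles[all_above])
    below_faces = list(mesh.triangles[all_below])

    def cut_vertex(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        idx = cut_cache.get(key)
        if idx is None:
            t = s[key[0]] / (s[key[0]] - s[key[1]])
            p = v[key[0]] + t * (v[key[1]] - v[key[0]])
            idx = len(v) + len(extra)
            extra.append(p)
            cut_cache[key] = idx
        return idx

    crossing = np.flatnonzero(~all_above & ~all_below)
    for ti in crossing:
        ids = mesh.triangles[ti]
        for keep_above, faces in ((True, above_faces), (False, below_faces)):
            poly: list[int] = []
            for k in range(3):
                i, j = ids[k], ids[(k + 1) % 3]
                si, sj = s[i], s[j]
                inside_i = si >= 0.0 if keep_above else si <= 0.0
                inside_j = sj >= 0.0 if keep_above else sj <= 0.0
                if inside_i:
                    poly.append(int(i))
                if (si > 0.0 and sj < 0.0) or (si < 0.0 and sj > 0.0):
                    poly.append(cut_vertex(int(i), int(j)))
                elif inside_j and not inside_i:
                    pass  # j emitted on its own turn
            # fan-triangulate the clipped polygon (3 or 4 vertices)
            for k in range(1, len(poly) - 1):
                faces.append(np.array([poly[0], poly[k], poly[k + 1]]))

    all_v = np.vstack([v] + [np.asarray(extra)]) if extra else v

    def build(faces: list[np.ndarray]) -> TriangleMesh:
        if not faces:
            return TriangleMesh(
                np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64), validate=False
            )
        tris = np.asarray(faces, dtype=np.int64)
        # drop slivers degenerated to a repeated index by the eps snap
        ok = (tris[:, 0] != tris[:, 1]) & (tris[:, 1] != tris[:, 2]) & (tris[:, 0] != tris[:, 2])
        tris = tris[ok]
        full = TriangleMesh(all_v, tris, validate=False)
        return full.submesh(np.ones(len(all_v), dtype=bool)) if len(tris) else TriangleMesh(
            np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64), validate=False
        )

    return build(above_faces), build(below_faces)


def split_thirds(
    mesh: TriangleMesh, frame: NHPFrame, glabella, subnasale
) -> dict[str, TriangleMesh]:
    """Split a face into upper/middle/lower thirds by the glabella and
    subnasale planes (both normal to the frame's vertical axis)."""
    y_g = frame.height_of(glabella)
    y_s = frame.height_of(subnasale)
    if y_g <= y_s:
        raise InvalidPlaneError(
            f"glabella (frame-Y {y_g:.3f}) must lie above subnasale (frame-Y {y_s:.3f})"
        )
    upper, rest = split_mesh_by_plane(mesh, glabella, frame.y_axis)
    if rest.n_triangles:
        middle, lower = split_mesh_by_plane(rest, subnasale, frame.y_axis)
    else:
        middle = lower = rest
    return {"upper": upper, "middle": middle, "lower": lower}


# --------------------------------------------------------------------------
# Common-boundary trimming
# --------------------------------------------------------------------------

@dataclass
class TrimBoundary:
    """The shared trimming boundary applied to every registered mesh.

    ``planes`` is a list of (point, normal) pairs in world coordinates; the
    half-space the normal points into is kept (exact clipping). After
    clipping, a vertex survives only if it lies within ``overlap_mm`` of the
    surface of every other mesh (mutual-overlap mask); triangles touching a
    dropped vertex are removed.
    """

    planes: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    overlap_mm: float = 10.0


def trim_common(meshes: list[TriangleMesh], boundary: TrimBoundary | None = None) -> list[TriangleMesh]:
    """Apply the same boundary (clip planes + mutual-overlap mask) to all
    registered meshes. Raises :class:`OverTrimError` if any mesh vanishes."""
    boundary = boundary or TrimBoundary()
    clipped = []
    for k, mesh in enumerate(meshes):
        m = mesh
        for point, normal in boundary.planes:
            m, _ = split_mesh_by_plane(m, point, normal)
            if m.n_triangles == 0:
                raise OverTrimError(f"clip planes removed all of mesh {k}")
        clipped.append(m)

    if len(clipped) < 2:
        return clipped
    indexes = [MeshIndex(m) for m in clipped]
    out = []
    for k, m in enumerate(clipped):
        keep = np.ones(m.n_vertices, dtype=bool)
        for j, idx in enumerate(indexes):
            if j == k:
                continue
            keep &= idx.query(m.vertices).distances <= boundary.overlap_mm
        trimmed = m.submesh(keep)
        if trimmed.n_triangles == 0:
            raise OverTrimError(f"mutual-overlap mask removed all of mesh {k}")
        out.append(trimmed)
    return out
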