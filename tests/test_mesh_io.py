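"""Mesh/landmark containers and format round-trips.

trimesh serves as the independent reader/writer oracle: files written by
this package must parse identically under trimesh, and vice versa.
"""

import struct

import numpy as np
import pytest
import trimesh

from meshacc.io import (
    MeshFormatError,
    read_landmarks,
    read_mesh,
    write_landmarks,
    write_mesh,
)
from meshacc.mesh import (
    LandmarkSet,
    MeshValidationError,
    PointCloud,
    TriangleMesh,
    validate_mesh,
)

from conftest import submesh_first_triangles


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

class TestContainers:
    def test_mesh_invariants_enforced(self):
        with pytest.raises(MeshValidationError):
            TriangleMesh([[0, 0, 0]], np.zeros((0, 3), dtype=int))  # no triangle
        with pytest.raises(MeshValidationError):
            TriangleMesh([[0, 0, np.nan], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        with pytest.raises(MeshValidationError):
            TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 3]])  # out of range
        with pytest.raises(MeshValidationError):
            TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 1]])  # repeated

    def test_point_cloud_invariants(self):
        with pytest.raises(MeshValidationError):
            PointCloud(np.zeros((0, 3)))
        assert len(PointCloud([[1.0, 2.0, 3.0]])) == 1

    def test_landmark_duplicate_names_rejected(self):
        with pytest.raises(MeshValidationError, match="glabella"):
            LandmarkSet([("glabella", [0, 0, 0]), ("glabella", [1, 1, 1])])

    def test_landmark_correspondence_is_ordered_name_equality(self):
        a = LandmarkSet([("n1", [0, 0, 0]), ("n2", [1, 0, 0])])
        b = LandmarkSet([("n2", [1, 0, 0]), ("n1", [0, 0, 0])])
        assert not a.corresponds_to(b)
        assert a.corresponds_to(a.subset(["n1", "n2"]))

    def test_validate_mesh_reports_issues(self, tiny_mesh):
        assert validate_mesh(tiny_mesh) == []
        degenerate = TriangleMesh(
            [[0, 0, 0], [1, 0, 0], [2, 0, 0]], [[0, 1, 2]]  # collinear, zero area
        )
        issues = validate_mesh(degenerate)
        assert [i.kind for i in issues] == ["degenerate_triangle"]
        # out-of-range index equal to the vertex count
        invalid = TriangleMesh(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 3]], validate=False
        )
        kinds = {i.kind for i in validate_mesh(invalid)}
        assert "index_out_of_range" in kinds
        # unreferenced vertex
        extra = TriangleMesh(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 5]], [[0, 1, 2]]
        )
        assert [i.kind for i in validate_mesh(extra)] == ["unreferenced_vertex"]


# --------------------------------------------------------------------------
# round-trips
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "fmt,ext,tol",
    [
        ("obj", ".obj", 1e-6),
        ("stl_ascii", ".stl", 1e-6),
        ("stl", ".stl", None),  # binary STL is float32 by format definition
        ("ply_ascii", ".ply", 1e-6),
        ("ply", ".ply", 1e-6),
    ],
)
def test_round_trip_phantom(tmp_path, phantom_mesh, fmt, ext, tol):
    """write_mesh -> read_mesh preserves coordinates and connectivity."""
    mesh = submesh_first_triangles(phantom_mesh, 100)
    path = tmp_path / f"m{ext}"
    write_mesh(mesh, path, format=fmt)
    back = read_mesh(path, format="stl" if fmt == "stl_ascii" else fmt.split("_")[0])
    if tol is None:
        tol = 4 * np.finfo(np.float32).eps * np.abs(mesh.vertices).max()
    if "stl" in fmt:
        # STL stores an unindexed soup: shared connectivity is recovered by
        # exact-coordinate merging, so vertex labels follow first-occurrence
        # order; compare geometry triangle by triangle plus merged counts.
        assert back.n_vertices == mesh.n_vertices
        assert back.n_triangles == mesh.n_triangles
        np.testing.assert_allclose(
            back.vertices[back.triangles], mesh.vertices[mesh.triangles], atol=tol, rtol=0
        )
    else:
        np.testing.assert_allclose(back.vertices, mesh.vertices, atol=tol, rtol=0)
        np.testing.assert_array_equal(back.triangles, mesh.triangles)


@pytest.mark.parametrize("fmt", ["obj", "stl", "ply", "ply_ascii"])
def test_trimesh_cross_check(tmp_path, phantom_mesh, fmt):
    """Files we write parse identically under the independent trimesh reader."""
    mesh = submesh_first_triangles(phantom_mesh, 60)
    path = tmp_path / ("m." + ("stl" if "stl" in fmt else "ply" if "ply" in fmt else "obj"))
    write_mesh(mesh, path, format=fmt)
    other = trimesh.load_mesh(str(path), process=False, maintain_order=True)
    if fmt == "stl":  # soup: compare unindexed corner coordinates
        ours = mesh.vertices[mesh.triangles].reshape(-1, 3)
        theirs = other.vertices[other.faces].reshape(-1, 3)
        np.testing.assert_allclose(theirs, ours, atol=1e-5, rtol=0)
    else:
        np.testing.assert_allclose(other.vertices, mesh.vertices, atol=1e-7, rtol=0)
        np.testing.assert_array_equal(other.faces, mesh.triangles)


def test_read_trimesh_written_file(tmp_path, phantom_mesh):
    mesh = submesh_first_triangles(phantom_mesh, 60)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    path = tmp_path / "t.ply"
    tm.export(str(path))
    back = read_mesh(path)
    np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-4, rtol=0)
    np.testing.assert_array_equal(back.triangles, mesh.triangles)


# --------------------------------------------------------------------------
# dialect specifics
# --------------------------------------------------------------------------

class TestObj:
    def test_minimal_parse(self, tmp_path):
        p = tmp_path / "t.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        m = read_mesh(p)
        assert m.n_vertices == 3 and m.n_triangles == 1

    def test_quad_fan_triangulation(self, tmp_path):
        p = tmp_path / "q.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n")
        m = read_mesh(p)
        assert m.triangles.tolist() == [[0, 1, 2], [0, 2, 3]]

    def test_out_of_range_index_names_line(self, tmp_path):
        p = tmp_path / "bad.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 9\n")
        with pytest.raises(MeshFormatError, match=r"bad\.obj:4"):
            read_mesh(p)

    def test_negative_relative_indices(self, tmp_path):
        p = tmp_path / "neg.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf -3 -2 -1\n")
        assert read_mesh(p).triangles.tolist() == [[0, 1, 2]]

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(IOError):
            read_mesh(tmp_path / "absent.obj")


class TestStl:
    def test_ascii_single_triangle(self, tmp_path):
        p = tmp_path / "one.stl"
        p.write_text(
            "solid t\nfacet normal 0 0 1\nouter loop\n"
            "vertex 0 0 0\nvertex 1 0 0\nvertex 0 1 0\n"
            "endloop\nendfacet\nendsolid t\n"
        )
        m = read_mesh(p)
        assert m.n_vertices == 3 and m.n_triangles == 1

    def test_binary_size_is_84_plus_50n(self, tmp_path, phantom_mesh):
        mesh = submesh_first_triangles(phantom_mesh, 37)
        p = tmp_path / "b.stl"
        write_mesh(mesh, p, format="stl")
        assert p.stat().st_size == 84 + 50 * mesh.n_triangles

    def test_truncated_binary_rejected(self, tmp_path):
        p = tmp_path / "trunc.stl"
        p.write_bytes(b"\0" * 80 + struct.pack("<I", 5) + b"\0" * 40)
        with pytest.raises(MeshFormatError, match="truncated"):
            read_mesh(p)


class TestPly:
    def test_color_properties_written_only_when_present(self, tmp_path, tiny_mesh):
        plain = tmp_path / "plain.ply"
        write_mesh(tiny_mesh, plain, format="ply_ascii")
        assert b"red" not in plain.read_bytes()

        colored = tiny_mesh.with_colors([[255, 0, 0]] * 4)
        cpath = tmp_path / "color.ply"
        write_mesh(colored, cpath, format="ply_ascii")
        head = cpath.read_bytes()
        assert b"property uchar red" in head and b"property uchar blue" in head

    @pytest.mark.parametrize("fmt", ["ply", "ply_ascii"])
    def test_colors_round_trip(self, tmp_path, tiny_mesh, fmt):
        colors = np.array([[255, 0, 0], [0, 255, 0], [0, 0, 255], [10, 20, 30]], dtype=np.uint8)
        path = tmp_path / "c.ply"
        write_mesh(tiny_mesh.with_colors(colors), path, format=fmt)
        back = read_mesh(path)
        np.testing.assert_array_equal(back.colors, colors)

    def test_malformed_header_rejected(self, tmp_path):
        p = tmp_path / "bad.ply"
        p.write_text("ply\nformat ascii 1.0\nwhatnot 3\nend_header\n")
        with pytest.raises(MeshFormatError, match="whatnot"):
            read_mesh(p)


# --------------------------------------------------------------------------
# landmarks
# --------------------------------------------------------------------------

class TestLandmarkIO:
    def test_single_landmark(self, tmp_path):
        p = tmp_path / "one.lmk"
        p.write_text("pronasale 0 10 25\n")
        lms = read_landmarks(p)
        assert lms.names == ["pronasale"]
        np.testing.assert_array_equal(lms["pronasale"], [0, 10, 25])

    def test_duplicate_name_rejected(self, tmp_path):
        p = tmp_path / "dup.lmk"
        p.write_text("glabella 0 1 2\nglabella 3 4 5\n")
        with pytest.raises(MeshFormatError, match="duplicate"):
            read_landmarks(p)

    def test_non_numeric_rejected(self, tmp_path):
        p = tmp_path / "nn.lmk"
        p.write_text("glabella a b c\n")
        with pytest.raises(MeshFormatError, match="non-numeric"):
            read_landmarks(p)

    def test_round_trip_phantom_set(self, tmp_path, phantom_landmarks):
        p = tmp_path / "phantom.lmk"
        write_landmarks(phantom_landmarks, p)
        assert read_landmarks(p) == phantom_landmarks
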