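"""Synthetic face phantoms and simulated optical scanners.

No scan data ships with the package; every test and virtual study runs on
phantoms generated here. A phantom is a height field over a curved base —
smooth analytic bumps model the nose, brow, lips and chin, so every
anatomical landmark has an exact analytic surface position. An optional
deformity term (collapse/deflection with a sharp crease, concentrated in a
chosen facial third, by default the lower) emulates the jaw/maxillary
deformities that make optical scanning hard.

A simulated scanner applies, in order: undercut dropout, decimation,
Gaussian noise along vertex normals (the depth-error model of triangulation
scanners), Laplacian smoothing (the optical low-pass), and an unknown rigid
displacement. The true displacement and noise level are recorded so
registration recovery and noise floors can be audited.

All randomness flows from explicit seeds; identical specs give bit-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .geometry import vertex_pseudo_normals
from .io import write_landmarks, write_mesh
from .mesh import LandmarkSet, TriangleMesh
from .transforms import RigidTransform, random_rigid_transform

__all__ = [
    "PhantomSpec",
    "DeformitySpec",
    "ScannerModel",
    "ScanResult",
    "StudyCase",
    "StudyConfig",
    "generate_phantom",
    "flat_patch",
    "simulate_scan",
    "decimate",
    "laplacian_smooth",
    "generate_study",
    "make_study",
    "OverDropoutError",
    "LANDMARK_POSITIONS",
]


class OverDropoutError(RuntimeError):
    """Dropout regions removed more than half of the surface."""


#: Analytic (x, y) landmark positions on the default phantom, mm.
#: x is the lateral axis (subject's right negative), y vertical, z depth.
LANDMARK_POSITIONS = {
    "exocanthion_r": (-45.0, 30.0),
    "exocanthion_l": (45.0, 30.0),
    "endocanthion_r": (-17.0, 30.0),
    "endocanthion_l": (17.0, 30.0),
    "pronasale": (0.0, 8.0),
    "subnasale": (0.0, -6.0),
    "cheilion_r": (-23.0, -28.0),
    "cheilion_l": (23.0, -28.0),
    "pogonion": (0.0, -62.0),
    "glabella": (0.0, 42.0),
}

_REGION_CENTER_Y = {"upper": 55.0, "middle": 15.0, "lower": -45.0}


@dataclass(frozen=True)
class DeformitySpec:
    """A collapse/deflection perturbation concentrated in one facial third.

    ``magnitude_mm`` is the peak inward displacement; ``lateral_offset_mm``
    shifts the deformity off the midline (deflection). The perturbation has
    a broad collapse component plus a sharp crease, so low-pass scanners
    lose part of it.
    """

    region: str = "lower"
    magnitude_mm: float = 0.0
    lateral_offset_mm: float = 0.0

    def __post_init__(self):
        if self.region not in _REGION_CENTER_Y:
            raise ValueError(f"unknown deformity region {self.region!r}")
        if not np.isfinite(self.magnitude_mm):
            raise ValueError("deformity magnitude must be finite")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of an analytic face phantom.

    resolution: vertices per axis of the height-field grid (>= 20).
    width_mm/height_mm: lateral and vertical extent of the face patch.
    nose/brow/lips/chin_mm: bump amplitudes.
    deformity: optional shape perturbation (see :class:`DeformitySpec`).
    seed: recorded provenance tag; generation itself is deterministic.
    """

    resolution: tuple[int, int] = (96, 96)
    width_mm: float = 140.0
    height_mm: float = 170.0
    nose_mm: float = 16.0
    brow_mm: float = 5.0
    lips_mm: float = 3.5
    chin_mm: float = 6.0
    deformity: DeformitySpec | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.resolution) < 20:
            raise ValueError("phantom resolution must be >= 20 per axis")
        for a in (self.nose_mm, self.brow_mm, self.lips_mm, self.chin_mm):
            if not np.isfinite(a):
                raise ValueError("feature amplitudes must be finite")

    # -- the analytic surface ----------------------------------------------

    def height(self, x, y):
        """Analytic depth z(x, y) of the phantom surface, mm."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        z = 42.0 * (1.0 - (x / 105.0) ** 2 - (y / 130.0) ** 2)
        z = z + self.brow_mm * np.exp(-((x / 48.0) ** 2) - (((y - 48.0) / 12.0) ** 2))
        z = z + self.nose_mm * np.exp(-((x / 9.0) ** 2) - (((y - 8.0) / 18.0) ** 2))
        z = z + self.lips_mm * np.exp(-((x / 24.0) ** 2) - (((y + 28.0) / 7.0) ** 2))
        z = z + self.chin_mm * np.exp(-((x / 20.0) ** 2) - (((y + 58.0) / 14.0) ** 2))
        if self.deformity is not None and self.deformity.magnitude_mm != 0.0:
            d = self.deformity
            y0 = _REGION_CENTER_Y[d.region]
            xc = x - d.lateral_offset_mm
            z = z - d.magnitude_mm * np.exp(-((xc / 16.0) ** 2) - (((y - y0) / 14.0) ** 2))
            z = z - 0.6 * d.magnitude_mm * np.exp(-((xc / 4.0) ** 2) - (((y - y0 + 5.0) / 4.0) ** 2))
        return z


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[TriangleMesh, LandmarkSet]:
    """Build the phantom mesh and its landmark set.

    Emits the nine registration landmarks plus glabella (subnasale is shared
    between the registration set and the partition planes), each at its
    exact analytic surface position.
    """
    spec = spec or PhantomSpec()
    nx, ny = spec.resolution
    xs = np.linspace(-spec.width_mm / 2.0, spec.width_mm / 2.0, nx)
    ys = np.linspace(-spec.height_mm / 2.0 - 10.0, spec.height_mm / 2.0 - 10.0, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gz = spec.height(gx, gy)
    vertices = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    triangles = _grid_triangles(nx, ny)
    mesh = TriangleMesh(vertices, triangles)
    lms = LandmarkSet(
        [
            (name, np.array([x, y, float(spec.height(x, y))]))
            for name, (x, y) in LANDMARK_POSITIONS.items()
        ]
    )
    return mesh, lms


def _grid_triangles(nx: int, ny: int) -> np.ndarray:
    i, j = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    v00 = (i * ny + j).ravel()
    v01 = v00 + 1
    v10 = v00 + ny
    v11 = v10 + 1
    return np.concatenate(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )


def flat_patch(n: int = 145, spacing_mm: float = 5.0, z: float = 0.0) -> TriangleMesh:
    """A flat n-by-n square grid at height ``z`` — the standard fixture for
    noise-floor and uniform-offset checks."""
    xs = np.arange(n, dtype=np.float64) * spacing_mm
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    v = np.column_stack([gx.ravel(), gy.ravel(), np.full(n * n, float(z))])
    return TriangleMesh(v, _grid_triangles(n, n))


# --------------------------------------------------------------------------
# Scanner simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScannerModel:
    """Degradation model of one optical scanner.

    noise_sigma_mm: Gaussian depth noise along vertex normals.
    smoothing_iterations / smoothing_lambda: Laplacian low-pass passes.
    decimate_target: triangle-count target (None = keep full resolution).
    dropout_boxes: (xmin, xmax, ymin, ymax) regions, in phantom coordinates,
        removed before anything else (optical undercut shadowing).
    landmark_sigma_mm: digitization jitter added to carried landmarks.
    displacement: explicit rigid displacement, or None to draw one of
        magnitude <= displacement_max_deg / displacement_max_mm per scan.
    """

    name: str = "scanner"
    noise_sigma_mm: float = 0.0
    smoothing_iterations: int = 0
    smoothing_lambda: float = 0.5
    decimate_target: int | None = None
    dropout_boxes: tuple[tuple[float, float, float, float], ...] = ()
    landmark_sigma_mm: float = 0.0
    displacement: RigidTransform | None = None
    displacement_max_deg: float = 10.0
    displacement_max_mm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma_mm < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.decimate_target is not None and self.decimate_target < 100:
            raise ValueError("decimation target must be >= 100 triangles")


@dataclass
class ScanResult:
    """A simulated scan plus the ground truth needed to audit it."""

    mesh: TriangleMesh
    landmarks: LandmarkSet
    applied_displacement: RigidTransform
    noise_sigma_mm: float
    model_name: str


def simulate_scan(
    truth: TriangleMesh,
    landmarks: LandmarkSet,
    model: ScannerModel,
    rng: np.random.Generator | None = None,
) -> ScanResult:
    """Degrade a ground-truth surface the way ``model`` prescribes.

    Stages run in order dropout -> decimation -> noise -> smoothing -> rigid
    displacement; landmarks ride through the displacement and receive their
    own jitter.
    """
    rng = rng or np.random.default_rng(model.seed)
    mesh = truth

    if model.dropout_boxes:
        area_before = mesh.area()
        keep = np.ones(mesh.n_vertices, dtype=bool)
        x, y = mesh.vertices[:, 0], mesh.vertices[:, 1]
        for xmin, xmax, ymin, ymax in model.dropout_boxes:
            keep &= ~((x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax))
        mesh = mesh.submesh(keep)
        if mesh.n_triangles == 0 or mesh.area() < 0.5 * area_before:
            raise OverDropoutError("dropout regions removed more than 50% of the surface")

    if model.decimate_target is not None and model.decimate_target < mesh.n_triangles:
        mesh = decimate(mesh, model.decimate_target)

    if model.noise_sigma_mm > 0.0:
        normals = vertex_pseudo_normals(mesh)
        offsets = rng.normal(0.0, model.noise_sigma_mm, size=mesh.n_vertices)
        mesh = TriangleMesh(
            mesh.vertices + offsets[:, None] * normals, mesh.triangles, validate=False
        )

    if model.smoothing_iterations > 0:
        mesh = laplacian_smooth(mesh, model.smoothing_iterations, model.smoothing_lambda)

    displacement = model.displacement
    if displacement is None:
        displacement = random_rigid_transform(
            rng, model.displacement_max_deg, model.displacement_max_mm
        )
    mesh = TriangleMesh(displacement.apply(mesh.vertices), mesh.triangles, validate=False)
    lm_pts = displacement.apply(landmarks.points)
    if model.landmark_sigma_mm > 0.0:
        lm_pts = lm_pts + rng.normal(0.0, model.landmark_sigma_mm, size=lm_pts.shape)
    scan_lms = LandmarkSet(list(zip(landmarks.names, lm_pts)))
    return ScanResult(
        mesh=mesh,
        landmarks=scan_lms,
        applied_displacement=displacement,
        noise_sigma_mm=model.noise_sigma_mm,
        model_name=model.name,
    )


def laplacian_smooth(mesh: TriangleMesh, iterations: int, lam: float = 0.5) -> TriangleMesh:
    """Uniform-weight Laplacian smoothing (shrinks the surface slightly,
    like an optical low-pass)."""
    t = mesh.triangles
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    n = mesh.n_vertices
    data = np.ones(2 * len(edges))
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    v = mesh.vertices.copy()
    for _ in range(iterations):
        v = v + lam * (adj @ v / deg[:, None] - v)
    return TriangleMesh(v, t, validate=False)


def decimate(mesh: TriangleMesh, target_triangles: int) -> TriangleMesh:
    """Reduce triangle count by deterministic grid vertex clustering.

    The clustering cell size is bisected until the triangle count lands
    within ~10% of the target (or the bisection exhausts). Cluster
    representatives are coordinate means; collapsed (degenerate) triangles
    are dropped.
    """
    if target_triangles >= mesh.n_triangles:
        return mesh

    lo, hi = 1e-3, mesh.diameter()
    best: TriangleMesh | None = None
    best_err = np.inf
    for _ in range(40):
        cell = 0.5 * (lo + hi)
        candidate = _cluster_decimate(mesh, cell)
        err = abs(candidate.n_triangles - target_triangles)
        if err < best_err:
            best, best_err = candidate, err
        if candidate.n_triangles > target_triangles:
            lo = cell
        else:
            hi = cell
        if err <= 0.1 * target_triangles:
            break
    assert best is not None
    return best


def _cluster_decimate(mesh: TriangleMesh, cell: float) -> TriangleMesh:
    v = mesh.vertices
    keys = np.floor((v - v.min(axis=0)) / cell).astype(np.int64)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    counts = np.bincount(inverse)
    centers = np.zeros((len(uniq), 3))
    np.add.at(centers, inverse, v)
    centers /= counts[:, None]
    tris = inverse[mesh.triangles]
    ok = (tris[:, 0] != tris[:, 1]) & (tris[:, 1] != tris[:, 2]) & (tris[:, 0] != tris[:, 2])
    tris = np.unique(tris[ok], axis=0)
    if len(tris) == 0:
        return TriangleMesh(centers[:1], np.zeros((0, 3), dtype=np.int64), validate=False)
    return TriangleMesh(centers, tris, validate=False).submesh(
        np.ones(len(centers), dtype=bool)
    )


# --------------------------------------------------------------------------
# Virtual studies
# --------------------------------------------------------------------------

@dataclass
class StudyCase:
    """One virtual patient: the analytic truth plus three simulated scans."""

    case_id: str
    truth_mesh: TriangleMesh
    truth_landmarks: LandmarkSet
    reference: ScanResult
    scans: dict[str, ScanResult]  # scanner label ('A', 'B') -> scan
    deformity: DeformitySpec | None


@dataclass
class StudyConfig:
    """Design of a multi-case virtual study.

    The default geometry is desk-scale: a 96x96 truth grid (~18k triangles)
    standing in for the ~200k-triangle reference and ~40-60k-triangle test
    scans of a clinical acquisition; the reference scanner keeps full
    resolution at near-zero noise while test scanners are noisier, smoothed
    and decimated. Cases emulate a deformity-patient cohort:
    ``deformity_magnitude_range`` draws a per-case lower-face collapse
    ((0, 0) disables deformities — a null study) and ``shape_variation``
    jitters the facial feature amplitudes between cases.
    """

    n_cases: int = 10
    resolution: tuple[int, int] = (96, 96)
    deformity_magnitude_range: tuple[float, float] = (3.0, 8.0)
    deformity_region: str = "lower"
    shape_variation: float = 0.2  # per-case fractional jitter of feature amplitudes
    reference_model: ScannerModel = field(
        default_factory=lambda: ScannerModel(
            name="reference", noise_sigma_mm=0.05, displacement_max_deg=0.0,
            displacement_max_mm=0.0,
        )
    )
    test_models: dict[str, ScannerModel] = field(
        default_factory=lambda: {
            "A": ScannerModel(
                name="stereophotography", noise_sigma_mm=0.4, smoothing_iterations=2,
                decimate_target=6000, landmark_sigma_mm=0.5,
                displacement_max_deg=8.0, displacement_max_mm=8.0,
            ),
            "B": ScannerModel(
                name="structured_light", noise_sigma_mm=0.4, smoothing_iterations=2,
                decimate_target=4000, landmark_sigma_mm=0.5,
                displacement_max_deg=8.0, displacement_max_mm=8.0,
            ),
        }
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1:
            raise ValueError("a study needs at least one case")


def generate_study(config: StudyConfig | None = None) -> list[StudyCase]:
    """Generate an in-memory virtual study (one phantom + 3 scans per case)."""
    config = config or StudyConfig()
    root_rng = np.random.default_rng(config.seed)
    cases = []
    base = PhantomSpec()
    for c in range(config.n_cases):
        case_rng = np.random.default_rng(root_rng.integers(2**31))
        lo, hi = config.deformity_magnitude_range
        deformity = None
        if hi > 0.0:
            deformity = DeformitySpec(
                region=config.deformity_region,
                magnitude_mm=float(case_rng.uniform(lo, hi)),
                lateral_offset_mm=float(case_rng.uniform(-10.0, 10.0)),
            )
        sv = config.shape_variation

        def jitter(amplitude: float) -> float:
            return float(amplitude * (1.0 + case_rng.uniform(-sv, sv))) if sv > 0 else amplitude

        spec = PhantomSpec(
            resolution=config.resolution,
            nose_mm=jitter(base.nose_mm), brow_mm=jitter(base.brow_mm),
            lips_mm=jitter(base.lips_mm), chin_mm=jitter(base.chin_mm),
            deformity=deformity, seed=config.seed + c,
        )
        truth, lms = generate_phantom(spec)
        reference = simulate_scan(truth, lms, config.reference_model, rng=case_rng)
        scans = {
            label: simulate_scan(truth, lms, model, rng=case_rng)
            for label, model in config.test_models.items()
        }
        cases.append(
            StudyCase(
                case_id=f"case{c:03d}",
                truth_mesh=truth,
                truth_landmarks=lms,
                reference=reference,
                scans=scans,
                deformity=deformity,
            )
        )
    return cases


def make_study(out_dir, config: StudyConfig | None = None) -> Path:
    """Write a virtual study to disk (meshes, landmarks, ground-truth
    transforms, manifest) in a layout the CLI pipeline consumes."""
    config = config or StudyConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cases = generate_study(config)
    manifest = {
        "n_cases": config.n_cases,
        "seed": config.seed,
        "resolution": list(config.resolution),
        "deformity_magnitude_range": list(config.deformity_magnitude_range),
        "reference_model": _model_dict(config.reference_model),
        "test_models": {k: _model_dict(m) for k, m in config.test_models.items()},
        "cases": [],
    }
    for case in cases:
        cdir = out / case.case_id
        cdir.mkdir(exist_ok=True)
        write_mesh(case.truth_mesh, cdir / "truth.ply")
        write_landmarks(case.truth_landmarks, cdir / "truth.lmk")
        write_mesh(case.reference.mesh, cdir / "face_r.ply")
        write_landmarks(case.reference.landmarks, cdir / "face_r.lmk")
        truths = {"reference": case.reference.applied_displacement.to_dict()}
        for label, scan in case.scans.items():
            write_mesh(scan.mesh, cdir / f"face_{label.lower()}.ply")
            write_landmarks(scan.landmarks, cdir / f"face_{label.lower()}.lmk")
            truths[label] = scan.applied_displacement.to_dict()
        with open(cdir / "ground_truth.json", "w") as fh:
            json.dump(truths, fh, indent=2)
        manifest["cases"].append(
            {
                "case_id": case.case_id,
                "deformity": None if case.deformity is None else asdict(case.deformity),
                "scanners": sorted(case.scans),
            }
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def null_study_config(seed: int, resolution: tuple[int, int] = (20, 20),
                      n_cases: int = 10) -> StudyConfig:
    """An all-null study: the two test scanners share identical parameters
    (only their noise realizations differ), no deformities.

    Under this design any systematic A-vs-B difference is spurious, so the
    paired t-tests should reject at their nominal rate. The reduced
    resolution keeps replicate batteries cheap; exchangeability between the
    scanners — the property being calibrated — does not depend on it.
    """
    mk = lambda name: ScannerModel(
        name=name, noise_sigma_mm=0.4, smoothing_iterations=1,
        landmark_sigma_mm=0.5, displacement_max_deg=8.0, displacement_max_mm=8.0,
    )
    return StudyConfig(
        n_cases=n_cases, resolution=resolution, seed=seed,
        deformity_magnitude_range=(0.0, 0.0),
        reference_model=ScannerModel(
            name="reference", noise_sigma_mm=0.05,
            displacement_max_deg=0.0, displacement_max_mm=0.0,
        ),
        test_models={"A": mk("stereophotography"), "B": mk("structured_light")},
    )


#: Undercut dropout band below the lower lip (labiofacial sulcus region),
#: in phantom coordinates: optical line-of-sight shadowing of the deformed
#: lower face.
LOWER_FACE_DROPOUT = ((-20.0, 20.0, -52.0, -38.0),)


def deformity_study_config(seed: int, resolution: tuple[int, int] = (32, 32),
                           magnitude_range: tuple[float, float] = (4.0, 8.0),
                           n_cases: int = 10) -> StudyConfig:
    """A study of lower-face deformity patients.

    Each case draws a lower-third collapse of ``magnitude_range`` mm with a
    sharp crease; the test scanners additionally lose the undercut band
    below the lower lip and low-pass the surface, so the lower third scans
    worse than the middle — the qualitative pattern the evaluation method
    is meant to expose.
    """
    mk = lambda name: ScannerModel(
        name=name, noise_sigma_mm=0.4, smoothing_iterations=2,
        dropout_boxes=LOWER_FACE_DROPOUT, landmark_sigma_mm=0.5,
        displacement_max_deg=8.0, displacement_max_mm=8.0,
    )
    return StudyConfig(
        n_cases=n_cases, resolution=resolution, seed=seed,
        deformity_magnitude_range=magnitude_range, deformity_region="lower",
        reference_model=ScannerModel(
            name="reference", noise_sigma_mm=0.05,
            displacement_max_deg=0.0, displacement_max_mm=0.0,
        ),
        test_models={"A": mk("stereophotography"), "B": mk("structured_light")},
    )


def _model_dict(model: ScannerModel) -> dict:
    d = asdict(model)
    if model.displacement is not None:
        d["displacement"] = model.displacement.to_dict()
    return d
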