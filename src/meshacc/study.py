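"""End-to-end accuracy evaluation: register, trim, partition, measure.

For each case the pipeline aligns every test scan onto the reference scan
(landmark pre-alignment + ICP), trims all surfaces to the shared boundary,
splits them into facial thirds in the reference's NHP frame, and computes
the RMS "3D error" globally and per third — yielding the eight
scanner-by-region groups the statistical battery consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .deviation import ColorMapSpec, compute_deviation
from .geometry import MeshIndex
from .io import read_landmarks, read_mesh
from .mesh import LandmarkSet, TriangleMesh
from .partition import TrimBoundary, build_nhp_frame, split_thirds, trim_common
from .registration import (
    DEFAULT_REGISTRATION_LANDMARKS,
    ICPParams,
    ICPResult,
    apply_transform,
    icp_refine,
    landmark_rigid_align,
)
from .stats import BatteryReport, StudyTable, run_battery
from .phantom import StudyCase

__all__ = [
    "AnalysisConfig",
    "CaseComparison",
    "StudyAnalysis",
    "register_pair",
    "analyze_pair",
    "analyze_case",
    "analyze_study",
    "load_study_cases",
]


@dataclass
class AnalysisConfig:
    """Knobs of the evaluation pipeline.

    exclusion_mm: the deviation band; pairs beyond it leave the RMS.
    overlap_mm: mutual-overlap trim distance applied to each compared pair.
    registration_landmarks: the corresponding landmarks used for coarse
        alignment (subset shared by both landmark files is required).
    """

    icp: ICPParams = field(default_factory=ICPParams)
    exclusion_mm: float = 5.0
    overlap_mm: float = 10.0
    clip_planes: list = field(default_factory=list)
    registration_landmarks: list[str] = field(
        default_factory=lambda: list(DEFAULT_REGISTRATION_LANDMARKS)
    )

    @classmethod
    def fast(cls) -> "AnalysisConfig":
        """Settings for replicated simulation studies: few ICP iterations at
        a loose tolerance (alignment quality saturates quickly at the small
        phantom resolutions these studies use)."""
        return cls(icp=ICPParams(max_iterations=6, tol=1e-3))


@dataclass
class CaseComparison:
    """All RMS numbers of one reference-vs-test comparison."""

    scanner: str
    rms_global: float
    rms_upper: float
    rms_middle: float
    rms_lower: float
    n_excluded_global: int
    icp: ICPResult

    def by_region(self) -> dict[str, float]:
        return {
            "global": self.rms_global,
            "upper": self.rms_upper,
            "middle": self.rms_middle,
            "lower": self.rms_lower,
        }


def register_pair(
    fixed_mesh: TriangleMesh,
    fixed_lms: LandmarkSet,
    floating_mesh: TriangleMesh,
    floating_lms: LandmarkSet,
    config: AnalysisConfig | None = None,
    fixed_index: MeshIndex | None = None,
) -> tuple[TriangleMesh, ICPResult]:
    """Landmark pre-alignment followed by ICP; returns the aligned floating
    mesh and the ICP diagnostics."""
    config = config or AnalysisConfig()
    names = [n for n in config.registration_landmarks if n in fixed_lms and n in floating_lms]
    init = landmark_rigid_align(fixed_lms.subset(names), floating_lms.subset(names))
    icp = icp_refine(fixed_mesh, floating_mesh, init=init, params=config.icp, fixed_index=fixed_index)
    return apply_transform(floating_mesh, icp.transform), icp


def analyze_pair(
    reference_mesh: TriangleMesh,
    reference_lms: LandmarkSet,
    test_mesh: TriangleMesh,
    test_lms: LandmarkSet,
    scanner: str = "A",
    config: AnalysisConfig | None = None,
) -> CaseComparison:
    """Full evaluation of one test scan against one reference scan."""
    config = config or AnalysisConfig()
    ref_index = MeshIndex(reference_mesh)
    aligned, icp = register_pair(
        reference_mesh, reference_lms, test_mesh, test_lms, config, fixed_index=ref_index
    )
    boundary = TrimBoundary(planes=list(config.clip_planes), overlap_mm=config.overlap_mm)
    ref_trim, test_trim = trim_common([reference_mesh, aligned], boundary)

    frame = build_nhp_frame(reference_lms)
    glabella = reference_lms["glabella"]
    subnasale = reference_lms["subnasale"]
    ref_parts = split_thirds(ref_trim, frame, glabella, subnasale)
    test_parts = split_thirds(test_trim, frame, glabella, subnasale)

    spec = ColorMapSpec(limit_mm=config.exclusion_mm)
    global_dev = compute_deviation(ref_trim, test_trim, spec)
    part_rms = {}
    for label in ("upper", "middle", "lower"):
        part_rms[label] = compute_deviation(
            ref_parts[label], test_parts[label], spec, signed=False
        ).rms
    return CaseComparison(
        scanner=scanner,
        rms_global=global_dev.rms,
        rms_upper=part_rms["upper"],
        rms_middle=part_rms["middle"],
        rms_lower=part_rms["lower"],
        n_excluded_global=global_dev.n_excluded,
        icp=icp,
    )


def analyze_case(case: StudyCase, config: AnalysisConfig | None = None) -> dict[str, CaseComparison]:
    """Evaluate every test scanner of a virtual-study case against its
    reference scan."""
    config = config or AnalysisConfig()
    out = {}
    for label, scan in sorted(case.scans.items()):
        out[label] = analyze_pair(
            case.reference.mesh,
            case.reference.landmarks,
            scan.mesh,
            scan.landmarks,
            scanner=label,
            config=config,
        )
    return out


@dataclass
class StudyAnalysis:
    table: StudyTable
    battery: BatteryReport
    comparisons: dict[str, dict[str, CaseComparison]]  # case id -> scanner -> result

    def to_dict(self) -> dict:
        return {
            "table": self.table.data.rename_axis("case").reset_index().to_dict(orient="records"),
            "battery": self.battery.to_dict(),
        }


def analyze_study(cases: list[StudyCase], config: AnalysisConfig | None = None,
                  run_stats: bool = True) -> StudyAnalysis:
    """Run the pipeline over all cases and (optionally) the statistical
    battery over the resulting 8-group table."""
    config = config or AnalysisConfig()
    rows = {}
    comparisons = {}
    for case in cases:
        per_scanner = analyze_case(case, config)
        comparisons[case.case_id] = per_scanner
        row = {}
        for label, comp in per_scanner.items():
            row[label] = comp.rms_global
            row[label + "U"] = comp.rms_upper
            row[label + "M"] = comp.rms_middle
            row[label + "L"] = comp.rms_lower
        rows[case.case_id] = row
    table = StudyTable(pd.DataFrame.from_dict(rows, orient="index"))
    battery = run_battery(table) if run_stats else None
    return StudyAnalysis(table=table, battery=battery, comparisons=comparisons)


def load_study_cases(study_dir) -> list[StudyCase]:
    """Load a study written by :func:`meshacc.phantom.make_study`."""
    from .phantom import DeformitySpec, ScanResult  # local import to avoid cycle at module load
    from .transforms import RigidTransform

    root = Path(study_dir)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    cases = []
    for entry in manifest["cases"]:
        cdir = root / entry["case_id"]
        with open(cdir / "ground_truth.json") as fh:
            truths = json.load(fh)
        reference = ScanResult(
            mesh=read_mesh(cdir / "face_r.ply"),
            landmarks=read_landmarks(cdir / "face_r.lmk"),
            applied_displacement=RigidTransform.from_dict(truths["reference"]),
            noise_sigma_mm=manifest["reference_model"]["noise_sigma_mm"],
            model_name=manifest["reference_model"]["name"],
        )
        scans = {}
        for label in entry["scanners"]:
            scans[label] = ScanResult(
                mesh=read_mesh(cdir / f"face_{label.lower()}.ply"),
                landmarks=read_landmarks(cdir / f"face_{label.lower()}.lmk"),
                applied_displacement=RigidTransform.from_dict(truths[label]),
                noise_sigma_mm=manifest["test_models"][label]["noise_sigma_mm"],
                model_name=manifest["test_models"][label]["name"],
            )
        cases.append(
            StudyCase(
                case_id=entry["case_id"],
                truth_mesh=read_mesh(cdir / "truth.ply"),
                truth_landmarks=read_landmarks(cdir / "truth.lmk"),
                reference=reference,
                scans=scans,
                deformity=None if entry["deformity"] is None else DeformitySpec(**entry["deformity"]),
            )
        )
    return cases
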