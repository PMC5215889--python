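"""Two-stage rigid registration of a test (floating) scan onto a reference.

Stage 1 appoints corresponding anatomical landmarks on both surfaces and
solves the closed-form least-squares rigid transform (no scaling). Stage 2
refines with iterative closest point (ICP): floating vertices are matched to
their nearest points on the *surface* of the fixed mesh (not to its
vertices, since scan densities differ by factors of 3-5), far pairs are
rejected, and the closed-form rigid update is applied until the objective
stalls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import MeshIndex
from .mesh import LandmarkSet, TriangleMesh
from .transforms import RigidTransform, kabsch

__all__ = [
    "RegistrationError",
    "DegenerateConfigurationError",
    "CorrespondenceError",
    "ICPParams",
    "ICPResult",
    "landmark_rigid_align",
    "apply_transform",
    "icp_refine",
    "DEFAULT_REGISTRATION_LANDMARKS",
]

log = logging.getLogger(__name__)

#: The nine corresponding landmarks used for coarse alignment by default.
DEFAULT_REGISTRATION_LANDMARKS = [
    "exocanthion_r",
    "exocanthion_l",
    "endocanthion_r",
    "endocanthion_l",
    "pronasale",
    "subnasale",
    "cheilion_r",
    "cheilion_l",
    "pogonion",
]


class RegistrationError(RuntimeError):
    """Registration failed (no usable correspondences / non-finite objective)."""


class DegenerateConfigurationError(RegistrationError):
    """Landmark configuration does not pin down a rigid transform."""


class CorrespondenceError(RegistrationError):
    """The two landmark sets do not correspond (name lists differ)."""


def landmark_rigid_align(fixed: LandmarkSet, floating: LandmarkSet) -> RigidTransform:
    """Least-squares rigid transform taking floating landmarks onto fixed.

    Exact (machine precision) for noise-free corresponding sets. Requires at
    least three non-collinear landmarks with identical ordered name lists.
    """
    if not fixed.corresponds_to(floating):
        raise CorrespondenceError(
            f"landmark sets do not correspond: {fixed.names} vs {floating.names}"
        )
    if len(fixed) < 3:
        raise DegenerateConfigurationError(
            f"need >= 3 landmarks to align, got {len(fixed)}"
        )
    P = floating.points
    centered = P - P.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateConfigurationError("landmarks are collinear (or coincident)")
    return kabsch(P, fixed.points)


def apply_transform(mesh: TriangleMesh, transform: RigidTransform) -> TriangleMesh:
    """Map every vertex through the rigid transform; connectivity unchanged."""
    return TriangleMesh(
        transform.apply(mesh.vertices), mesh.triangles, mesh.colors, validate=False
    )


@dataclass
class ICPParams:
    """ICP settings.

    rejection_mm: correspondence pairs farther than this are discarded each
        iteration (guards against boundary/hair outliers; distinct from the
        5 mm analysis exclusion band).
    tol: relative objective-change convergence threshold.
    abs_tol_mm: absolute objective floor counting as converged immediately.
    max_sample: floating vertices used; all vertices up to this cap, then a
        seeded uniform subsample for determinism.
    """

    max_iterations: int = 100
    tol: float = 1e-6
    rejection_mm: float = 10.0
    max_sample: int = 50_000
    abs_tol_mm: float = 1e-9
    seed: int = 0


@dataclass
class ICPResult:
    transform: RigidTransform
    iterations: int
    objective_trace: list[float]
    converged: bool

    @property
    def final_objective(self) -> float:
        return self.objective_trace[-1]


def icp_refine(
    fixed: TriangleMesh,
    floating: TriangleMesh,
    init: RigidTransform | None = None,
    params: ICPParams | None = None,
    fixed_index: MeshIndex | None = None,
) -> ICPResult:
    """Refine a rigid alignment of ``floating`` onto the surface of ``fixed``.

    Each iteration matches a fixed subsample of floating vertices to their
    exact nearest points on the fixed surface, drops pairs beyond the
    rejection threshold, and applies the closed-form rigid update. The
    objective is the RMS of accepted correspondence distances (mm).
    """
    params = params or ICPParams()
    transform = init or RigidTransform.identity()
    index = fixed_index or MeshIndex(fixed)

    pts = floating.vertices
    if len(pts) > params.max_sample:
        rng = np.random.default_rng(params.seed)
        sel = rng.choice(len(pts), size=params.max_sample, replace=False)
        pts = pts[np.sort(sel)]

    trace: list[float] = []
    converged = False
    prev = np.inf
    iteration = 0
    for iteration in range(1, params.max_iterations + 1):
        moved = transform.apply(pts)
        res = index.query(moved)
        accept = res.distances <= params.rejection_mm
        if not accept.any():
            raise RegistrationError(
                f"ICP iteration {iteration}: all correspondences beyond "
                f"{params.rejection_mm} mm rejection threshold"
            )
        rms = float(np.sqrt(np.mean(res.distances[accept] ** 2)))
        if not np.isfinite(rms):
            raise RegistrationError(f"ICP iteration {iteration}: non-finite objective")
        trace.append(rms)
        log.info("ICP iteration %d: rms %.6f mm (%d/%d pairs)", iteration, rms, accept.sum(), len(pts))
        if rms <= params.abs_tol_mm or (
            np.isfinite(prev) and abs(prev - rms) <= params.tol * max(prev, 1e-300)
        ):
            converged = True
            break
        prev = rms
        # closed-form update mapping original floating coords onto matches
        transform = kabsch(pts[accept], res.points[accept])
    return ICPResult(transform=transform, iterations=iteration, objective_trace=trace, converged=converged)
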