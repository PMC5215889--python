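"""Whole-surface deviation between a reference and a registered test scan.

For every vertex P_i of the reference surface the nearest point P_i' on the
test surface is found; X_i = ||P_i - P_i'|| is the pair's distance. Pairs
beyond the exclusion band (default 5 mm, the same band that clips the color
map) are dropped, and the "3D error" is the root mean square over the N
retained pairs:

    RMS = sqrt( (X_1^2 + X_2^2 + ... + X_N^2) / N )

Deviations are always sampled from reference vertices onto the test surface;
swap the arguments for the reverse direction. Signed distances carry the
sign of (P_i - P_i') . n̂(P_i') with n̂ the angle-weighted pseudo-normal of
the test surface, so "positive" means the reference lies on the outward side
of the test surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MeshIndex
from .mesh import TriangleMesh

__all__ = [
    "ColorMapSpec",
    "DeviationResult",
    "NoOverlapError",
    "compute_deviation",
    "colorize",
]


class NoOverlapError(RuntimeError):
    """Every point pair fell outside the exclusion band."""


@dataclass(frozen=True)
class ColorMapSpec:
    """Deviation color map: +/- ``limit_mm`` ramp, black outside the band.

    The band both clips the color display and excludes pairs from the RMS.
    Ramp (piecewise linear in u = d / limit_mm):
      u = -1 -> blue (0,0,255); u = 0 -> green (0,255,0);
      u = +0.5 -> yellow (255,255,0); u = +1 -> red (255,0,0);
      |u| > 1 (excluded) -> black.
    """

    limit_mm: float = 5.0

    def __post_init__(self):
        if self.limit_mm <= 0:
            raise ValueError("color map range limit must be positive")


@dataclass
class DeviationResult:
    """Per-reference-vertex deviation field plus the RMS summary."""

    reference_points: np.ndarray  # (n, 3) P_i
    matched_points: np.ndarray  # (n, 3) P_i'
    distances: np.ndarray  # (n,) X_i >= 0, mm
    signed_distances: np.ndarray  # (n,) d_i with |d_i| = X_i
    excluded: np.ndarray  # (n,) bool, X_i > limit
    limit_mm: float
    n_included: int
    rms: float  # mm, over included pairs

    @property
    def n_excluded(self) -> int:
        return int(self.excluded.sum())

    def mean_signed(self) -> float:
        return float(self.signed_distances[~self.excluded].mean())

    def histogram(self, bins: int = 40) -> dict:
        counts, edges = np.histogram(
            self.signed_distances[~self.excluded], bins=bins,
            range=(-self.limit_mm, self.limit_mm),
        )
        return {"counts": counts.tolist(), "edges": edges.tolist()}

    def summary(self) -> dict:
        return {
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "rms_mm": self.rms,
            "rms_mm_reported": round(self.rms, 2),
            "mean_signed_mm": self.mean_signed(),
            "limit_mm": self.limit_mm,
        }


def compute_deviation(
    reference: TriangleMesh,
    test: TriangleMesh,
    spec: ColorMapSpec | None = None,
    test_index: MeshIndex | None = None,
    signed: bool = True,
) -> DeviationResult:
    """Deviation field from reference vertices onto the test surface.

    The meshes must already be registered; no transform is applied here.
    Raises :class:`NoOverlapError` if every pair exceeds the band.
    ``signed=False`` skips the pseudo-normal sign pass (the RMS only needs
    magnitudes); the signed field then holds the unsigned distances.
    """
    spec = spec or ColorMapSpec()
    index = test_index or MeshIndex(test)
    p = reference.vertices
    res = index.query(p)
    signed_d = res.signed_distances(p) if signed else res.distances.copy()
    excluded = res.distances > spec.limit_mm
    n_included = int((~excluded).sum())
    if n_included == 0:
        raise NoOverlapError(
            f"all {len(p)} point pairs exceed the {spec.limit_mm} mm band: no overlap"
        )
    rms = float(np.sqrt(np.sum(res.distances[~excluded] ** 2) / n_included))
    return DeviationResult(
        reference_points=p,
        matched_points=res.points,
        distances=res.distances,
        signed_distances=signed_d,
        excluded=excluded,
        limit_mm=spec.limit_mm,
        n_included=n_included,
        rms=rms,
    )


def colorize(result: DeviationResult, spec: ColorMapSpec | None = None) -> np.ndarray:
    """Per-reference-vertex RGB colors for the deviation map.

    Negative deviations ramp green -> blue, positive green -> yellow -> red,
    excluded vertices are black. Returns a (n, 3) uint8 array suitable for
    ``TriangleMesh.with_colors``.
    """
    spec = spec or ColorMapSpec(limit_mm=result.limit_mm)
    u = np.clip(result.signed_distances / spec.limit_mm, -1.0, 1.0)
    r = np.zeros_like(u)
    g = np.zeros_like(u)
    b = np.zeros_like(u)
    neg = u < 0.0
    g[neg] = 1.0 + u[neg]
    b[neg] = -u[neg]
    lo = ~neg & (u <= 0.5)
    r[lo] = 2.0 * u[lo]
    g[lo] = 1.0
    hi = u > 0.5
    r[hi] = 1.0
    g[hi] = 2.0 - 2.0 * u[hi]
    colors = np.stack([r, g, b], axis=1)
    colors = np.round(colors * 255.0).astype(np.uint8)
    colors[result.excluded] = 0
    return colors
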