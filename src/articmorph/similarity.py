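"""Curvature similarity between opposing articular surfaces.

For a joint with cuneiform-side and metatarsal-side signed Gaussian
curvatures ``k_cun`` and ``k_met`` the similarity is

    s = -sign(k_cun * k_met) / (1 + |log |k_cun / k_met||)

so that ``s = +1`` for equal magnitudes with matched curvature (one concave
and one convex surface), ``s = -1`` for equal magnitudes with mismatched
curvature (two concave or two convex), and ``|s| -> 0`` as the magnitudes
diverge.  The natural log is the default; the base only sets the decay rate
of ``|s|`` with the magnitude ratio, never the +-1 landmarks.

If either curvature is numerically zero the measure carries no information
(the statistic is known to be of limited use on nearly flat regions) and 0 is
returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .curvature import CurvatureField, region_mean_curvature
from .frames import AnatomicFrame
from .mesh_core import SurfacePatch
from .morphometry import QUADRANTS, quadrant_split

__all__ = ["SimilarityResult", "curvature_similarity", "joint_similarity"]

_EPS = 1e-9

REGIONS = ("whole",) + QUADRANTS


@dataclass(frozen=True)
class SimilarityResult:
    """Similarity of one joint region, with the two curvatures that made it."""

    joint: str
    region: str
    k_cun: float | None
    k_met: float | None
    value: float | None

    @property
    def absent(self) -> bool:
        return self.value is None


def curvature_similarity(
    k_cun: float, k_met: float, log_base: float = math.e, eps: float = _EPS
) -> float:
    """Similarity in [-1, 1] of two signed Gaussian curvatures."""
    if not (math.isfinite(k_cun) and math.isfinite(k_met)):
        raise ValueError("curvatures must be finite")
    if abs(k_cun) < eps or abs(k_met) < eps:
        return 0.0
    ratio = abs(math.log(abs(k_cun / k_met), log_base))
    return -math.copysign(1.0, k_cun * k_met) / (1.0 + ratio)


def joint_similarity(
    cun_patch: SurfacePatch,
    cun_field: CurvatureField,
    cun_frame: AnatomicFrame,
    met_patch: SurfacePatch,
    met_field: CurvatureField,
    met_frame: AnatomicFrame,
    joint: str = "TMT1",
    log_base: float = math.e,
) -> list[SimilarityResult]:
    """Similarity for the whole joint and its four quadrant pairs.

    Quadrants are paired by identical anatomical label.  A quadrant missing
    on either side yields an absent result rather than an error.
    """
    results = []
    cun_regions = {"whole": cun_patch, **quadrant_split(cun_patch, cun_frame, strict=False)}
    met_regions = {"whole": met_patch, **quadrant_split(met_patch, met_frame, strict=False)}
    for region in REGIONS:
        cp, mp = cun_regions.get(region), met_regions.get(region)
        if cp is None or mp is None or len(cp) == 0 or len(mp) == 0:
            results.append(SimilarityResult(joint, region, None, None, None))
            continue
        k_cun = region_mean_curvature(cun_field, cp)
        k_met = region_mean_curvature(met_field, mp)
        results.append(
            SimilarityResult(
                joint, region, k_cun, k_met,
                curvature_similarity(k_cun, k_met, log_base=log_base),
            )
        )
    return results
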