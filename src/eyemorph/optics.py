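"""Inter-ommatidial angles, eye curvature, and visual-acuity estimates.

Two complementary estimates of the inter-ommatidial angle dPhi are computed:

* a *global* angle from the total ommatidia count, assuming the eye surveys a
  hemispheric visual field: dPhi_G = sqrt(23818 / n) degrees; and
* a *local* angle from the radius-of-curvature method: from the arc length b
  (mm) of eye surface covered at a sampling angle a (degrees), and the mean
  local facet diameter D, dPhi = D / (b / a).

Visual acuity is reported as twice the inter-ommatidial angle; smaller angles
(and acuities, on this convention) mean finer spatial sampling.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

from .types import AcuityEstimate, CurvatureRecord

#: Solid-angle constant (deg^2) of the hemispheric-field approximation.
HEMISPHERIC_CONSTANT = 23818.0


def global_ioa(n: float) -> float:
    """Global inter-ommatidial angle (degrees) from the ommatidia count.

    dPhi_G = sqrt(23818 / n); n = 23818 gives exactly 1 degree.
    """
    if n <= 0:
        raise ValueError(f"ommatidia count must be positive, got {n}")
    return float(np.sqrt(HEMISPHERIC_CONSTANT / n))


def count_from_global_ioa(dphi_g: float) -> float:
    """Invert :func:`global_ioa`: the count implied by a global angle."""
    if dphi_g <= 0:
        raise ValueError("dPhi_G must be positive")
    return HEMISPHERIC_CONSTANT / dphi_g**2


def local_curvature(rec: CurvatureRecord) -> float:
    """Local eye curvature (degrees per mm): sampling angle over arc length."""
    return rec.a_deg / rec.b_mm


def mean_facet_diameter(diameters_um: Iterable[float]) -> float:
    """Average a set of local facet diameters (um), e.g. five per direction."""
    d = np.asarray(list(diameters_um), dtype=float)
    if len(d) == 0 or not np.all(d > 0):
        raise ValueError("need a non-empty set of positive diameters")
    return float(d.mean())


def local_ioa(rec: CurvatureRecord) -> float:
    """Local inter-ommatidial angle (degrees) by the radius-of-curvature method.

    dPhi = D / (b / a) with D converted um -> mm, so facet diameter times
    local curvature (a/b, degrees per mm).
    """
    d_mm = rec.D_um / 1000.0
    return d_mm * rec.a_deg / rec.b_mm


def visual_acuity(dphi_deg: float) -> float:
    """Acuity estimate (degrees): twice the inter-ommatidial angle."""
    if dphi_deg < 0:
        raise ValueError("inter-ommatidial angle cannot be negative")
    return 2.0 * dphi_deg


def acuity_profile(
    n: Optional[float] = None,
    records: Sequence[CurvatureRecord] = (),
    specimen_id: str = "",
    group: str = "",
) -> AcuityEstimate:
    """Assemble global and per-axis angle/acuity estimates for one specimen.

    ``records`` may hold at most one record per axis; a missing axis (or a
    missing count) propagates as NaN.
    """
    est = AcuityEstimate(specimen_id=specimen_id, group=group)
    if n is not None:
        est.dphi_global_deg = global_ioa(n)
        est.acuity_global_deg = visual_acuity(est.dphi_global_deg)
    seen = set()
    for rec in records:
        if rec.axis in seen:
            raise ValueError(f"duplicate curvature record for axis {rec.axis!r}")
        seen.add(rec.axis)
        dphi = local_ioa(rec)
        curv = local_curvature(rec)
        if rec.axis == "x":
            est.dphi_x_deg = dphi
            est.acuity_x_deg = visual_acuity(dphi)
            est.curvature_x_deg_per_mm = curv
        else:
            est.dphi_y_deg = dphi
            est.acuity_y_deg = visual_acuity(dphi)
            est.curvature_y_deg_per_mm = curv
    return est
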