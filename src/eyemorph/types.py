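"""Core record types shared across the pipeline.

Conventions: cast coordinates and outlines are stored in mm (flattened-cast
plane, y increasing dorsally); facet diameters are reported in micrometres;
angles are degrees throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

GROUPS = ("small_male", "large_male", "female")

MM_TO_UM = 1000.0


class DegenerateInputError(ValueError):
    """Raised when an input is geometrically or statistically degenerate."""


@dataclass
class EyeCast:
    """One flattened eye cast: facet-center coordinates plus outline polygon.

    ``centers`` is an (n, 2) array in mm; ``outline`` an (m, 2) closed polygon
    (first vertex not repeated) in mm.
    """

    specimen_id: str
    group: str
    centers: np.ndarray
    outline: np.ndarray
    scale_provenance: str = ""

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.outline = np.asarray(self.outline, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 2:
            raise ValueError("centers must be an (n, 2) array")
        if self.centers.shape[0] < 7:
            raise DegenerateInputError(
                f"an eye cast needs >= 7 facet centers, got {self.centers.shape[0]}"
            )
        if self.outline.ndim != 2 or self.outline.shape[1] != 2 or len(self.outline) < 3:
            raise ValueError("outline must be an (m>=3, 2) polygon")

    @property
    def n_ommatidia(self) -> int:
        return int(self.centers.shape[0])


@dataclass
class FacetMap:
    """Neighbor graph over facet centers with per-facet diameter estimates.

    ``neighbor_edges`` is a (k, 2) array of index pairs (i < j); the graph is
    undirected.  ``diameters_um`` is per-facet, NaN for isolated facets.
    ``boundary_flag`` marks facets with truncated neighborhoods (convex-hull
    vertices and facets that lost an edge to pruning).
    """

    neighbor_edges: np.ndarray
    diameters_um: Optional[np.ndarray] = None
    boundary_flag: Optional[np.ndarray] = None

    @property
    def n_edges(self) -> int:
        return int(len(self.neighbor_edges))

    def degree(self, n_facets: int) -> np.ndarray:
        deg = np.zeros(n_facets, dtype=int)
        if len(self.neighbor_edges):
            np.add.at(deg, self.neighbor_edges[:, 0], 1)
            np.add.at(deg, self.neighbor_edges[:, 1], 1)
        return deg


@dataclass
class EyeSummary:
    specimen_id: str
    group: str
    n_ommatidia: int
    surface_area_mm2: float
    density_per_mm2: float
    smallest_um: float
    average_um: float
    largest_um: float


@dataclass
class CurvatureRecord:
    """One radius-of-curvature measurement along one eye axis.

    ``a_deg`` is the sampling angle, ``b_mm`` the arc of eye surface it covers,
    ``D_um`` the mean of five local facet diameters near the measurement site.
    """

    axis: str  # "x" (parallel to horizon) or "y" (perpendicular)
    a_deg: float
    b_mm: float
    D_um: float
    specimen_id: str = ""
    group: str = ""
    measurement_site: str = ""

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y"):
            raise ValueError(f"axis must be 'x' or 'y', got {self.axis!r}")
        if not self.a_deg > 0:
            raise ValueError("sampling angle a must be > 0 degrees")
        if not self.b_mm > 0:
            raise ValueError("arc length b must be > 0 mm")
        if not self.D_um > 0:
            raise ValueError("facet diameter D must be > 0 um")


@dataclass
class AcuityEstimate:
    """Global and local inter-ommatidial angles with their acuity estimates.

    Acuity is twice the inter-ommatidial angle; smaller angles mean finer
    spatial sampling.  Missing axes propagate as NaN.
    """

    specimen_id: str = ""
    group: str = ""
    dphi_global_deg: float = float("nan")
    dphi_x_deg: float = float("nan")
    dphi_y_deg: float = float("nan")
    acuity_global_deg: float = float("nan")
    acuity_x_deg: float = float("nan")
    acuity_y_deg: float = float("nan")
    curvature_x_deg_per_mm: float = float("nan")
    curvature_y_deg_per_mm: float = float("nan")


@dataclass
class SpecimenRecord:
    specimen_id: str
    group: str
    head_width_mm: float
    head_height_mm: float = float("nan")
    eye_height_mm: float = float("nan")
    it_span_mm: float = float("nan")
    mass_g: float = float("nan")
    n_ommatidia: Optional[int] = None
    dphi_x_deg: float = float("nan")
    dphi_y_deg: float = float("nan")

    @property
    def rel_eye_head(self) -> float:
        return self.eye_height_mm / self.head_height_mm


@dataclass
class AllometryFit:
    """An OLS scaling fit; ``slope`` is the exponent b when ``log_log``.

    ``classification`` (hypo-/iso-/hyperallometric) is only set for log-log
    fits, from a two-sided test of the slope against the isometry reference.
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    F: float
    df: int
    p: float
    n: int
    log_log: bool
    classification: str = "n/a"
    response: str = ""
    predictor: str = ""


@dataclass
class PosthocResult:
    pair: tuple
    statistic: float
    p_adjusted: float
    method: str


@dataclass
class GroupComparison:
    variable: str
    omnibus: str  # t_test, welch_t_test, anova, kruskal_wallis
    statistic: float
    df: float
    p: float
    group_names: Sequence[str] = ()
    group_n: Sequence[int] = ()
    posthoc: list = field(default_factory=list)
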