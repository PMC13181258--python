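"""Facet-level geometry: neighbor graphs, diameters, areas, and hotspot maps.

The measurement chain mirrors how eye casts are digitized: a point per
ommatidium center and a traced outline.  Facet diameter is taken as the
center-to-center distance to retained neighbors (hexagonally packed facets
tile the cornea, so neighbor spacing equals facet diameter), the outline
polygon gives the eye surface area, and the diameter field across the cast
reveals the dorsofrontal acute zone.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .types import MM_TO_UM, DegenerateInputError, EyeCast, EyeSummary, FacetMap

DEFAULT_PRUNE_FACTOR = 1.5


def _delaunay_edges(points: np.ndarray) -> np.ndarray:
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise DegenerateInputError(
            "Delaunay triangulation failed (collinear or duplicate centers?)"
        ) from exc
    e = np.vstack(
        [tri.simplices[:, [0, 1]], tri.simplices[:, [1, 2]], tri.simplices[:, [0, 2]]]
    )
    e.sort(axis=1)
    return np.unique(e, axis=0), tri


def build_neighbor_graph(
    cast: EyeCast,
    prune_factor: float = DEFAULT_PRUNE_FACTOR,
    prune_mode: str = "local",
) -> FacetMap:
    """Delaunay neighbor graph over facet centers, with long edges pruned.

    Delaunay triangulation of a near-hexagonal point pattern recovers the
    physical facet adjacency, plus spurious long edges along the outline and
    across gaps in the cast.  An edge is pruned when it exceeds
    ``prune_factor`` times a reference edge length: with ``prune_mode="local"``
    (default) the reference is the smaller of the two endpoints' median
    incident edge lengths, which tolerates smooth diameter gradients such as
    the acute zone; ``"global"`` uses the global median edge length.

    Boundary facets — convex-hull vertices and facets that lost an edge to
    pruning — are flagged.  Facets left with no retained edge are isolated
    (flagged, no diameter).
    """
    points = cast.centers
    if len(points) < 3:
        raise DegenerateInputError("need at least 3 facet centers")
    (edges, tri) = _delaunay_edges(points)
    lengths = np.linalg.norm(points[edges[:, 0]] - points[edges[:, 1]], axis=1)

    if prune_mode == "global":
        keep = lengths <= prune_factor * np.median(lengths)
    elif prune_mode == "local":
        n = len(points)
        local_med = np.empty(n)
        # median incident edge length per vertex
        order = np.argsort(np.concatenate([edges[:, 0], edges[:, 1]]), kind="stable")
        flat_v = np.concatenate([edges[:, 0], edges[:, 1]])[order]
        flat_l = np.concatenate([lengths, lengths])[order]
        starts = np.searchsorted(flat_v, np.arange(n))
        ends = np.searchsorted(flat_v, np.arange(n) + 1)
        for v in range(n):
            seg = flat_l[starts[v] : ends[v]]
            local_med[v] = np.median(seg) if len(seg) else np.inf
        ref = np.minimum(local_med[edges[:, 0]], local_med[edges[:, 1]])
        keep = lengths <= prune_factor * ref
    else:
        raise ValueError(f"unknown prune_mode {prune_mode!r}")

    retained = edges[keep]
    boundary = np.zeros(len(points), dtype=bool)
    boundary[np.unique(tri.convex_hull)] = True
    pruned = edges[~keep]
    boundary[np.unique(pruned)] = True
    return FacetMap(neighbor_edges=retained, boundary_flag=boundary)


def estimate_diameters(fmap: FacetMap, cast: EyeCast) -> np.ndarray:
    """Per-facet diameter (um): mean retained-edge length incident to the facet.

    Isolated facets (no retained edges) get NaN.  Also stored on ``fmap``.
    """
    n = cast.n_ommatidia
    edges = fmap.neighbor_edges
    total = np.zeros(n)
    deg = np.zeros(n)
    if len(edges):
        lengths = np.linalg.norm(
            cast.centers[edges[:, 0]] - cast.centers[edges[:, 1]], axis=1
        )
        np.add.at(total, edges[:, 0], lengths)
        np.add.at(total, edges[:, 1], lengths)
        np.add.at(deg, edges[:, 0], 1.0)
        np.add.at(deg, edges[:, 1], 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        diam = np.where(deg > 0, total / deg, np.nan) * MM_TO_UM
    fmap.diameters_um = diam
    return diam


def eye_surface_area(outline: np.ndarray) -> float:
    """Polygon area (mm²) by the shoelace formula; orientation-independent."""
    poly = np.asarray(outline, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("outline must be an (m>=3, 2) polygon")
    x, y = poly[:, 0], poly[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def summarize_eye(cast: EyeCast, fmap: FacetMap) -> EyeSummary:
    """Count, surface area, density, and diameter extrema for one eye.

    Density is ommatidia per mm² of traced surface.  The smallest/average/
    largest diameters are taken over interior (non-boundary) facets, whose
    neighborhoods are complete; boundary facets still count toward n and
    density.
    """
    if fmap.diameters_um is None:
        estimate_diameters(fmap, cast)
    area = eye_surface_area(cast.outline)
    n = cast.n_ommatidia
    interior = ~fmap.boundary_flag if fmap.boundary_flag is not None else np.ones(n, bool)
    d = fmap.diameters_um[interior]
    d = d[np.isfinite(d)]
    if len(d) == 0:  # fall back to all facets if everything is boundary
        d = fmap.diameters_um[np.isfinite(fmap.diameters_um)]
    if len(d) == 0:
        raise DegenerateInputError("no facet has a measurable diameter")
    return EyeSummary(
        specimen_id=cast.specimen_id,
        group=cast.group,
        n_ommatidia=n,
        surface_area_mm2=area,
        density_per_mm2=n / area,
        smallest_um=float(d.min()),
        average_um=float(d.mean()),
        largest_um=float(d.max()),
    )


def diameter_histogram(diameters_um: np.ndarray, bin_width_um: float = 2.0):
    """Relative-frequency histogram of facet diameters.

    Bins are aligned at integer multiples of the bin width (default 2 um);
    frequencies sum to 1 over non-missing facets.  Returns a DataFrame with
    ``bin_left_um``, ``bin_right_um``, ``rel_freq``.
    """
    import pandas as pd

    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    d = np.asarray(diameters_um, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) == 0:
        raise DegenerateInputError("no finite diameters to bin")
    lo = np.floor(d.min() / bin_width_um) * bin_width_um
    hi = np.ceil(d.max() / bin_width_um) * bin_width_um
    if hi <= lo:
        hi = lo + bin_width_um
    edges = np.arange(lo, hi + 0.5 * bin_width_um, bin_width_um)
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame(
        {
            "bin_left_um": edges[:-1],
            "bin_right_um": edges[1:],
            "rel_freq": counts / counts.sum(),
        }
    )


_NULL_COLOR = "#bbbbbb"


def _viridis_hex(t: float) -> str:
    """Hex color from a fixed 9-anchor viridis ramp (t in [0, 1])."""
    anchors = [
        (68, 1, 84), (72, 40, 120), (62, 74, 137), (49, 104, 142),
        (38, 130, 142), (31, 158, 137), (53, 183, 121), (109, 205, 89),
        (180, 222, 44),
    ]
    t = min(max(float(t), 0.0), 1.0) * (len(anchors) - 1)
    i = min(int(t), len(anchors) - 2)
    f = t - i
    rgb = [round(a + (b - a) * f) for a, b in zip(anchors[i], anchors[i + 1])]
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def hotspot_map(
    cast: EyeCast,
    fmap: FacetMap,
    path: str,
    marker_scale: float = 0.45,
) -> str:
    """Render the facet-diameter field as an SVG color-gradient map.

    One circle per facet, colored linearly from the minimum to the maximum
    diameter; facets with missing diameters are drawn in gray.  A legend with
    the diameter range and a 0.5 mm scale bar is included.  Output is plain
    deterministic SVG text.  Returns the path written.
    """
    if fmap.diameters_um is None:
        estimate_diameters(fmap, cast)
    d = fmap.diameters_um
    finite = np.isfinite(d)
    if cast.n_ommatidia == 0 or not finite.any():
        raise DegenerateInputError("no facets with diameters to render")
    dmin, dmax = float(d[finite].min()), float(d[finite].max())
    span = dmax - dmin
    if span <= 1e-9 * max(abs(dmax), 1.0):  # effectively uniform diameters
        span = 0.0

    pts = cast.centers
    all_xy = np.vstack([pts, cast.outline])
    x0, y0 = all_xy.min(axis=0) - 0.2
    x1, y1 = all_xy.max(axis=0) + 0.2
    w, h = x1 - x0, y1 - y0
    px = 900.0
    sc = px / w

    def X(x):
        return (x - x0) * sc

    def Y(y):  # flip so dorsal (larger y) is up
        return (y1 - y) * sc

    median_d = np.median(d[finite])
    r_px = marker_scale * (median_d / MM_TO_UM) * sc

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{px:.0f}" '
        f'height="{h * sc + 80:.0f}" viewBox="0 0 {px:.0f} {h * sc + 80:.0f}">',
        '<rect width="100%" height="100%" fill="white"/>',
    ]
    ol = " ".join(f"{X(x):.2f},{Y(y):.2f}" for x, y in cast.outline)
    parts.append(f'<polygon points="{ol}" fill="none" stroke="#333333" stroke-width="1"/>')
    for i in range(cast.n_ommatidia):
        if finite[i]:
            t = (d[i] - dmin) / span if span > 0 else 0.5
            color = _viridis_hex(t)
        else:
            color = _NULL_COLOR
        parts.append(
            f'<circle cx="{X(pts[i, 0]):.2f}" cy="{Y(pts[i, 1]):.2f}" '
            f'r="{r_px:.2f}" fill="{color}"/>'
        )
    # legend: color ramp + labels + 0.5 mm scale bar
    ly = h * sc + 20
    for k in range(100):
        parts.append(
            f'<rect x="{20 + 2 * k}" y="{ly:.1f}" width="2" height="14" '
            f'fill="{_viridis_hex(k / 99)}"/>'
        )
    parts.append(
        f'<text x="20" y="{ly + 32:.1f}" font-size="14" font-family="sans-serif">'
        f"{dmin:.1f} um</text>"
    )
    parts.append(
        f'<text x="180" y="{ly + 32:.1f}" font-size="14" font-family="sans-serif">'
        f"{dmax:.1f} um</text>"
    )
    bar = 0.5 * sc
    parts.append(
        f'<rect x="{px - bar - 30:.1f}" y="{ly:.1f}" width="{bar:.1f}" height="5" fill="black"/>'
    )
    parts.append(
        f'<text x="{px - bar - 30:.1f}" y="{ly + 25:.1f}" font-size="14" '
        f'font-family="sans-serif">0.5 mm</text>'
    )
    parts.append("</svg>")
    svg = "\n".join(parts) + "\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(svg)
    return path


def hotspot_centroid(cast: EyeCast, fmap: FacetMap, top_fraction: float = 0.1) -> np.ndarray:
    """Centroid (mm) of the facets in the top decile of diameter.

    A cheap localizer for the acute zone: where the largest facets cluster.
    """
    if fmap.diameters_um is None:
        estimate_diameters(fmap, cast)
    d = fmap.diameters_um
    finite = np.isfinite(d)
    if not finite.any():
        raise DegenerateInputError("no diameters available")
    thresh = np.quantile(d[finite], 1.0 - top_fraction)
    sel = finite & (d >= thresh)
    return cast.centers[sel].mean(axis=0)
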