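"""Facet geometry: neighbor graphs, diameters, areas, histograms, hotspot map."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eyemorph import (
    DegenerateInputError,
    EyeCast,
    build_neighbor_graph,
    diameter_histogram,
    estimate_diameters,
    eye_surface_area,
    hotspot_centroid,
    hotspot_map,
    summarize_eye,
)
from eyemorph.eyegen import EyeGenParams, generate_eye_cast

from conftest import hex_lattice, square_outline


class TestNeighborGraph:
    def test_hexagon_center_has_six_edges_of_side_length(self, hexagon_cast):
        fmap = build_neighbor_graph(hexagon_cast)
        deg = fmap.degree(7)
        assert deg[0] == 6
        center_edges = fmap.neighbor_edges[(fmap.neighbor_edges == 0).any(axis=1)]
        lengths = np.linalg.norm(
            hexagon_cast.centers[center_edges[:, 0]]
            - hexagon_cast.centers[center_edges[:, 1]],
            axis=1,
        )
        assert np.allclose(lengths, 0.03, atol=1e-12)

    @pytest.mark.parametrize("prune_mode", ["local", "global"])
    def test_no_edge_spans_an_artificial_gap(self, prune_mode):
        """Removing one lattice facet must not leave graph edges bridging the hole.

        Brute force: with spacing s, any retained edge must be ~s; the hole's
        Delaunay diagonals (sqrt(3)s and 2s) are pruned.
        """
        s = 0.03
        pts = hex_lattice(s, 15, 15)
        gap_idx = np.argmin(np.linalg.norm(pts, axis=1))
        pts = np.delete(pts, gap_idx, axis=0)
        cast = EyeCast("gap", "female", pts, square_outline(0.4))
        fmap = build_neighbor_graph(cast, prune_mode=prune_mode)
        lengths = np.linalg.norm(
            pts[fmap.neighbor_edges[:, 0]] - pts[fmap.neighbor_edges[:, 1]], axis=1
        )
        assert lengths.max() < 1.5 * s  # no sqrt(3)s or 2s bridges survive

    def test_collinear_points_raise_geometry_error(self):
        pts = np.column_stack([np.linspace(0, 1, 8), np.zeros(8)])
        cast = EyeCast("line", "female", pts, square_outline(2.0))
        with pytest.raises(DegenerateInputError):
            build_neighbor_graph(cast)

    def test_local_pruning_preserves_acute_zone_edges(self, hotspot_cast):
        """Enlarged hotspot facets keep their neighbors under local pruning."""
        _, cast, _ = hotspot_cast
        fmap = build_neighbor_graph(cast)
        diam = estimate_diameters(fmap, cast)
        interior = ~fmap.boundary_flag
        assert np.isfinite(diam[interior]).all()
        assert fmap.degree(cast.n_ommatidia)[interior].min() >= 3


class TestDiameters:
    def test_uniform_lattice_interior_diameters_exact(self, uniform_cast):
        fmap = build_neighbor_graph(uniform_cast)
        diam = estimate_diameters(fmap, uniform_cast)
        interior = ~fmap.boundary_flag
        assert interior.sum() > 100
        assert np.allclose(diam[interior], 30.0, atol=1e-9)

    def test_jittered_lattice_mean_diameter_near_spacing(self):
        """Small positional noise leaves the population mean within 0.5 um of 30."""
        rng = np.random.default_rng(12345)
        pts = hex_lattice(0.030, 40, 40) + rng.normal(0, 0.001, (1600, 2))
        cast = EyeCast("jitter", "female", pts, square_outline(0.8))
        fmap = build_neighbor_graph(cast)
        diam = estimate_diameters(fmap, cast)
        interior = ~fmap.boundary_flag
        # independent brute-force: mean over all retained edge lengths
        e = fmap.neighbor_edges
        brute = np.linalg.norm(pts[e[:, 0]] - pts[e[:, 1]], axis=1).mean() * 1000
        assert abs(np.nanmean(diam[interior]) - 30.0) < 0.5
        assert abs(brute - 30.0) < 0.5

    def test_hotspot_ratio_recovered_within_10pct(self, hotspot_cast):
        _, cast, true_diam = hotspot_cast
        fmap = build_neighbor_graph(cast)
        diam = estimate_diameters(fmap, cast)
        interior = ~fmap.boundary_flag
        est_ratio = np.nanmax(diam[interior]) / np.nanmin(diam[interior])
        true_ratio = true_diam[interior].max() / true_diam[interior].min()
        assert est_ratio == pytest.approx(true_ratio, rel=0.10)

    def test_rigid_motion_invariance(self, hotspot_cast):
        """Diameters are unchanged (1e-9 relative) by rotation + translation."""
        _, cast, _ = hotspot_cast
        fmap = build_neighbor_graph(cast)
        d0 = estimate_diameters(fmap, cast)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = EyeCast(
            cast.specimen_id, cast.group,
            cast.centers @ R.T + np.array([3.0, -2.0]),
            cast.outline @ R.T + np.array([3.0, -2.0]),
        )
        fmap2 = build_neighbor_graph(moved)
        d1 = estimate_diameters(fmap2, moved)
        mask = np.isfinite(d0) & np.isfinite(d1)
        assert np.allclose(d0[mask], d1[mask], rtol=1e-9)


class TestSurfaceArea:
    def test_unit_square_and_triangle(self):
        assert eye_surface_area(np.array([[0, 0], [1, 0], [1, 1], [0, 1]])) == 1.0
        assert eye_surface_area(np.array([[0, 0], [1, 0], [0, 1]])) == 0.5
        # orientation-independent
        assert eye_surface_area(np.array([[0, 0], [0, 1], [1, 0]])) == 0.5

    def test_regular_256gon_approximates_circle(self):
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        poly = np.column_stack([np.cos(theta), np.sin(theta)])
        # closed-form n-gon area: (n/2) sin(2 pi / n)
        exact = 128 * np.sin(2 * np.pi / 256)
        assert eye_surface_area(poly) == pytest.approx(exact, abs=1e-12)
        assert eye_surface_area(poly) == pytest.approx(np.pi, abs=1e-3)

    def test_matches_shapely_on_irregular_polygon(self):
        from shapely.geometry import Polygon

        rng = np.random.default_rng(99)
        theta = np.sort(rng.uniform(0, 2 * np.pi, 25))
        r = rng.uniform(0.5, 2.0, 25)
        poly = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        assert eye_surface_area(poly) == pytest.approx(Polygon(poly).area, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        n=st.integers(5, 40),
        seed=st.integers(0, 2**20),
        scale=st.floats(0.1, 50.0),
    )
    def test_shoelace_equals_fan_triangulation_on_convex_polygons(self, n, seed, scale):
        rng = np.random.default_rng(seed)
        theta = np.sort(rng.uniform(0, 2 * np.pi, n))
        poly = scale * np.column_stack([np.cos(theta), np.sin(theta)])  # convex
        fan = 0.0
        for i in range(1, n - 1):
            u, v = poly[i] - poly[0], poly[i + 1] - poly[0]
            fan += 0.5 * abs(u[0] * v[1] - u[1] * v[0])
        assert eye_surface_area(poly) == pytest.approx(fan, rel=1e-10)


class TestSummaryAndHistogram:
    def test_density_is_count_over_area(self, uniform_cast):
        fmap = build_neighbor_graph(uniform_cast)
        s = summarize_eye(uniform_cast, fmap)
        area = eye_surface_area(uniform_cast.outline)
        assert s.density_per_mm2 * s.surface_area_mm2 == pytest.approx(s.n_ommatidia)
        assert s.surface_area_mm2 == pytest.approx(area)
        assert s.smallest_um <= s.average_um <= s.largest_um

    def test_known_density(self):
        """100 facets in a 4 mm² outline give 25 per mm²."""
        rng = np.random.default_rng(0)
        pts = rng.uniform(-0.9, 0.9, (100, 2))
        cast = EyeCast("d", "female", pts, square_outline(1.0))
        fmap = build_neighbor_graph(cast)
        s = summarize_eye(cast, fmap)
        assert s.n_ommatidia == 100
        assert s.density_per_mm2 == pytest.approx(25.0)

    def test_summary_extrema_match_estimated_diameters(self, hotspot_cast):
        _, cast, _ = hotspot_cast
        fmap = build_neighbor_graph(cast)
        diam = estimate_diameters(fmap, cast)
        s = summarize_eye(cast, fmap)
        interior = ~fmap.boundary_flag
        assert s.smallest_um == np.nanmin(diam[interior])
        assert s.largest_um == np.nanmax(diam[interior])

    def test_large_male_like_cast_mean_diameter(self):
        """Cast built at the large-male scale recovers the generator mean to 1 um."""
        p = EyeGenParams(
            lattice_spacing=0.0295, n_target=4000, hotspot_amplitude=1.55,
            gradient_scale=0.5, hotspot_center=(0.9, 0.7), jitter_sd=0.001,
            outline_shape=(4.4, 2.8), seed=21,
        )
        cast, true_diam = generate_eye_cast(p)
        fmap = build_neighbor_graph(cast)
        diam = estimate_diameters(fmap, cast)
        interior = ~fmap.boundary_flag
        assert abs(np.nanmean(diam[interior]) - true_diam[interior].mean()) < 1.0

    def test_histogram_trivial_cases(self):
        h = diameter_histogram(np.full(50, 30.0))
        assert h.rel_freq.sum() == pytest.approx(1.0)
        assert (h.rel_freq == 1.0).sum() == 1
        h2 = diameter_histogram(np.array([20.0] * 25 + [30.0] * 25))
        nz = h2[h2.rel_freq > 0]
        assert list(nz.rel_freq) == [0.5, 0.5]
        assert (nz.bin_left_um % 2 == 0).all()  # bins aligned at even um

    def test_histogram_mass_above_28um_increases_with_amplitude(self):
        masses = []
        for amp in [1.0, 1.3, 1.6]:
            p = EyeGenParams(
                lattice_spacing=0.026, n_target=2500, hotspot_amplitude=amp,
                gradient_scale=0.25, hotspot_center=(0.0, 0.0), jitter_sd=0.001,
                outline_shape=(2.4, 1.8), seed=13,
            )
            cast, _ = generate_eye_cast(p)
            fmap = build_neighbor_graph(cast)
            diam = estimate_diameters(fmap, cast)
            h = diameter_histogram(diam[~fmap.boundary_flag])
            masses.append(h.rel_freq[h.bin_left_um >= 28].sum())
        assert masses[0] < masses[1] < masses[2]


class TestHotspotMap:
    def test_uniform_cast_renders_single_color(self, uniform_cast, tmp_path):
        fmap = build_neighbor_graph(uniform_cast)
        path = hotspot_map(uniform_cast, fmap, str(tmp_path / "u.svg"))
        svg = open(path).read()
        fills = {
            line.split('fill="')[1].split('"')[0]
            for line in svg.splitlines()
            if "<circle" in line
        }
        assert len(fills) == 1

    def test_map_is_deterministic(self, hotspot_cast, tmp_path):
        _, cast, _ = hotspot_cast
        fmap = build_neighbor_graph(cast)
        p1 = hotspot_map(cast, fmap, str(tmp_path / "a.svg"))
        p2 = hotspot_map(cast, fmap, str(tmp_path / "b.svg"))
        assert open(p1).read() == open(p2).read()

    def test_top_decile_centroid_near_true_hotspot(self, hotspot_cast):
        params, cast, _ = hotspot_cast
        fmap = build_neighbor_graph(cast)
        estimate_diameters(fmap, cast)
        centroid = hotspot_centroid(cast, fmap)
        assert np.linalg.norm(centroid - params.hotspot_center) < params.gradient_scale

    def test_empty_or_missing_diameters_error(self):
        pts = np.column_stack([np.arange(7) % 3, np.arange(7) // 3]).astype(float)
        cast = EyeCast("tiny", "female", pts, square_outline(5.0))
        from eyemorph.types import FacetMap

        fmap = FacetMap(
            neighbor_edges=np.empty((0, 2), dtype=int),
            diameters_um=np.full(7, np.nan),
            boundary_flag=np.ones(7, bool),
        )
        with pytest.raises(DegenerateInputError):
            hotspot_map(cast, fmap, "/dev/null")
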