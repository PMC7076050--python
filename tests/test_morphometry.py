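"""Geometry primitives, cell classification and slide measurement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smearshed import (
    CellObservation,
    ClassifierThresholds,
    SmearScene,
    classify_cell,
    count_complete_cells,
    mean_field_count,
    measure_slide,
    polygon_area,
    read_scene,
    sci_eligible,
    superficial_cell_index,
    write_scene,
)
from smearshed.cohort import generate_scene
from smearshed.errors import GenerationError, GeometryError, IntegrityError, UndefinedSCIError
from smearshed.geometry import angularity
from smearshed.morphometry import cell_inside_bounds, largest_aggregate_area


def square(side, x0=0.0, y0=0.0):
    return [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]


def make_cell(center, radius=20.0, n=8, nucleus_frac=0.05):
    theta = 2 * np.pi * np.arange(n) / n
    cx, cy = center
    outline = np.column_stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)])
    nucleus = np.column_stack(
        [cx + 0.3 * radius * np.cos(theta), cy + 0.3 * radius * np.sin(theta)]
    )
    del nucleus_frac
    return CellObservation(outline, nucleus)


class TestPolygonArea:
    def test_square_and_triangle_closed_forms(self):
        assert polygon_area(square(100)) == pytest.approx(10_000)
        assert polygon_area([(0, 0), (100, 0), (0, 100)]) == pytest.approx(5_000)

    def test_orientation_independent(self):
        assert polygon_area(square(7)[::-1]) == pytest.approx(49)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(GeometryError):
            polygon_area([(0, 0), (1, 1)])

    def test_self_intersection_rejected(self):
        bowtie = [(0, 0), (2, 2), (2, 0), (0, 2)]
        with pytest.raises(GeometryError):
            polygon_area(bowtie)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_picks_theorem_on_lattice_polygons(self, seed):
        """Shoelace area equals interior + boundary/2 - 1 on lattice polygons."""
        rng = np.random.default_rng(seed)
        pts = rng.integers(0, 12, size=(12, 2))
        hull = _convex_hull(np.unique(pts, axis=0))
        if hull.shape[0] < 3:
            return
        interior, boundary = _lattice_point_counts(hull)
        assert polygon_area(hull) == pytest.approx(interior + boundary / 2 - 1)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        dx=st.floats(-500, 500), dy=st.floats(-500, 500),
        angle=st.floats(0, 2 * math.pi), scale=st.floats(0.1, 10),
    )
    def test_rigid_motion_invariance_and_quadratic_scaling(self, dx, dy, angle, scale):
        poly = np.asarray([(0, 0), (30, 5), (40, 30), (10, 40)], dtype=float)
        base = polygon_area(poly)
        rot = np.array([[math.cos(angle), -math.sin(angle)],
                        [math.sin(angle), math.cos(angle)]])
        moved = poly @ rot.T + [dx, dy]
        assert polygon_area(moved) == pytest.approx(base, rel=1e-9)
        assert polygon_area(poly * scale) == pytest.approx(base * scale ** 2, rel=1e-9)


def _convex_hull(pts):
    # Andrew's monotone chain on integer points
    pts = sorted(map(tuple, pts))
    if len(pts) <= 2:
        return np.asarray(pts)

    def half(points):
        out = []
        for p in points:
            while len(out) >= 2 and _cross(out[-2], out[-1], p) <= 0:
                out.pop()
            out.append(p)
        return out

    lower, upper = half(pts), half(pts[::-1])
    return np.asarray(lower[:-1] + upper[:-1])


def _cross(o, a, b):
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _lattice_point_counts(poly):
    """Brute-force interior/boundary lattice-point counts for Pick's theorem."""
    from shapely.geometry import Point, Polygon

    shp = Polygon(poly)
    x0, y0, x1, y1 = (int(v) for v in shp.bounds)
    interior = boundary = 0
    for x in range(x0, x1 + 1):
        for y in range(y0, y1 + 1):
            p = Point(x, y)
            if shp.touches(p) or shp.exterior.distance(p) < 1e-9:
                boundary += 1
            elif shp.contains(p):
                interior += 1
    return interior, boundary


class TestCompleteCellCounting:
    def test_interior_counted_straddling_excluded(self):
        inside = [make_cell((100 + 60 * i, 100)) for i in range(5)]
        straddling = [make_cell((1340, 500)), make_cell((1335, 800))]
        scene = SmearScene((1340, 1000), cells=inside + straddling,
                           aggregate_outlines=[square(50, 600, 600)])
        assert count_complete_cells(scene) == 5

    def test_boundary_touching_counts_as_inside(self):
        cell = make_cell((20, 500), radius=20)  # leftmost vertex exactly at x=0
        scene = SmearScene((1340, 1000), cells=[cell])
        assert count_complete_cells(scene) == 1

    def test_empty_scene(self):
        scene = SmearScene((1340, 1000))
        assert count_complete_cells(scene) == 0

    def test_matches_brute_force_vertex_containment(self):
        rng = np.random.default_rng(42)
        cells = [make_cell((rng.uniform(-30, 1370), rng.uniform(-30, 1030)))
                 for _ in range(200)]
        scene = SmearScene((1340, 1000), cells=cells)
        expected = sum(
            all(0 <= x <= 1340 and 0 <= y <= 1000 for x, y in c.cell_outline)
            for c in cells
        )
        assert count_complete_cells(scene) == expected

    def test_monotone_as_field_shrinks(self):
        rng = np.random.default_rng(3)
        cells = [make_cell((rng.uniform(0, 1340), rng.uniform(0, 1000)))
                 for _ in range(80)]
        prev = math.inf
        for w, h in [(1340, 1000), (1000, 800), (600, 500), (300, 200)]:
            n = count_complete_cells(SmearScene((w, h), cells=cells))
            assert n <= prev
            prev = n


class TestClassification:
    def test_superficial_by_construction(self):
        # octagon, area 3000, nucleus fraction 0.03: condensed nucleus,
        # large angular cytoplasm
        cell = _feature_cell(n=8, area=3000, f=0.03)
        assert classify_cell(cell) == "superficial"

    def test_parabasal_by_construction(self):
        cell = _feature_cell(n=16, area=500, f=0.45)
        assert classify_cell(cell) == "parabasal"

    def test_intermediate_is_the_fallback(self):
        cell = _feature_cell(n=24, area=1400, f=0.18)
        assert classify_cell(cell) == "intermediate"

    def test_low_angularity_blocks_superficial(self):
        # right size and nucleus but near-circular margin (40-gon)
        cell = _feature_cell(n=40, area=3000, f=0.03)
        assert classify_cell(cell) == "intermediate"

    def test_nucleus_larger_than_cell_rejected(self):
        theta = 2 * np.pi * np.arange(8) / 8
        big = np.column_stack([50 * np.cos(theta), 50 * np.sin(theta)])
        small = big * 0.5
        with pytest.raises(GeometryError):
            classify_cell(CellObservation(small, big))

    def test_generated_scenes_are_fully_separable(self):
        scene = generate_scene(60, 5, (0.4, 0.3, 0.3), 50_000.0, seed=17)
        for cell in scene.cells:
            assert classify_cell(cell) == cell.true_class

    def test_accuracy_degrades_with_feature_noise(self):
        accs = [_noisy_accuracy(noise, n=300) for noise in (0.0, 0.4, 1.2)]
        assert accs[0] == 1.0
        assert accs[0] >= accs[1] >= accs[2]
        assert accs[2] < 1.0


def _feature_cell(n, area, f):
    theta = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([np.cos(theta), np.sin(theta)])
    pts *= math.sqrt(area / polygon_area(pts))
    nucleus = pts * math.sqrt(f)
    return CellObservation(pts, nucleus)


def _noisy_accuracy(noise, n):
    """Classification accuracy when class features are log-normally blurred."""
    rng = np.random.default_rng(1234)
    protos = {"superficial": (8, 3000, 0.04), "intermediate": (24, 1400, 0.18),
              "parabasal": (16, 500, 0.45)}
    hits = 0
    for i in range(n):
        cls = ("superficial", "intermediate", "parabasal")[i % 3]
        nv, area, f = protos[cls]
        area = area * math.exp(noise * rng.normal(0, 0.4))
        f = min(0.9, f * math.exp(noise * rng.normal(0, 0.5)))
        hits += classify_cell(_feature_cell(nv, area, f)) == cls
    return hits / n


class TestSciPrimitives:
    @pytest.mark.parametrize("s, t, expected", [(17, 20, 0.85), (0, 10, 0.0), (7, 7, 1.0)])
    def test_exact_ratio(self, s, t, expected):
        assert superficial_cell_index(s, t) == pytest.approx(expected)

    def test_undefined_and_inconsistent_inputs(self):
        with pytest.raises(UndefinedSCIError):
            superficial_cell_index(0, 0)
        with pytest.raises(IntegrityError):
            superficial_cell_index(11, 10)

    def test_duplication_invariance(self):
        assert superficial_cell_index(34, 40) == superficial_cell_index(17, 20)

    @pytest.mark.parametrize("mean, eligible", [(50.0, True), (50.333, False), (0.0, True)])
    def test_gate_boundary(self, mean, eligible):
        assert sci_eligible(mean) is eligible

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            sci_eligible(-1.0)

    def test_mean_field_count(self):
        assert mean_field_count((91, 91, 91)) == 91.0
        assert mean_field_count((0, 0, 0)) == 0.0
        assert mean_field_count((10, 20, 40)) == pytest.approx(23.333333, abs=1e-5)
        with pytest.raises(ValueError):
            mean_field_count((1, 2))


class TestMeasureSlide:
    def test_composition_on_constructed_scenes(self):
        scenes = [generate_scene(30, 4, (1.0, 0.0, 0.0), 50_000.0, seed=s)
                  for s in (1, 2, 3)]
        m = measure_slide(scenes)
        assert m.mean_cell_count == 30.0
        assert m.sci == 1.0
        assert m.n_total == 90

    def test_gate_suppresses_sci(self):
        scenes = [generate_scene(60, 0, (1.0, 0.0, 0.0), 50_000.0, seed=s)
                  for s in (4, 5, 6)]
        m = measure_slide(scenes)
        assert m.mean_cell_count == 60.0
        assert m.sci is None and m.n_total is None

    def test_matches_independent_recomputation(self):
        rng_seeds = (11, 12, 13)
        scenes = [generate_scene(25, 3, (0.5, 0.3, 0.2), 30_000.0, seed=s)
                  for s in rng_seeds]
        m = measure_slide(scenes)
        counts = [count_complete_cells(s) for s in scenes]
        assert m.mean_cell_count == pytest.approx(mean_field_count(counts))
        areas = [largest_aggregate_area(s) for s in scenes]
        assert m.mean_aggregate_area_um2 == pytest.approx(float(np.mean(areas)))
        n_tot = n_sup = 0
        for sc in scenes:
            for c in sc.cells:
                if cell_inside_bounds(c, sc.field_bounds):
                    n_tot += 1
                    n_sup += classify_cell(c) == "superficial"
        assert (m.n_superficial, m.n_total) == (n_sup, n_tot)
        assert m.sci == superficial_cell_index(n_sup, n_tot)


class TestSceneGeneration:
    def test_complete_count_is_exact(self):
        scene = generate_scene(40, 5, (0.4, 0.35, 0.25), 220_000.0, seed=3)
        assert count_complete_cells(scene) == 40
        assert len(scene.cells) == 45

    def test_aggregate_area_within_one_percent(self):
        for target in (7_000.0, 50_000.0, 220_000.0):
            scene = generate_scene(5, 0, (1, 0, 0), target, seed=8)
            measured = polygon_area(scene.aggregate_outlines[0])
            assert measured == pytest.approx(target, rel=0.01)

    def test_infeasible_packing_raises(self):
        with pytest.raises(GenerationError):
            generate_scene(100_000, 0, (1, 0, 0), 1000.0, seed=0)

    def test_seed_determinism(self):
        a = generate_scene(20, 2, (0.5, 0.25, 0.25), 9_000.0, seed=99)
        b = generate_scene(20, 2, (0.5, 0.25, 0.25), 9_000.0, seed=99)
        assert all(np.array_equal(x.cell_outline, y.cell_outline)
                   for x, y in zip(a.cells, b.cells))

    def test_json_roundtrip(self, tmp_path):
        scene = generate_scene(10, 1, (0.4, 0.3, 0.3), 12_000.0, seed=5)
        path = write_scene(scene, tmp_path / "scene.json")
        back = read_scene(path)
        assert back.field_bounds == scene.field_bounds
        assert len(back.cells) == len(scene.cells)
        assert np.allclose(back.cells[0].cell_outline, scene.cells[0].cell_outline)
        assert [c.true_class for c in back.cells] == [c.true_class for c in scene.cells]
        assert np.allclose(back.aggregate_outlines[0], scene.aggregate_outlines[0])
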