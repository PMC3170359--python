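import heapq
import itertools

import numpy as np
import pytest

from volescape.data_io import SymmetricMatrix
from volescape.landscape import (
    CostModelSpec,
    CostRaster,
    DrainageFeature,
    GridSpec,
    PondFeature,
    VegetationFeature,
    build_cost_surface,
    least_cost_distance,
    rasterize_favorability,
    read_ascii_grid,
    robustness_cv,
    write_ascii_grid,
)
from volescape.distances import euclidean_matrix


def dijkstra_oracle(cost: np.ndarray, cell: float, src, dst) -> float:
    """Independent least-cost path: binary-heap Dijkstra with plain loops."""
    R, C = cost.shape
    dist = {src: 0.0}
    pq = [(0.0, src)]
    seen = set()
    while pq:
        d, (r, c) = heapq.heappop(pq)
        if (r, c) in seen:
            continue
        seen.add((r, c))
        if (r, c) == dst:
            return d
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < R and 0 <= c2 < C):
                    continue
                step = cell * (np.sqrt(2) if dr and dc else 1.0)
                w = step * 0.5 * (cost[r, c] + cost[r2, c2])
                nd = d + w
                if nd < dist.get((r2, c2), np.inf):
                    dist[(r2, c2)] = nd
                    heapq.heappush(pq, (nd, (r2, c2)))
    return np.inf


def center(raster: CostRaster, row: int, col: int):
    x = raster.origin[0] + (col + 0.5) * raster.cell_size
    y = raster.origin[1] + (raster.n_rows - 1 - row + 0.5) * raster.cell_size
    return (x, y)


class TestRasterize:
    def test_full_pond_cell_q_one(self):
        grid = GridSpec((0, 0), 500.0, 4, 4)
        # pond covering one cell entirely (big circle centred on the cell)
        layers = rasterize_favorability(
            [PondFeature((750.0, 750.0), 260.0)], grid
        )
        q = layers["ponds"].data
        r, c = layers["ponds"].cell_of(750.0, 750.0)
        assert q[r, c] == pytest.approx(1.0)

    def test_empty_cell_q_zero(self):
        grid = GridSpec((0, 0), 500.0, 4, 4)
        layers = rasterize_favorability(
            [PondFeature((750.0, 750.0), 100.0)], grid
        )
        assert layers["ponds"].data[0, 3] == 0.0
        assert np.all(layers["drainages"].data == 0.0)

    def test_diagonal_drainage_length(self):
        grid = GridSpec((0, 0), 500.0, 2, 2)
        feat = DrainageFeature([(0.0, 0.0), (500.0, 500.0)])
        layers = rasterize_favorability([feat], grid)
        raster = layers["drainages"]
        r, c = raster.cell_of(250.0, 250.0)
        # diagonal across a 500 m cell is 707.1 m; it is the max cell so q=1
        assert raster.data[r, c] == pytest.approx(1.0)

    def test_vegetation_rank_weights(self):
        grid = GridSpec((0, 0), 500.0, 1, 2)
        full = [(0.0, 0.0), (500.0, 0.0), (500.0, 500.0), (0.0, 500.0)]
        shifted = [(v[0] + 500, v[1]) for v in full]
        layers = rasterize_favorability(
            [VegetationFeature(full, rank=1), VegetationFeature(shifted, rank=3)],
            grid,
        )
        q = layers["vegetation"].data[0]
        assert q[0] == pytest.approx(1.0) and q[1] == pytest.approx(0.5)

    def test_out_of_grid_clipped_with_warning(self):
        grid = GridSpec((0, 0), 500.0, 2, 2)
        with pytest.warns(UserWarning, match="clipped"):
            rasterize_favorability([PondFeature((0.0, 0.0), 300.0)], grid)


class TestCostSurface:
    def test_transform_endpoints(self):
        layer = CostRaster((0, 0), 500.0, np.array([[0.0, 1.0, 0.5]]))
        surf = build_cost_surface(layer, CostModelSpec("ponds", 101.0))
        assert surf.data[0, 0] == 101.0
        assert surf.data[0, 1] == 1.0
        assert surf.data[0, 2] == 51.0

    def test_cmax_must_exceed_one(self):
        layer = CostRaster((0, 0), 500.0, np.zeros((2, 2)))
        with pytest.raises(ValueError):
            build_cost_surface(layer, CostModelSpec("ponds", 1.0))


class TestLeastCostDistance:
    def test_uniform_row_distance(self):
        flat = CostRaster((0, 0), 500.0, np.ones((3, 8)))
        pts = {"a": center(flat, 1, 1), "b": center(flat, 1, 6)}
        lcd = least_cost_distance(flat, pts)
        assert lcd.pair("a", "b") == pytest.approx(5 * 500.0)

    def test_uniform_cost_scales_lcd(self):
        flat1 = CostRaster((0, 0), 500.0, np.ones((4, 6)))
        flat3 = CostRaster((0, 0), 500.0, 3 * np.ones((4, 6)))
        pts = {"a": center(flat1, 0, 0), "b": center(flat1, 3, 5)}
        a = least_cost_distance(flat1, pts).pair("a", "b")
        b = least_cost_distance(flat3, pts).pair("a", "b")
        assert b == pytest.approx(3 * a)

    def test_wall_detour_matches_dijkstra_oracle(self):
        cost = np.ones((5, 5))
        cost[0:4, 2] = 100.0  # wall with a gap at the bottom
        raster = CostRaster((0, 0), 500.0, cost)
        pts = {"a": center(raster, 2, 0), "b": center(raster, 2, 4)}
        lcd = least_cost_distance(raster, pts)
        expected = dijkstra_oracle(cost, 500.0, (2, 0), (2, 4))
        assert lcd.pair("a", "b") == pytest.approx(expected)
        assert lcd.pair("a", "b") > 4 * 500.0  # forced detour

    def test_random_grids_match_dijkstra_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            cost = np.exp(rng.normal(0, 1, size=(5, 5)))
            raster = CostRaster((0, 0), 500.0, cost)
            pts = {"a": center(raster, 0, 0), "b": center(raster, 4, 4)}
            lcd = least_cost_distance(raster, pts).pair("a", "b")
            assert lcd == pytest.approx(
                dijkstra_oracle(cost, 500.0, (0, 0), (4, 4))
            )

    def test_unreachable_pair_infinite(self):
        cost = np.ones((3, 5))
        cost[:, 2] = np.inf
        raster = CostRaster((0, 0), 500.0, cost)
        pts = {"a": center(raster, 1, 0), "b": center(raster, 1, 4)}
        assert np.isinf(least_cost_distance(raster, pts).pair("a", "b"))

    def test_octile_bound_on_uniform_cost(self):
        flat = CostRaster((0, 0), 500.0, np.ones((10, 10)))
        rng = np.random.default_rng(1)
        cells = [(int(r), int(c))
                 for r, c in rng.integers(0, 10, size=(6, 2))]
        pts = {f"p{i}": center(flat, r, c) for i, (r, c) in enumerate(cells)}
        lcd = least_cost_distance(flat, pts)
        eu = euclidean_matrix(pts)
        for i, j in itertools.combinations(range(len(cells)), 2):
            e = eu.values[i, j]
            l = lcd.values[i, j]
            assert e - 1e-9 <= l <= 1.083 * e + 2 * 500.0

    def test_triangle_inequality(self):
        rng = np.random.default_rng(2)
        cost = np.exp(rng.normal(0, 0.5, size=(6, 6)))
        raster = CostRaster((0, 0), 500.0, cost)
        pts = {f"p{i}": center(raster, *rc)
               for i, rc in enumerate([(0, 0), (5, 5), (0, 5), (3, 2)])}
        lcd = least_cost_distance(raster, pts)
        labs = list(pts)
        for a, b, c in itertools.permutations(labs, 3):
            assert lcd.pair(a, c) <= lcd.pair(a, b) + lcd.pair(b, c) + 1e-9


class TestRobustness:
    def test_uniform_landscape_cv_zero(self):
        layer = CostRaster((0, 0), 500.0, 0.4 * np.ones((4, 8)))
        pts = {"a": center(layer, 1, 1), "b": center(layer, 2, 6),
               "c": center(layer, 3, 3)}
        out = robustness_cv(layer, pts, (2, 10, 100))
        assert np.allclose(out["per_pair_cv"], 0.0, atol=1e-12)

    def test_single_pair_mean_only(self):
        layer = CostRaster((0, 0), 500.0, np.ones((3, 5)))
        pts = {"a": center(layer, 1, 1), "b": center(layer, 1, 3)}
        out = robustness_cv(layer, pts, (2, 10, 100))
        assert np.isnan(out["sd_cv"]) and np.isfinite(out["mean_cv"])

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(3)
        layer = CostRaster((0, 0), 500.0, rng.random((5, 7)))
        pts = {"a": center(layer, 1, 1), "b": center(layer, 3, 5),
               "c": center(layer, 4, 2)}
        cmaxes = (2.0, 10.0, 100.0)
        out = robustness_cv(layer, pts, cmaxes)
        lcds = []
        for cm in cmaxes:
            surf = build_cost_surface(layer, CostModelSpec("x", cm))
            v = least_cost_distance(surf, pts).condensed()
            lcds.append(v / v.mean())
        lcds = np.array(lcds)
        cv = lcds.std(axis=0, ddof=1) / lcds.mean(axis=0)
        assert np.allclose(out["per_pair_cv"], cv)

    def test_normalized_lcd_monotone_in_cmax(self):
        rng = np.random.default_rng(4)
        layer = CostRaster((0, 0), 500.0, rng.random((5, 7)))
        pts = {"a": center(layer, 0, 0), "b": center(layer, 4, 6),
               "c": center(layer, 2, 3)}
        flat = CostRaster((0, 0), 500.0, np.ones((5, 7)))
        base = least_cost_distance(flat, pts).condensed()
        prev = None
        for cm in (2, 5, 10, 50, 100):
            surf = build_cost_surface(layer, CostModelSpec("x", cm))
            ratio = least_cost_distance(surf, pts).condensed() / base
            if prev is not None:
                assert np.all(ratio >= prev - 1e-9)
            prev = ratio

    def test_needs_three_cmax(self):
        layer = CostRaster((0, 0), 500.0, np.ones((2, 2)))
        with pytest.raises(ValueError):
            robustness_cv(layer, {"a": (250, 250), "b": (750, 750)}, (2, 10))


class TestAsciiGrid:
    def test_roundtrip(self):
        rng = np.random.default_rng(5)
        r = CostRaster((1000.0, 2000.0), 500.0, rng.random((3, 4)).round(4))
        r2 = read_ascii_grid(write_ascii_grid(r))
        assert r2.origin == r.origin and r2.cell_size == r.cell_size
        assert np.allclose(r2.data, r.data)

    def test_nodata_roundtrip(self):
        data = np.array([[1.0, np.nan], [0.5, 2.0]])
        r = CostRaster((0.0, 0.0), 500.0, data)
        r2 = read_ascii_grid(write_ascii_grid(r))
        assert np.isnan(r2.data[0, 1]) and r2.data[1, 0] == 0.5

    def test_header_mismatch(self):
        with pytest.raises(ValueError):
            read_ascii_grid(
                "ncols 3\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 500\n"
                "NODATA_value -9999\n1 2 3\n"
            )
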