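"""Favorability rasters, cost surfaces and least-cost distances.

The study region is gridded into square cells (500 m by default).  Each
landscape layer stores a favorability q ∈ [0, 1] per cell — the rescaled
proportion of pond surface, drainage length or preference-weighted
vegetation cover.  A cost surface maps favorability to a dispersal cost
cost(q) = 1 + (C_max − 1)·(1 − q), so fully favorable cells cost 1 and
barren cells cost C_max.  Least-cost distances run over the 8-connected
cell graph with edge weight = step length × mean cost of the two cells.
A robustness analysis recomputes least-cost distances over a range of
C_max values and summarizes the per-pair coefficient of variation of the
scale-normalized distances.
"""

from __future__ import annotations

import io
import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import LineString, Point, Polygon, box

from .data_io import SymmetricMatrix

__all__ = [
    "CostRaster",
    "CostModelSpec",
    "PondFeature",
    "DrainageFeature",
    "VegetationFeature",
    "read_ascii_grid",
    "write_ascii_grid",
    "rasterize_favorability",
    "build_cost_surface",
    "least_cost_distance",
    "robustness_cv",
]

VEG_RANK_SCORE = {1: 1.00, 2: 0.75, 3: 0.50, 4: 0.25, 5: 0.00}


@dataclass
class CostRaster:
    """A gridded layer: favorability or cost, origin at the lower-left corner."""

    origin: tuple[float, float]   # (easting, northing) of lower-left corner
    cell_size: float
    data: np.ndarray              # (n_rows, n_cols), row 0 = northernmost

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        # snap origin to a multiple of the cell size (PathMatrix convention)
        self.origin = (
            round(self.origin[0] / self.cell_size) * self.cell_size,
            round(self.origin[1] / self.cell_size) * self.cell_size,
        )

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; row 0 is the top."""
        col = int((x - self.origin[0]) // self.cell_size)
        row_from_bottom = int((y - self.origin[1]) // self.cell_size)
        row = self.n_rows - 1 - row_from_bottom
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside the grid")
        return row, col

    def cell_box(self, row: int, col: int):
        x0 = self.origin[0] + col * self.cell_size
        y0 = self.origin[1] + (self.n_rows - 1 - row) * self.cell_size
        return box(x0, y0, x0 + self.cell_size, y0 + self.cell_size)


@dataclass
class CostModelSpec:
    """Cost model: layer name plus the maximum cost of fully unfavorable cells."""

    layer: str
    c_max: float

    def cost(self, q: np.ndarray) -> np.ndarray:
        if self.c_max <= 1:
            raise ValueError("C_max must exceed 1")
        return 1.0 + (self.c_max - 1.0) * (1.0 - np.asarray(q, dtype=float))


@dataclass
class PondFeature:
    center: tuple[float, float]
    radius: float

    def geometry(self):
        return Point(self.center).buffer(self.radius, quad_segs=64)


@dataclass
class DrainageFeature:
    points: list[tuple[float, float]]

    def geometry(self):
        return LineString(self.points)


@dataclass
class VegetationFeature:
    vertices: list[tuple[float, float]]
    rank: int  # 1 (most preferred) .. 5 (least)

    def geometry(self):
        return Polygon(self.vertices)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def read_ascii_grid(text: str) -> CostRaster:
    lines = text.strip().splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            hdr[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    data = np.loadtxt(io.StringIO("\n".join(lines[i:])))
    data = np.atleast_2d(data)
    if data.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
        raise ValueError("grid body does not match header dimensions")
    if "nodata_value" in hdr:
        data = np.where(data == hdr["nodata_value"], np.nan, data)
    return CostRaster(
        origin=(hdr["xllcorner"], hdr["yllcorner"]),
        cell_size=hdr["cellsize"],
        data=data,
    )


def write_ascii_grid(raster: CostRaster, nodata: float = -9999.0) -> str:
    out = io.StringIO()
    out.write(f"ncols {raster.n_cols}\n")
    out.write(f"nrows {raster.n_rows}\n")
    out.write(f"xllcorner {raster.origin[0]:.6f}\n")
    out.write(f"yllcorner {raster.origin[1]:.6f}\n")
    out.write(f"cellsize {raster.cell_size:.6f}\n")
    out.write(f"NODATA_value {nodata:g}\n")
    body = np.where(np.isnan(raster.data), nodata, raster.data)
    for row in body:
        out.write(" ".join(f"{v:.6g}" for v in row) + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    origin: tuple[float, float]
    cell_size: float
    n_rows: int
    n_cols: int

    def empty(self) -> CostRaster:
        return CostRaster(self.origin, self.cell_size,
                          np.zeros((self.n_rows, self.n_cols)))


def rasterize_favorability(features: list, grid: GridSpec) -> dict[str, CostRaster]:
    """Build favorability layers (q ∈ [0,1]) from geometric features.

    * ponds: q = pond-area fraction per cell, rescaled by the maximum cell;
    * drainages: q = drainage length per cell, rescaled likewise;
    * vegetation: q = area-weighted preference score, ranks 1–5 mapping to
      scores (1.00, 0.75, 0.50, 0.25, 0.00).

    Features extending outside the grid are clipped with a warning.
    """
    ponds = grid.empty()
    drains = grid.empty()
    veg = grid.empty()
    cell_area = grid.cell_size**2
    extent = box(
        grid.origin[0],
        grid.origin[1],
        grid.origin[0] + grid.n_cols * grid.cell_size,
        grid.origin[1] + grid.n_rows * grid.cell_size,
    )
    for feat in features:
        geom = feat.geometry()
        if not extent.contains(geom):
            warnings.warn(f"feature {feat} extends outside the grid; clipped")
            geom = geom.intersection(extent)
            if geom.is_empty:
                continue
        minx, miny, maxx, maxy = geom.bounds
        c0 = max(0, int((minx - grid.origin[0]) // grid.cell_size))
        c1 = min(grid.n_cols - 1, int((maxx - grid.origin[0]) // grid.cell_size))
        rb0 = max(0, int((miny - grid.origin[1]) // grid.cell_size))
        rb1 = min(grid.n_rows - 1, int((maxy - grid.origin[1]) // grid.cell_size))
        for rb in range(rb0, rb1 + 1):
            row = grid.n_rows - 1 - rb
            for col in range(c0, c1 + 1):
                cell = ponds.cell_box(row, col)
                inter = geom.intersection(cell)
                if inter.is_empty:
                    continue
                if isinstance(feat, PondFeature):
                    ponds.data[row, col] += inter.area / cell_area
                elif isinstance(feat, DrainageFeature):
                    drains.data[row, col] += inter.length
                elif isinstance(feat, VegetationFeature):
                    veg.data[row, col] += (
                        VEG_RANK_SCORE[feat.rank] * inter.area / cell_area
                    )
    for layer in (ponds, drains, veg):
        m = np.nanmax(layer.data)
        if m > 0:
            layer.data /= m
        layer.data = np.clip(layer.data, 0.0, 1.0)
    return {"ponds": ponds, "drainages": drains, "vegetation": veg}


def build_cost_surface(layer: CostRaster, spec: CostModelSpec) -> CostRaster:
    """Cost raster from a favorability layer: cost = 1 + (C_max−1)(1−q)."""
    return CostRaster(layer.origin, layer.cell_size, spec.cost(layer.data))


# ---------------------------------------------------------------------------
# least-cost distances
# ---------------------------------------------------------------------------

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _cost_graph(cost: CostRaster):
    R, C = cost.n_rows, cost.n_cols
    cs = cost.cell_size
    rows_i, cols_j, w = [], [], []
    idx = np.arange(R * C).reshape(R, C)
    for dr, dc in _NEIGHBORS:
        if (dr, dc) < (0, 0) or (dr, dc) == (0, -1):
            continue  # add each undirected edge once
        r0, r1 = max(0, -dr), min(R, R - dr)
        c0, c1 = max(0, -dc), min(C, C - dc)
        src = idx[r0:r1, c0:c1]
        dst = idx[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        step = cs * (np.sqrt(2.0) if dr and dc else 1.0)
        cc = 0.5 * (
            cost.data[r0:r1, c0:c1] + cost.data[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        )
        rows_i.append(src.ravel())
        cols_j.append(dst.ravel())
        w.append((step * cc).ravel())
    rows_i = np.concatenate(rows_i)
    cols_j = np.concatenate(cols_j)
    w = np.concatenate(w)
    finite = np.isfinite(w)
    return coo_matrix(
        (w[finite], (rows_i[finite], cols_j[finite])), shape=(R * C, R * C)
    ).tocsr()


def least_cost_distance(
    cost: CostRaster, points: dict[str, tuple[float, float]]
) -> SymmetricMatrix:
    """Least-cost distances (cost-weighted meters) between labelled points.

    Points snap to the center of their containing cell.  Paths run on the
    8-connected cell graph; a diagonal step costs √2 × cell size times the
    mean of the two cells' costs.  Unreachable pairs are flagged infinite.
    """
    labels = list(points)
    cells = [cost.cell_of(*points[l]) for l in labels]
    nodes = np.array([r * cost.n_cols + c for r, c in cells])
    graph = _cost_graph(cost)
    uniq, inv = np.unique(nodes, return_inverse=True)
    dmat = dijkstra(graph, directed=False, indices=uniq)
    k = len(labels)
    out = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        out[i, j] = out[j, i] = dmat[inv[i], nodes[j]]
    return SymmetricMatrix(labels, out, "cost-weighted meters")


def robustness_cv(
    layer: CostRaster,
    points: dict[str, tuple[float, float]],
    cmax_set: tuple[float, ...] = (2, 5, 10, 50, 100, 1000),
    layer_name: str = "layer",
) -> dict:
    """Sensitivity of least-cost distances to the arbitrary maximum cost.

    For each C_max the LCD matrix is normalized by its mean over pairs
    (pure rescaling of all costs then cancels), and the per-pair coefficient
    of variation sd/mean is taken across the C_max values.  Returns the
    per-pair CVs plus their mean ± sd over pairs.  Pairs with an infinite
    LCD under any C_max are excluded with a warning.
    """
    if len(cmax_set) < 3:
        raise ValueError("need at least 3 C_max values")
    lcds = []
    for c_max in cmax_set:
        surf = build_cost_surface(layer, CostModelSpec(layer_name, c_max))
        lcd = least_cost_distance(surf, points).condensed()
        lcds.append(lcd)
    lcds = np.array(lcds)  # (n_cmax, n_pairs)
    finite = np.isfinite(lcds).all(axis=0) & (lcds > 0).all(axis=0)
    if not finite.all():
        warnings.warn("pairs with infinite/zero LCD excluded from CV")
    norm = lcds[:, finite] / lcds[:, finite].mean(axis=1, keepdims=True)
    cv = norm.std(axis=0, ddof=1) / norm.mean(axis=0)
    return {
        "per_pair_cv": cv,
        "mean_cv": float(cv.mean()) if cv.size else np.nan,
        "sd_cv": float(cv.std(ddof=1)) if cv.size > 1 else np.nan,
        "cmax_set": tuple(cmax_set),
    }
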