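"""Variably sized analysis grid.

Concentrations, emissions and the source-receptor matrix all live on a
single planar grid of axis-aligned square cells whose side lengths form a
dyadic ladder (finest × 2^k).  The grid is built by quadtree refinement of
coarse tiles, driven by population: any tile larger than the finest size is
split into four children if it contains more than ``max_pop`` people or
overlaps a block group denser than ``max_density`` people per km².  This
mirrors reduced-complexity air-quality models that resolve populated areas
at ~1 km while leaving remote areas coarse.

Cell boundaries are half-open ``[x0, x1) × [y0, y1)`` so every interior
point belongs to exactly one cell.  Stable integer ids are assigned by
Morton (Z-order) traversal of the final tree, making rebuilds reproducible.
All coordinates are planar meters in a projected convention; no geodesy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import box, mapping
from shapely.strtree import STRtree

from .errors import ConfigError, DataError, OutsideDomainError

__all__ = [
    "VariableGrid",
    "PopulationSurface",
    "build_grid",
    "grid_summary",
    "point_to_cell",
]

_M2_PER_KM2 = 1.0e6


@dataclass(frozen=True)
class VariableGrid:
    """An exact tiling of a rectangular domain by dyadic square cells.

    Attributes
    ----------
    x0, y0 : ndarray of float
        Lower-left corner of each cell (meters).
    side : ndarray of float
        Side length of each cell (meters); values lie on the ladder
        ``finest * 2**k``.
    domain : tuple
        ``(xmin, ymin, xmax, ymax)`` in meters.
    """

    x0: np.ndarray
    y0: np.ndarray
    side: np.ndarray
    domain: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        n = len(self.x0)
        if not (len(self.y0) == len(self.side) == n):
            raise DataError("grid arrays must have equal length")
        if n == 0:
            raise DataError("grid has no cells")
        xmin, ymin, xmax, ymax = self.domain
        area = np.sum(self.side.astype(float) ** 2)
        dom_area = (xmax - xmin) * (ymax - ymin)
        if not np.isclose(area, dom_area, rtol=1e-9):
            raise DataError(
                f"cells do not tile the domain: cell area {area} vs domain {dom_area}"
            )

    @property
    def n(self) -> int:
        return len(self.side)

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of cell centroids."""
        return np.column_stack([self.x0 + self.side / 2, self.y0 + self.side / 2])

    @property
    def areas(self) -> np.ndarray:
        """Cell areas in m²."""
        return self.side.astype(float) ** 2

    @property
    def finest(self) -> float:
        return float(self.side.min())

    def fingerprint(self) -> str:
        """Stable hash of the grid geometry, used to guard artifact reuse."""
        h = hashlib.sha256()
        for arr in (self.x0, self.y0, self.side):
            h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
        h.update(repr(tuple(float(v) for v in self.domain)).encode())
        return h.hexdigest()[:16]

    def cell_polygon(self, i: int):
        return box(
            float(self.x0[i]),
            float(self.y0[i]),
            float(self.x0[i] + self.side[i]),
            float(self.y0[i] + self.side[i]),
        )

    def cell_polygons(self) -> list:
        return [self.cell_polygon(i) for i in range(self.n)]

    # -- lookup ----------------------------------------------------------

    def point_to_cell(self, x: float, y: float) -> int:
        """Map a point to the unique cell containing it (half-open rule)."""
        xmin, ymin, xmax, ymax = self.domain
        if not (xmin <= x < xmax and ymin <= y < ymax):
            raise OutsideDomainError(f"point ({x}, {y}) outside domain {self.domain}")
        hit = np.flatnonzero(
            (self.x0 <= x)
            & (x < self.x0 + self.side)
            & (self.y0 <= y)
            & (y < self.y0 + self.side)
        )
        # tiling invariant guarantees exactly one hit
        return int(hit[0])

    def points_to_cells(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        return np.array([self.point_to_cell(x, y) for x, y in zip(xs, ys)], dtype=int)

    # -- serialization ---------------------------------------------------

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {"id": np.arange(self.n), "x0": self.x0, "y0": self.y0, "side_m": self.side}
        )
        with open(path, "w") as fh:
            fh.write(f"# roadpm grid; planar meters; domain={self.domain}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "VariableGrid":
        import pandas as pd

        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise DataError("grid CSV missing domain header line")
            domain = tuple(
                float(v) for v in header.split("domain=")[1].strip(" ()\n").split(",")
            )
            df = pd.read_csv(fh)
        df = df.sort_values("id")
        return cls(
            x0=df["x0"].to_numpy(float),
            y0=df["y0"].to_numpy(float),
            side=df["side_m"].to_numpy(float),
            domain=domain,  # type: ignore[arg-type]
        )

    def to_geojson(self, path) -> None:
        features = []
        for i in range(self.n):
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(self.cell_polygon(i)),
                    "properties": {"id": i, "side_m": float(self.side[i])},
                }
            )
        doc = {
            "type": "FeatureCollection",
            "crs_note": "planar projected coordinates, meters",
            "domain": list(self.domain),
            "features": features,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


@dataclass(frozen=True)
class PopulationSurface:
    """Block-group-like population polygons driving grid refinement.

    ``polygons`` are shapely polygons, ``population`` the people counts.
    Density (people per km²) is derived from polygon area.
    """

    polygons: Sequence
    population: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if len(self.polygons) != len(self.population):
            raise DataError("polygons and population must have equal length")
        if np.any(np.asarray(self.population) < 0):
            raise DataError("population counts must be non-negative")

    @property
    def density(self) -> np.ndarray:
        areas = np.array([p.area for p in self.polygons])
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(areas > 0, self.population / (areas / _M2_PER_KM2), 0.0)


def _validate_ladder(finest: float, coarsest: float) -> int:
    if finest <= 0 or coarsest <= 0:
        raise ConfigError("finest and coarsest must be positive")
    ratio = coarsest / finest
    k = round(np.log2(ratio))
    if k < 0 or not np.isclose(ratio, 2.0**k, rtol=1e-12):
        raise ConfigError(
            f"coarsest ({coarsest}) must equal finest ({finest}) times a power of two"
        )
    return int(k)


def build_grid(
    population_surface: PopulationSurface,
    domain: tuple[float, float, float, float],
    finest: float = 1000.0,
    coarsest: float = 64000.0,
    max_pop: float = 20000.0,
    max_density: float = 2500.0,
) -> VariableGrid:
    """Quadtree-refine coarse tiles into a population-resolving grid.

    A tile larger than ``finest`` is split into four children when the
    population contained in it (area-apportioned from the block groups)
    exceeds ``max_pop`` people, or when it overlaps any block group whose
    density exceeds ``max_density`` people/km².  Splits are all-or-none:
    a violating parent always produces four children even if three are
    empty.  Recursion stops at ``finest``.

    Parameters
    ----------
    population_surface
        Block-group polygons with population counts.
    domain
        ``(xmin, ymin, xmax, ymax)``; width and height must be positive
        multiples of ``coarsest``.
    finest, coarsest
        Dyadic ladder endpoints in meters (``coarsest = finest * 2**k``).
    max_pop
        Contained-population split threshold (people).
    max_density
        Block-group density split threshold (people per km²).
    """
    _validate_ladder(finest, coarsest)
    if max_pop <= 0 or max_density <= 0:
        raise ConfigError("thresholds must be positive")
    xmin, ymin, xmax, ymax = (float(v) for v in domain)
    w, h = xmax - xmin, ymax - ymin
    if w <= 0 or h <= 0:
        raise ConfigError("degenerate domain extent")
    nx, ny = w / coarsest, h / coarsest
    if not (np.isclose(nx, round(nx)) and np.isclose(ny, round(ny))):
        raise ConfigError(
            f"domain size ({w} x {h}) must be a multiple of coarsest ({coarsest})"
        )
    nx, ny = int(round(nx)), int(round(ny))

    polys = list(population_surface.polygons)
    pops = np.asarray(population_surface.population, dtype=float)
    dens = population_surface.density
    bg_areas = np.array([p.area for p in polys])
    tree = STRtree(polys) if polys else None

    def contained_pop_and_density_hit(x0: float, y0: float, side: float):
        cell = box(x0, y0, x0 + side, y0 + side)
        if tree is None:
            return 0.0, False
        idx = tree.query(cell)
        pop = 0.0
        dense_hit = False
        for j in idx:
            inter = polys[j].intersection(cell)
            if inter.is_empty or inter.area <= 0:
                continue  # mere touching does not count as overlap
            if bg_areas[j] > 0:
                pop += pops[j] * inter.area / bg_areas[j]
            if dens[j] > max_density:
                dense_hit = True
        return pop, dense_hit

    leaves_x: list[float] = []
    leaves_y: list[float] = []
    leaves_s: list[float] = []

    def refine(x0: float, y0: float, side: float) -> None:
        if side > finest:
            pop, dense = contained_pop_and_density_hit(x0, y0, side)
            if pop > max_pop or dense:
                half = side / 2
                # Morton (Z-order) child traversal: SW, SE, NW, NE
                refine(x0, y0, half)
                refine(x0 + half, y0, half)
                refine(x0, y0 + half, half)
                refine(x0 + half, y0 + half, half)
                return
        leaves_x.append(x0)
        leaves_y.append(y0)
        leaves_s.append(side)

    for iy in range(ny):
        for ix in range(nx):
            refine(xmin + ix * coarsest, ymin + iy * coarsest, coarsest)

    return VariableGrid(
        x0=np.array(leaves_x),
        y0=np.array(leaves_y),
        side=np.array(leaves_s),
        domain=(xmin, ymin, xmax, ymax),
    )


def point_to_cell(grid: VariableGrid, x: float, y: float) -> int:
    """Functional wrapper for :meth:`VariableGrid.point_to_cell`."""
    return grid.point_to_cell(x, y)


def grid_summary(
    grid: VariableGrid,
    cell_population: np.ndarray,
    urban_density_threshold: float = 2500.0,
) -> dict:
    """Population-weighted grid statistics.

    Returns the fraction of cells at the finest size and the
    population-weighted mean cell side, overall and split into urban
    (cell density above ``urban_density_threshold`` people/km²) and rural
    cells.

    ``cell_population`` is the per-cell total population (people), e.g.
    from :func:`roadpm.popmap.intersect_tracts_with_grid`.
    """
    pop = np.asarray(cell_population, dtype=float)
    if pop.shape != (grid.n,):
        raise DataError("cell_population must have one entry per grid cell")
    if np.any(pop < 0):
        raise DataError("cell populations must be non-negative")
    total = pop.sum()
    if total <= 0:
        raise DataError("grid summary undefined for zero total population")
    finest = grid.finest
    side = grid.side.astype(float)
    density = pop / (grid.areas / _M2_PER_KM2)
    urban = density > urban_density_threshold

    def wmean(mask: np.ndarray) -> float:
        p = pop[mask]
        return float(np.sum(p * side[mask]) / p.sum()) if p.sum() > 0 else float("nan")

    return {
        "fraction_finest": float(np.mean(side == finest)),
        "pop_weighted_mean_size": float(np.sum(pop * side) / total),
        "pop_weighted_mean_size_urban": wmean(urban),
        "pop_weighted_mean_size_rural": wmean(~urban),
    }
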