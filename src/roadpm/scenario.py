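"""Synthetic multi-year vehicle-emission scenarios with known ground truth.

Real inputs to an exposure-disparity analysis — a regulatory emission
inventory gridded to ~1 km, a source-receptor matrix, and census tract
demographics — are large external datasets.  This module generates small
planar stand-ins that preserve the statistical structure the analysis
depends on, so every downstream stage is testable offline:

* a road network in which light-duty traffic concentrates on arterials
  running through the population core while heavy-duty traffic follows a
  freight corridor offset from it (distinct spatial footprints per fleet);
* per-year emissions that follow multiplicative annual trends per
  (species, process) — by default a ~70 % two-decade decline for exhaust
  PM2.5 / NOx / VOC, ~15 % for NH3, and a ~20 % *increase* for brake- and
  tire-wear PM2.5;
* spatially segregated demographics: a ``segregation`` dial in [0, 1]
  moves group A (and, on the freight corridor, group B) toward the
  emission corridors, with all groups spatially exchangeable at 0.

Everything is deterministic under a fixed seed: a single root seed
sequence spawns one child stream per operation in a fixed order.
All output counts are real-valued so that areal apportionment is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box

from .errors import ConfigError, DataError
from .grid import PopulationSurface, VariableGrid
from .popmap import DemographicTable, TractSet

__all__ = [
    "ScenarioConfig",
    "SyntheticTruth",
    "Road",
    "EmissionInventory",
    "make_road_network",
    "make_emissions",
    "make_population",
    "designate_communities",
    "generate_scenario",
]

DEFAULT_FLEETS = ("LDV", "MDV", "HDV", "OTH")
DEFAULT_SPECIES = ("PM25", "NOX", "VOC", "NH3", "SOX")
DEFAULT_PROCESSES = ("exhaust", "evaporative", "brake_wear", "tire_wear")
DEFAULT_GROUPS = ("A", "B", "C", "D", "other")
DEFAULT_YEARS = tuple(range(2000, 2020))

# Emission mass emitted per unit of fleet activity, by (species, process).
# Magnitudes are nominal "tons per activity unit"; the precursor gases
# (NOx, VOC) dominate by mass, primary PM2.5 is small but potent, and
# non-exhaust wear starts at roughly 15 % of primary PM2.5.
DEFAULT_BASE_RATES: dict[tuple[str, str], float] = {
    ("PM25", "exhaust"): 1.0,
    ("NOX", "exhaust"): 10.0,
    ("VOC", "exhaust"): 8.0,
    ("NH3", "exhaust"): 0.5,
    ("SOX", "exhaust"): 0.1,
    ("VOC", "evaporative"): 2.0,
    ("PM25", "brake_wear"): 0.10,
    ("PM25", "tire_wear"): 0.08,
}

# Annual multiplicative trend factors chosen so the cumulative change over
# the default 20-year horizon (19 annual steps) matches the scenario's
# aggregate targets: -70 % exhaust PM25/NOX/VOC (and SOX), -15 % NH3,
# +20 % brake/tire wear.
_N_STEPS = len(DEFAULT_YEARS) - 1
_DECLINE70 = 0.30 ** (1.0 / _N_STEPS)
_DECLINE15 = 0.85 ** (1.0 / _N_STEPS)
_GROWTH20 = 1.20 ** (1.0 / _N_STEPS)
DEFAULT_TREND_RATES: dict[tuple[str, str], float] = {
    ("PM25", "exhaust"): _DECLINE70,
    ("NOX", "exhaust"): _DECLINE70,
    ("VOC", "exhaust"): _DECLINE70,
    ("NH3", "exhaust"): _DECLINE15,
    ("SOX", "exhaust"): _DECLINE70,
    ("VOC", "evaporative"): _DECLINE70,
    ("PM25", "brake_wear"): _GROWTH20,
    ("PM25", "tire_wear"): _GROWTH20,
}

#: activity budget per fleet (nominal vehicle-kilometre units); light-duty
#: dominates, as in any on-road inventory.
DEFAULT_FLEET_ACTIVITY: dict[str, float] = {
    "LDV": 100.0,
    "MDV": 15.0,
    "HDV": 25.0,
    "OTH": 5.0,
}

#: share of each fleet's activity on the arterial system vs the freight
#: corridor; heavy-duty traffic is predominantly freight.
_ROUTE_SHARES: dict[str, tuple[float, float]] = {
    "LDV": (0.85, 0.15),
    "MDV": (0.55, 0.45),
    "HDV": (0.15, 0.85),
    "OTH": (0.75, 0.25),
}
_DEFAULT_ROUTE_SHARE = (0.70, 0.30)

#: baseline demographic composition (abstract groups, not census data)
_BASE_SHARES: dict[str, float] = {
    "A": 0.35,
    "B": 0.12,
    "C": 0.15,
    "D": 0.33,
    "other": 0.05,
}


def _unique_nonempty(name: str, labels: Sequence[str]) -> tuple[str, ...]:
    labels = tuple(labels)
    if not labels or len(set(labels)) != len(labels):
        raise ConfigError(f"{name} must be a non-empty set of unique labels")
    return labels


@dataclass(frozen=True)
class ScenarioConfig:
    """Declarative description of a synthetic scenario.

    ``trend_rates`` maps (species, process) to a strictly positive
    multiplicative annual change factor; ``base_rates`` to the base-year
    emission mass per unit fleet activity.  ``segregation`` in [0, 1]
    controls how strongly group shares tilt toward the emission
    corridors (0 = spatially exchangeable groups).
    """

    domain: tuple[float, float, float, float] = (0.0, 0.0, 32000.0, 32000.0)
    years: tuple[int, ...] = DEFAULT_YEARS
    fleets: tuple[str, ...] = DEFAULT_FLEETS
    species: tuple[str, ...] = DEFAULT_SPECIES
    processes: tuple[str, ...] = DEFAULT_PROCESSES
    groups: tuple[str, ...] = DEFAULT_GROUPS
    trend_rates: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TREND_RATES)
    )
    base_rates: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_RATES)
    )
    fleet_activity: Mapping[str, float] | None = None
    segregation: float = 0.6
    n_tracts: int = 144
    total_population: float = 400_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.domain
        if xmax <= xmin or ymax <= ymin:
            raise ConfigError("degenerate domain extent (zero area)")
        years = tuple(int(y) for y in self.years)
        if len(years) == 0 or any(b <= a for a, b in zip(years, years[1:])):
            raise ConfigError("years must be strictly increasing")
        object.__setattr__(self, "years", years)
        for nm in ("fleets", "species", "processes", "groups"):
            object.__setattr__(self, nm, _unique_nonempty(nm, getattr(self, nm)))
        # partial overrides merge onto the defaults
        object.__setattr__(
            self, "trend_rates", {**DEFAULT_TREND_RATES, **dict(self.trend_rates)}
        )
        object.__setattr__(
            self, "base_rates", {**DEFAULT_BASE_RATES, **dict(self.base_rates)}
        )
        if not 0.0 <= self.segregation <= 1.0:
            raise ConfigError("segregation must be in [0, 1]")
        if self.n_tracts < 4:
            raise ConfigError("n_tracts must be at least 4")
        if self.total_population <= 0:
            raise ConfigError("total_population must be positive")
        for key, f in self.trend_rates.items():
            if f <= 0:
                raise ConfigError(f"trend factor for {key} must be strictly positive")
        for key, r in self.base_rates.items():
            if r < 0:
                raise ConfigError(f"base rate for {key} must be non-negative")
        if self.fleet_activity is None:
            object.__setattr__(
                self,
                "fleet_activity",
                {f: DEFAULT_FLEET_ACTIVITY.get(f, 10.0) for f in self.fleets},
            )
        else:
            fa = dict(self.fleet_activity)
            missing = [f for f in self.fleets if f not in fa]
            if missing:
                raise ConfigError(f"fleet_activity missing fleets: {missing}")
            if any(v < 0 for v in fa.values()):
                raise ConfigError("fleet activity budgets must be non-negative")
            object.__setattr__(self, "fleet_activity", fa)
        # every emitting (species, process) combination needs a trend factor
        for key, r in self.base_rates.items():
            if r > 0 and key not in self.trend_rates:
                raise ConfigError(f"no trend factor defined for emitting slice {key}")

    # sub-streams are spawned in a fixed order so each operation is
    # individually deterministic regardless of call order
    def _rng(self, stream: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return np.random.default_rng(children[stream])

    def cumulative_factor(self, species: str, process: str, year: int) -> float:
        f = self.trend_rates.get((species, process), 1.0)
        return f ** (year - self.years[0])


@dataclass
class SyntheticTruth:
    """Ground truth recorded at generation time for parameter-recovery tests."""

    group_exposure_ordering: tuple[str, ...]
    segregation_used: float
    emission_totals: pd.DataFrame | None = None  # (year, species, fleet, process)


@dataclass(frozen=True)
class Road:
    name: str
    kind: str  # "arterial" | "freight"
    geometry: LineString
    weights: Mapping[str, float]  # fleet -> activity on this road


def make_road_network(config: ScenarioConfig) -> list[Road]:
    """Lay out arterials through the population core plus an offset freight
    corridor, and allocate each fleet's activity budget across them.

    Corridor positions are jittered slightly per seed (and never coincide
    with kilometre gridlines).  Per-fleet road weights sum exactly to the
    configured activity budget.
    """
    rng = config._rng(0)
    xmin, ymin, xmax, ymax = config.domain
    W, H = xmax - xmin, ymax - ymin
    y_art = ymin + (0.52 + rng.uniform(-0.03, 0.03)) * H
    x_art = xmin + (0.48 + rng.uniform(-0.03, 0.03)) * W
    y_fr = ymin + (0.22 + rng.uniform(-0.03, 0.03)) * H

    main = LineString([(xmin, y_art), (xmax, y_art)])
    cross = LineString([(x_art, ymin), (x_art, ymax)])
    freight = LineString([(xmin, y_fr), (xmax, y_fr)])

    art_len = main.length + cross.length
    roads = []
    for name, kind, geom, frac_within in (
        ("arterial_main", "arterial", main, main.length / art_len),
        ("arterial_cross", "arterial", cross, cross.length / art_len),
        ("freight_corridor", "freight", freight, 1.0),
    ):
        weights = {}
        for fleet in config.fleets:
            art_share, fr_share = _ROUTE_SHARES.get(fleet, _DEFAULT_ROUTE_SHARE)
            budget = config.fleet_activity[fleet]
            share = art_share if kind == "arterial" else fr_share
            weights[fleet] = budget * share * frac_within
        roads.append(Road(name, kind, geom, weights))
    return roads


class EmissionInventory:
    """Annual emissions indexed by (year, cell, fleet, species, process).

    Long-format table with a ``mass_per_year`` column (nominal tons/yr);
    zero entries are omitted.  ``n`` is the grid size and
    ``grid_fingerprint`` ties the inventory to the grid it was rasterized
    on.
    """

    COLUMNS = ["year", "cell_id", "fleet", "species", "process", "mass_per_year"]

    def __init__(self, df: pd.DataFrame, n: int, grid_fingerprint: str):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"emission table missing columns: {missing}")
        if (df["mass_per_year"] < 0).any():
            raise DataError("emissions must be non-negative")
        self.df = df.reset_index(drop=True)
        self.n = int(n)
        self.grid_fingerprint = grid_fingerprint

    def labels(self, dim: str) -> tuple[str, ...]:
        return tuple(sorted(self.df[dim].unique()))

    def _mask(self, year, species=None, fleets=None, processes=None) -> pd.Series:
        m = self.df["year"] == year
        if species is not None:
            sp = [species] if isinstance(species, str) else list(species)
            m &= self.df["species"].isin(sp)
        if fleets is not None:
            fl = [fleets] if isinstance(fleets, str) else list(fleets)
            m &= self.df["fleet"].isin(fl)
        if processes is not None:
            pr = [processes] if isinstance(processes, str) else list(processes)
            m &= self.df["process"].isin(pr)
        return m

    def vector(self, year, species=None, fleets=None, processes=None) -> np.ndarray:
        """Per-cell emission totals for a slice, as a dense length-n vector."""
        sub = self.df[self._mask(year, species, fleets, processes)]
        v = np.zeros(self.n)
        np.add.at(v, sub["cell_id"].to_numpy(), sub["mass_per_year"].to_numpy())
        return v

    def total(self, year, species=None, fleets=None, processes=None) -> float:
        return float(
            self.df.loc[self._mask(year, species, fleets, processes), "mass_per_year"].sum()
        )

    def to_csv(self, path) -> None:
        self.df[self.COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n: int, grid_fingerprint: str) -> "EmissionInventory":
        return cls(pd.read_csv(path), n, grid_fingerprint)


def make_emissions(
    config: ScenarioConfig, grid: VariableGrid, roads: Sequence[Road]
) -> EmissionInventory:
    """Rasterize road activity to the grid and apply annual trends.

    A road's activity is allocated to cells in proportion to the length of
    road falling in each cell; emissions in year *t* equal base-year
    emissions times the cumulative (species, process) trend factor.
    """
    dom = box(*grid.domain)
    for road in roads:
        if not dom.covers(road.geometry):
            raise DataError(f"road {road.name!r} extends outside the grid domain")
        for fleet, w in road.weights.items():
            if w < 0:
                raise DataError(f"negative activity weight on road {road.name!r}")

    cell_polys = grid.cell_polygons()
    from shapely.strtree import STRtree

    tree = STRtree(cell_polys)
    # base-year activity per (cell, fleet)
    activity: dict[tuple[int, str], float] = {}
    for road in roads:
        lengths: dict[int, float] = {}
        for ci in tree.query(road.geometry):
            seg = road.geometry.intersection(cell_polys[ci])
            if seg.is_empty or seg.length <= 0:
                continue
            lengths[int(ci)] = seg.length
        tot = sum(lengths.values())  # self-normalizing against edge overlap
        if tot <= 0:
            continue
        for ci, ln in lengths.items():
            for fleet, w in road.weights.items():
                if w > 0:
                    activity[(ci, fleet)] = activity.get((ci, fleet), 0.0) + w * ln / tot

    emitting = [(sp, pr) for (sp, pr), r in config.base_rates.items() if r > 0
                if sp in config.species and pr in config.processes]
    rows = []
    for year in config.years:
        for (sp, pr) in emitting:
            rate = config.base_rates[(sp, pr)] * config.cumulative_factor(sp, pr, year)
            for (ci, fleet), act in activity.items():
                rows.append((year, ci, fleet, sp, pr, act * rate))
    df = pd.DataFrame(rows, columns=EmissionInventory.COLUMNS)
    df = df.sort_values(["year", "species", "process", "fleet", "cell_id"]).reset_index(
        drop=True
    )
    return EmissionInventory(df, grid.n, grid.fingerprint())


def _tessellate(config: ScenarioConfig) -> TractSet:
    """Tile the domain with exactly n_tracts rectangles."""
    xmin, ymin, xmax, ymax = config.domain
    n = config.n_tracts
    cols = int(np.ceil(np.sqrt(n)))
    full_rows, rem = divmod(n, cols)
    n_rows = full_rows + (1 if rem else 0)
    row_h = (ymax - ymin) / n_rows
    polys, ids = [], []
    tid = 0
    for r in range(n_rows):
        ncol = cols if (r < full_rows) else rem
        col_w = (xmax - xmin) / ncol
        y0 = ymin + r * row_h
        for c in range(ncol):
            x0 = xmin + c * col_w
            polys.append(box(x0, y0, x0 + col_w, y0 + row_h))
            ids.append(tid)
            tid += 1
    return TractSet(ids=np.array(ids), polygons=polys)


def _corridor_proximity(
    tracts: TractSet, roads: Sequence[Road], scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tract exp(-d/scale) proximity to arterial and freight corridors."""
    cents = [p.centroid for p in tracts.polygons]
    art = [r.geometry for r in roads if r.kind == "arterial"]
    fr = [r.geometry for r in roads if r.kind == "freight"]
    d_art = np.array([min(g.distance(c) for g in art) if art else np.inf for c in cents])
    d_fr = np.array([min(g.distance(c) for g in fr) if fr else np.inf for c in cents])
    return np.exp(-d_art / scale), np.exp(-d_fr / scale)


def make_population(
    config: ScenarioConfig, roads: Sequence[Road] | None = None
) -> tuple[TractSet, DemographicTable, SyntheticTruth]:
    """Tessellate tracts and draw segregated group counts.

    Tract totals concentrate near the arterial (the population core).
    Group shares start from a common baseline; as ``segregation`` grows,
    group A tilts toward the road corridors (most strongly the freight
    corridor relative to where people live), group B toward the freight
    corridor, group C mildly toward roads, and group D away from them.
    At ``segregation=0`` the tilt vanishes and every group has the same
    expected spatial distribution, so all expected disparities are zero.
    Counts are real-valued and sum exactly to ``total_population``.
    """
    if roads is None:
        roads = make_road_network(config)
    rng = config._rng(1)
    tracts = _tessellate(config)
    xmin, ymin, xmax, ymax = config.domain
    H = ymax - ymin
    g_art, g_fr = _corridor_proximity(tracts, roads, scale=H / 8.0)

    # tract totals: population core around the arterial, lognormal noise
    w = (0.15 + g_art) * rng.lognormal(0.0, 0.25, size=len(tracts))
    totals = config.total_population * w / w.sum()

    # group affinities, mean-normalized so segregation=0 is exchangeable
    def norm(a: np.ndarray) -> np.ndarray:
        return a / a.mean()

    affinity = {
        "A": norm(g_art + 1.2 * g_fr),
        "B": 0.7 * norm(g_fr) + 0.3,
        "C": 0.5 * norm(g_art) + 0.5,
        "D": norm((1.0 - g_art / (g_art.max() + 1e-300)) + 0.1),
    }
    groups = config.groups
    base = np.array([_BASE_SHARES.get(g, 0.1) for g in groups])
    base = base / base.sum()
    s = config.segregation
    shares = np.empty((len(tracts), len(groups)))
    for j, g in enumerate(groups):
        h = affinity.get(g, np.ones(len(tracts)))
        shares[:, j] = base[j] * ((1.0 - s) + s * h)
    shares /= shares.sum(axis=1, keepdims=True)

    # per-tract Dirichlet draw around the expected shares
    alpha = 300.0
    drawn = np.vstack([rng.dirichlet(alpha * p) for p in shares])
    counts = drawn * totals[:, None]

    df = pd.DataFrame(counts, columns=list(groups),
                      index=pd.Index(tracts.ids, name="tract_id"))
    df["total"] = totals
    demo = DemographicTable(df, groups)

    # expected exposure ordering from the noise-free shares and a road
    # proximity proxy weighted by total road activity
    art_act = sum(sum(r.weights.values()) for r in roads if r.kind == "arterial")
    fr_act = sum(sum(r.weights.values()) for r in roads if r.kind == "freight")
    proxy = art_act * g_art + fr_act * g_fr
    expected = shares * totals[:, None]
    pwm = (expected * proxy[:, None]).sum(axis=0) / expected.sum(axis=0)
    order = tuple(np.array(groups)[np.argsort(-pwm, kind="stable")])
    truth = SyntheticTruth(group_exposure_ordering=order, segregation_used=s)
    return tracts, demo, truth


def designate_communities(
    demographics: DemographicTable, score: pd.Series, top_fraction: float
) -> pd.Series:
    """Flag the tracts holding the top ``top_fraction`` population share
    of the score distribution.

    Tracts are ranked by descending score (ties broken by ascending tract
    id, documented and stable); the minimal prefix whose cumulative
    population share reaches ``top_fraction`` is flagged, so the flagged
    share matches the target to within one tract.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ConfigError("top_fraction must be in (0, 1)")
    df = demographics.df
    missing = score.index.difference(df.index)
    if len(score) != len(df) or len(missing):
        raise DataError("score must be indexed by the tract ids")
    order = pd.DataFrame({"score": score, "pop": df["total"]})
    order = order.sort_index().sort_values("score", ascending=False, kind="stable")
    cum = order["pop"].cumsum() / order["pop"].sum()
    target = top_fraction
    flagged_ids = []
    for tid, c in cum.items():
        flagged_ids.append(tid)
        if c >= target - 1e-12:
            break
    flags = pd.Series(False, index=df.index, name="flag")
    flags.loc[flagged_ids] = True
    return flags


@dataclass
class Scenario:
    """A fully generated synthetic scenario bundle."""

    config: ScenarioConfig
    roads: list[Road]
    grid: VariableGrid
    emissions: EmissionInventory
    tracts: TractSet
    demographics: DemographicTable
    truth: SyntheticTruth


def generate_scenario(
    config: ScenarioConfig,
    finest: float = 1000.0,
    coarsest: float = 8000.0,
    max_pop: float = 20000.0,
    max_density: float = 2500.0,
) -> Scenario:
    """Generate roads, population, adaptive grid, and emissions in one go.

    The grid is refined against the synthetic tract population (tracts
    play the role of block groups for the density trigger).
    """
    from .grid import build_grid

    roads = make_road_network(config)
    tracts, demo, truth = make_population(config, roads)
    surface = PopulationSurface(
        polygons=list(tracts.polygons),
        population=demo.df.loc[tracts.ids, "total"].to_numpy(),
    )
    grid = build_grid(
        surface, config.domain, finest=finest, coarsest=coarsest,
        max_pop=max_pop, max_density=max_density,
    )
    emissions = make_emissions(config, grid, roads)
    totals = (
        emissions.df.groupby(["year", "species", "fleet", "process"])["mass_per_year"]
        .sum()
        .reset_index()
    )
    truth.emission_totals = totals
    return Scenario(config, roads, grid, emissions, tracts, demo, truth)
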