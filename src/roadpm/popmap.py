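"""Tract demographics and areal apportionment onto the analysis grid.

Census-style demographic counts are carried per tract; exposure metrics
need them per grid cell.  The bridge is areal interpolation: each
tract × cell overlap polygon becomes a *fragment* carrying the tract's
population in proportion to overlap area (uniform-density assumption —
the single largest approximation in this pipeline).  Concentrations are
constant within a cell, so a fragment simply inherits its cell's value.

Fragments, not cells, are the unit of all downstream metrics: a
population-weighted mean computed on fragments equals the one computed on
per-cell aggregates algebraically, but fragments additionally support
tract-level stratifiers (community-designation flags, score deciles).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.strtree import STRtree
from shapely.validation import explain_validity

from .errors import DataError, GridMismatchError
from .grid import VariableGrid

__all__ = [
    "DemographicTable",
    "TractSet",
    "PopulationField",
    "intersect_tracts_with_grid",
    "exposure_join",
    "stratify",
]

#: default fragment-area epsilon, as a fraction of tract area; smaller
#: overlaps are slivers from floating-point intersection and are merged
#: into the tract's dominant fragment.
SLIVER_EPS = 1e-6


@dataclass(frozen=True)
class TractSet:
    """Tract polygons keyed by stable integer tract ids."""

    ids: np.ndarray
    polygons: Sequence

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.polygons):
            raise DataError("ids and polygons must have equal length")
        if len(set(self.ids.tolist())) != len(self.ids):
            raise DataError("tract ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)


class DemographicTable:
    """Per-tract population counts by group plus designation flags.

    Wraps a DataFrame indexed by tract id with one column per demographic
    group, a ``total`` column, and optional boolean flag columns
    (e.g. ``ab617``, ``sb535``).  Group columns must partition the total.
    """

    def __init__(self, df: pd.DataFrame, groups: Sequence[str]):
        missing = [g for g in groups if g not in df.columns]
        if missing:
            raise DataError(f"missing group columns: {missing}")
        if "total" not in df.columns:
            df = df.copy()
            df["total"] = df[list(groups)].sum(axis=1)
        gsum = df[list(groups)].sum(axis=1)
        if np.any(df[list(groups)].to_numpy() < 0):
            raise DataError("group counts must be non-negative")
        if not np.allclose(gsum, df["total"], rtol=1e-9, atol=1e-9):
            raise DataError("group columns must sum to the total per tract")
        self.df = df
        self.groups = list(groups)

    @property
    def flags(self) -> list[str]:
        return [c for c in self.df.columns if self.df[c].dtype == bool]

    def total_population(self) -> float:
        return float(self.df["total"].sum())


def tracts_to_geojson(
    tracts: TractSet, demographics: DemographicTable, path
) -> None:
    """Write tracts + demographics as a GeoJSON FeatureCollection."""
    features = []
    for tid, poly in zip(tracts.ids, tracts.polygons):
        props = {"tract_id": int(tid)}
        row = demographics.df.loc[tid]
        for col in demographics.df.columns:
            v = row[col]
            props[col] = bool(v) if isinstance(v, (bool, np.bool_)) else float(v)
        features.append(
            {"type": "Feature", "geometry": mapping(poly), "properties": props}
        )
    doc = {
        "type": "FeatureCollection",
        "crs_note": "planar projected coordinates, meters",
        "groups": demographics.groups,
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def tracts_from_geojson(path) -> tuple[TractSet, DemographicTable]:
    with open(path) as fh:
        doc = json.load(fh)
    groups = doc.get("groups")
    ids, polys, rows = [], [], []
    for feat in doc["features"]:
        props = dict(feat["properties"])
        ids.append(int(props.pop("tract_id")))
        polys.append(shape(feat["geometry"]))
        rows.append(props)
    df = pd.DataFrame(rows, index=pd.Index(ids, name="tract_id"))
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].astype(bool)
    if groups is None:
        groups = [c for c in df.columns if c not in ("total",) and df[c].dtype != bool]
    tracts = TractSet(ids=np.array(ids), polygons=polys)
    return tracts, DemographicTable(df, groups)


class PopulationField:
    """Tract × cell fragments with apportioned group populations.

    ``df`` columns: ``tract_id``, ``cell_id``, ``area_share`` (share of the
    tract's area), ``rep_x``/``rep_y`` (a representative interior point of
    the overlap polygon, used for regional aggregation), one column per
    group, and ``total``.
    """

    def __init__(self, df: pd.DataFrame, groups: Sequence[str], grid_fingerprint: str):
        self.df = df.reset_index(drop=True)
        self.groups = list(groups)
        self.grid_fingerprint = grid_fingerprint

    def per_cell(self, n: int) -> pd.DataFrame:
        """Aggregate fragment populations to per-cell totals (n rows)."""
        agg = self.df.groupby("cell_id")[self.groups + ["total"]].sum()
        out = pd.DataFrame(
            0.0, index=pd.RangeIndex(n, name="cell_id"), columns=self.groups + ["total"]
        )
        out.loc[agg.index] = agg
        return out

    def cell_population(self, n: int) -> np.ndarray:
        return self.per_cell(n)["total"].to_numpy()

    def group_total(self, group: str) -> float:
        return float(self.df[group].sum())

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def intersect_tracts_with_grid(
    tracts: TractSet,
    demographics: DemographicTable,
    grid: VariableGrid,
    sliver_eps: float = SLIVER_EPS,
) -> PopulationField:
    """Areal apportionment of tract populations onto grid cells.

    Each tract is intersected with every overlapping grid cell; its
    population (total and per group) is split across the resulting
    fragments in proportion to overlap area.  Fragments smaller than
    ``sliver_eps`` times the tract area are merged into the tract's
    largest fragment.  Tracts that are invalid, degenerate, or extend
    outside the grid domain are rejected with the offending id.
    """
    cell_polys = grid.cell_polygons()
    tree = STRtree(cell_polys)
    rows = []
    for tid, poly in zip(tracts.ids, tracts.polygons):
        if not poly.is_valid:
            raise DataError(
                f"tract {tid} has invalid geometry: {explain_validity(poly)}"
            )
        tarea = poly.area
        if tarea <= 0:
            raise DataError(f"tract {tid} has zero area")
        pieces = []
        for ci in tree.query(poly):
            inter = poly.intersection(cell_polys[ci])
            if inter.is_empty or inter.area <= 0:
                continue
            rp = inter.representative_point()
            pieces.append((int(ci), inter.area, rp.x, rp.y))
        covered = sum(a for _, a, _, _ in pieces)
        if not np.isclose(covered, tarea, rtol=1e-6):
            raise DataError(
                f"tract {tid} extends outside the grid domain "
                f"(covered {covered:.6g} of {tarea:.6g} m²)"
            )
        # sliver merge into the dominant fragment of the same tract
        pieces.sort(key=lambda p: -p[1])
        kept = [list(pieces[0])]
        for p in pieces[1:]:
            if p[1] < sliver_eps * tarea:
                kept[0][1] += p[1]
            else:
                kept.append(list(p))
        total_area = sum(p[1] for p in kept)
        trow = demographics.df.loc[tid]
        for ci, a, rx, ry in kept:
            share = a / total_area
            row = {
                "tract_id": int(tid),
                "cell_id": ci,
                "area_share": share,
                "rep_x": rx,
                "rep_y": ry,
            }
            for g in demographics.groups:
                row[g] = share * float(trow[g])
            row["total"] = share * float(trow["total"])
            rows.append(row)
    df = pd.DataFrame(rows)
    return PopulationField(df, demographics.groups, grid.fingerprint())


def exposure_join(field, pop: PopulationField) -> pd.DataFrame:
    """Pair each fragment with its cell's concentration.

    ``field`` is a :class:`roadpm.srm.ConcentrationField`.  Concentrations
    are constant within a cell, so the fragment inherits the value
    unchanged.  Returns the fragment table with a ``concentration``
    column appended; populations and concentrations are never altered.
    """
    if field.grid_fingerprint != pop.grid_fingerprint:
        raise GridMismatchError(
            "concentration field and population field were built on different grids"
        )
    out = pop.df.copy()
    out["concentration"] = field.values[out["cell_id"].to_numpy()]
    return out


def stratify(
    pop: PopulationField,
    demographics: DemographicTable,
    by: str,
    n_bins: int = 10,
) -> PopulationField:
    """Re-group fragment populations by a tract-level stratifier.

    ``by`` is either a boolean flag column of the demographic table (the
    strata are then ``<by>`` and ``not_<by>``) or a numeric score column
    (strata are population-weighted score bins, ``<by>_bin_1`` lowest to
    ``<by>_bin_<n_bins>`` highest).  The result is a population field
    whose "groups" are the strata, usable by every downstream metric.
    """
    if by not in demographics.df.columns:
        raise DataError(f"stratifier column {by!r} not present")
    col = demographics.df[by]
    df = pop.df.copy()
    if col.dtype == bool:
        names = [by, f"not_{by}"]
        flagged = df["tract_id"].map(col).to_numpy(dtype=bool)
        df[names[0]] = np.where(flagged, df["total"], 0.0)
        df[names[1]] = np.where(~flagged, df["total"], 0.0)
    else:
        # population-weighted score bins over tracts, stable tract-id ties
        t = demographics.df[[by, "total"]].sort_index().sort_values(by, kind="stable")
        cum = t["total"].cumsum()
        total = t["total"].sum()
        edges = total * np.arange(1, n_bins + 1) / n_bins
        bin_of = pd.Series(
            np.minimum(np.searchsorted(edges, cum, side="left"), n_bins - 1),
            index=t.index,
        )
        names = [f"{by}_bin_{i + 1}" for i in range(n_bins)]
        tract_bin = df["tract_id"].map(bin_of).to_numpy()
        for i, name in enumerate(names):
            df[name] = np.where(tract_bin == i, df["total"], 0.0)
    keep = ["tract_id", "cell_id", "area_share", "rep_x", "rep_y"] + names
    out = df[keep].copy()
    out["total"] = df["total"]
    return PopulationField(out, names, pop.grid_fingerprint)
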