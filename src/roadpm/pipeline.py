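"""Multi-year scenario orchestration.

``run`` drives the whole analysis: generate (or load) a scenario, build
the per-species source-receptor matrices, map tract demographics onto the
grid once (demographics are treated as temporally static, applied to all
years), then for every year compute the full-fleet concentration field,
per-group exposure summaries, source decompositions, decile composition,
upper-percentile disparities, and community-stratified summaries.
Community designations are derived from the *first* year's full-fleet
exposure (flagging the most-exposed population shares), mirroring how
overburdened-area designations are fixed policy geographies rather than
per-year quantities.

All randomness lives in the scenario generator; the analysis path is
seed-free, so identical configs produce byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape

from . import __version__
from .errors import ConfigError, DataError, RoadPMError
from .grid import grid_summary
from .metrics import (
    decile_composition,
    exposure_inequality,
    exposure_summary,
    fractional_contribution,
    percentile_disparity,
)
from .popmap import (
    PopulationField,
    exposure_join,
    intersect_tracts_with_grid,
    stratify,
)
from .scenario import Scenario, ScenarioConfig, designate_communities, generate_scenario
from .srm import additive_decomposition, apply_srm, default_srm_set, exposure_per_ton

__all__ = ["RunConfig", "Results", "run", "analyze_scenario", "aggregate_scales"]

log = logging.getLogger("roadpm")

#: default designation rules: flag the top population shares of first-year
#: exposure (community-program analog ~8 %, disadvantaged-community analog
#: ~30 % of the population)
DEFAULT_DESIGNATIONS: dict[str, float] = {"ab617_analog": 0.081, "sb535_analog": 0.30}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to execute a pipeline run."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    finest: float = 1000.0
    coarsest: float = 8000.0
    max_pop: float = 20000.0
    max_density: float = 2500.0
    partitions: tuple[str, ...] = ("fleet", "primary_secondary", "exhaust_nonexhaust")
    percentiles: tuple[float, ...] = (75.0, 90.0)
    designations: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DESIGNATIONS)
    )
    output: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RunConfig":
        sc = dict(doc.get("scenario", {}))
        for key in ("trend_rates", "base_rates"):
            if key in sc:
                sc[key] = {
                    tuple(k.split(".")): float(v) for k, v in sc[key].items()
                }
        for key in ("domain", "years", "fleets", "species", "processes", "groups"):
            if key in sc:
                sc[key] = tuple(sc[key])
        try:
            scenario = ScenarioConfig(**sc)
        except TypeError as exc:
            raise ConfigError(f"bad scenario config: {exc}") from None
        g = doc.get("grid", {})
        a = doc.get("analysis", {})
        return cls(
            scenario=scenario,
            finest=float(g.get("finest", 1000.0)),
            coarsest=float(g.get("coarsest", 8000.0)),
            max_pop=float(g.get("max_pop", 20000.0)),
            max_density=float(g.get("max_density", 2500.0)),
            partitions=tuple(a.get("partitions", ("fleet", "primary_secondary",
                                                  "exhaust_nonexhaust"))),
            percentiles=tuple(float(q) for q in a.get("percentiles", (75.0, 90.0))),
            designations=dict(a.get("designations", DEFAULT_DESIGNATIONS)),
            output=doc.get("output"),
            log_level=str(doc.get("log_level", "INFO")),
        )

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, Mapping):
                return {str(k): enc(v) for k, v in sorted(o.items(), key=lambda t: str(t[0]))}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o

        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class Results:
    """Tidy result tables, one row per (year, group/source/bin/...)."""

    exposure: pd.DataFrame
    contributions: pd.DataFrame
    source_disparity: pd.DataFrame
    deciles: pd.DataFrame
    percentiles: pd.DataFrame
    stratified: pd.DataFrame
    inequality: pd.DataFrame
    grid_stats: dict
    manifest: dict
    scenario: Scenario
    population: PopulationField

    TABLES = (
        "exposure",
        "contributions",
        "source_disparity",
        "deciles",
        "percentiles",
        "stratified",
        "inequality",
    )

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        try:
            for name in self.TABLES:
                p = out / f"{name}.csv"
                getattr(self, name).to_csv(p, index=False)
                written.append(p)
            p = out / "manifest.json"
            with open(p, "w") as fh:
                json.dump({**self.manifest, "grid_stats": self.grid_stats}, fh,
                          indent=2)
            written.append(p)
        except Exception:
            for p in written:
                p.unlink(missing_ok=True)
            raise


def _tract_scores(pairs: pd.DataFrame) -> pd.Series:
    """Population-weighted mean concentration per tract (designation score)."""
    w = pairs["total"] * pairs["concentration"]
    num = w.groupby(pairs["tract_id"]).sum()
    den = pairs["total"].groupby(pairs["tract_id"]).sum()
    return num / den.replace(0.0, np.nan)


def analyze_scenario(scn: Scenario, cfg: RunConfig) -> Results:
    """Run the full analysis on an already generated scenario."""
    t0 = time.perf_counter()
    config = scn.config
    grid, emissions = scn.grid, scn.emissions
    srm_set = default_srm_set(grid, config.species)
    pop = intersect_tracts_with_grid(scn.tracts, scn.demographics, grid)
    groups = list(config.groups)
    n = grid.n

    # designation from first-year full-fleet exposure
    base_field = apply_srm(srm_set, emissions, config.years[0])
    base_pairs = exposure_join(base_field, pop)
    scores = _tract_scores(base_pairs)
    for flag_name, top_frac in cfg.designations.items():
        flags = designate_communities(scn.demographics, scores, top_frac)
        scn.demographics.df[flag_name] = flags.astype(bool)

    exposure_rows, contrib_rows, srcdisp_rows = [], [], []
    decile_rows, pct_rows, strat_rows, ineq_rows = [], [], [], []
    for year in config.years:
        field = apply_srm(srm_set, emissions, year)
        pairs = exposure_join(field, pop)
        summ = exposure_summary(pairs, groups)
        pwm_t = summ.attrs["pwm_total"]
        for g in groups:
            exposure_rows.append(
                {"year": year, "group": g, **summ.loc[g].to_dict(),
                 "pwm_total": pwm_t}
            )
        most = summ["pwm"].idxmax()
        least = summ["pwm"].idxmin()
        ineq_rows.append(
            {"year": year, "most": most, "least": least,
             "inequality": exposure_inequality(summ, most, least)}
        )

        for part_name in cfg.partitions:
            fields = additive_decomposition(srm_set, emissions, year, part_name)
            per_source = {}
            for src, f in fields.items():
                ps = exposure_summary(exposure_join(f, pop), groups)
                per_source[src] = ps
                for g in groups:
                    srcdisp_rows.append(
                        {"year": year, "partition": part_name, "source": src,
                         "group": g, "pwm": ps.loc[g, "pwm"],
                         "pwm_total": ps.attrs["pwm_total"],
                         "d_abs": ps.loc[g, "d_abs"],
                         "d_rel": ps.loc[g, "d_rel"]}
                    )
            ft = fractional_contribution(per_source, summ)
            ft.insert(0, "partition", part_name)
            ft.insert(0, "year", year)
            contrib_rows.append(ft)

        dec = decile_composition(pairs, groups)
        dec.insert(0, "year", year)
        decile_rows.append(dec)

        for g in groups:
            for q in cfg.percentiles:
                quant, rel = percentile_disparity(pairs, g, q, groups)
                pct_rows.append({"year": year, "group": g, "q": q,
                                 "quantile": quant, "rel_to_pwm_total": rel})

        for flag_name in cfg.designations:
            spop = stratify(pop, scn.demographics, flag_name)
            spairs = exposure_join(field, spop)
            ssumm = exposure_summary(spairs, spop.groups)
            for stratum in spop.groups:
                strat_rows.append(
                    {"year": year, "stratifier": flag_name, "stratum": stratum,
                     **ssumm.loc[stratum].to_dict(),
                     "pwm_total": ssumm.attrs["pwm_total"]}
                )

    gstats = grid_summary(grid, pop.cell_population(n), cfg.max_density)
    manifest = {
        "package": "roadpm",
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": config.seed,
        "grid_fingerprint": grid.fingerprint(),
        "n_cells": n,
        "n_tracts": len(scn.tracts),
        "years": list(config.years),
    }
    log.info("analysis finished in %.2f s", time.perf_counter() - t0)
    return Results(
        exposure=pd.DataFrame(exposure_rows),
        contributions=pd.concat(contrib_rows, ignore_index=True),
        source_disparity=pd.DataFrame(srcdisp_rows),
        deciles=pd.concat(decile_rows, ignore_index=True),
        percentiles=pd.DataFrame(pct_rows),
        stratified=pd.DataFrame(strat_rows),
        inequality=pd.DataFrame(ineq_rows),
        grid_stats=gstats,
        manifest=manifest,
        scenario=scn,
        population=pop,
    )


def single_year_summary(
    config: ScenarioConfig,
    year: int | None = None,
    finest: float = 1000.0,
    coarsest: float = 8000.0,
) -> pd.DataFrame:
    """Exposure summary for one year of a scenario, full fleet.

    A lean path through the pipeline (no decompositions, deciles or
    stratifications) for parameter-recovery studies that sweep many
    seeds.  Returns the per-group summary of :func:`exposure_summary`.
    """
    scn = generate_scenario(config, finest=finest, coarsest=coarsest)
    srm_set = default_srm_set(scn.grid, config.species)
    pop = intersect_tracts_with_grid(scn.tracts, scn.demographics, scn.grid)
    field = apply_srm(srm_set, scn.emissions,
                      config.years[0] if year is None else year)
    pairs = exposure_join(field, pop)
    return exposure_summary(pairs, list(config.groups))


def run(cfg: RunConfig, outdir=None) -> Results:
    """Generate the scenario and execute the full analysis.

    Stage failures abort with the stage name; partially written outputs
    are removed.
    """
    logging.basicConfig(level=cfg.log_level)
    stage = "scenario generation"
    try:
        scn = generate_scenario(
            cfg.scenario, finest=cfg.finest, coarsest=cfg.coarsest,
            max_pop=cfg.max_pop, max_density=cfg.max_density,
        )
        stage = "analysis"
        results = analyze_scenario(scn, cfg)
        out = outdir or cfg.output
        if out is not None:
            stage = "output"
            results.write(out)
        return results
    except RoadPMError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


def aggregate_scales(
    pop: PopulationField,
    fleet_fields: Mapping[str, "object"],
    regions: Mapping[str, "object"],
) -> pd.DataFrame:
    """Per-region PWM and fleet shares of exposure.

    ``fleet_fields`` maps fleet name to its :class:`ConcentrationField`
    (a fleet partition of the full field); ``regions`` maps region name
    to a shapely polygon.  A fragment belongs to the first region whose
    polygon covers its representative point.  Rows for regions with zero
    population are flagged ``empty`` rather than dropped.  Fleet shares
    sum to 1 per populated region.
    """
    region_items = list(regions.items())
    pts_x = pop.df["rep_x"].to_numpy()
    pts_y = pop.df["rep_y"].to_numpy()
    from shapely.geometry import Point

    assign = np.full(len(pop.df), -1)
    for ri, (_, poly) in enumerate(region_items):
        free = assign < 0
        for i in np.flatnonzero(free):
            if poly.covers(Point(pts_x[i], pts_y[i])):
                assign[i] = ri

    fleet_names = list(fleet_fields.keys())
    pairs = {fl: exposure_join(f, pop) for fl, f in fleet_fields.items()}
    rows = []
    for ri, (name, _) in enumerate(region_items):
        mask = assign == ri
        p = pop.df.loc[mask, "total"].to_numpy()
        tot = p.sum()
        row = {"region": name, "population": float(tot), "empty": bool(tot <= 0)}
        if tot > 0:
            pwms = {
                fl: float(np.sum(p * pairs[fl].loc[mask, "concentration"]) / tot)
                for fl in fleet_names
            }
            full = sum(pwms.values())
            row["pwm_total"] = full
            for fl in fleet_names:
                row[f"share_{fl}"] = pwms[fl] / full if full > 0 else np.nan
        else:
            row["pwm_total"] = np.nan
            for fl in fleet_names:
                row[f"share_{fl}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
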