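"""Exposure and disparity statistics.

All metrics operate on *pairs*: a fragment table carrying a
``concentration`` column (µg/m³, constant within a grid cell) and one
population column per demographic group (see
:func:`roadpm.popmap.exposure_join`).

Definitions, with ``P_{i,k}`` the population of group *k* in fragment *i*
and ``C_i`` the concentration there:

* population-weighted mean   ``PWM_k = Σ_i P_{i,k} C_i / Σ_i P_{i,k}``
* absolute disparity          ``D_A,k = PWM_k − PWM_T``   (µg/m³)
* relative disparity          ``D_R,k = D_A,k / PWM_T``   (dimensionless)
* fractional contribution of source *j*:  ``f_{j,k} = D_A,j,k / D_A,t,k``
* exposure inequality between most/least exposed groups:
  ``PWM_most / PWM_least − 1``.

``PWM_T`` is the whole-population PWM over the groups supplied (which
must partition the population for the zero-sum identities to hold).
Relative quantities are computed from unrounded internals; percent
formatting belongs to the reporting layer.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, MetricError

__all__ = [
    "pwm",
    "pwm_total",
    "exposure_summary",
    "absolute_disparity",
    "relative_disparity",
    "fractional_contribution",
    "source_relative_disparity",
    "exposure_inequality",
    "decile_composition",
    "weighted_quantile",
    "percentile_disparity",
    "percent_change",
]

#: |D_A,t,k| below this (µg/m³) makes fractional contributions unstable
CONTRIBUTION_TOL = 1e-12


def pwm(pairs: pd.DataFrame, group: str) -> float:
    """Population-weighted mean exposure of one group."""
    p = pairs[group].to_numpy(float)
    total = p.sum()
    if total <= 0:
        raise MetricError(f"PWM undefined: group {group!r} has zero population")
    return float(np.sum(p * pairs["concentration"].to_numpy(float)) / total)


def pwm_total(pairs: pd.DataFrame, groups: Sequence[str]) -> float:
    """Whole-population PWM over a set of groups that partition it."""
    p = pairs[list(groups)].sum(axis=1).to_numpy(float)
    total = p.sum()
    if total <= 0:
        raise MetricError("PWM undefined: zero total population")
    return float(np.sum(p * pairs["concentration"].to_numpy(float)) / total)


def absolute_disparity(pwm_k: float, pwm_t: float) -> float:
    """D_A,k = PWM_k − PWM_T (positive = overexposed)."""
    return pwm_k - pwm_t


def relative_disparity(pwm_k: float, pwm_t: float) -> float:
    """D_R,k = (PWM_k − PWM_T) / PWM_T (dimensionless)."""
    if pwm_t <= 0:
        raise MetricError("relative disparity undefined for PWM_T <= 0")
    return (pwm_k - pwm_t) / pwm_t


def exposure_summary(pairs: pd.DataFrame, groups: Sequence[str]) -> pd.DataFrame:
    """Per-group PWM, absolute and relative disparity, and population.

    Returns a DataFrame indexed by group with columns ``population``,
    ``pwm``, ``d_abs``, ``d_rel``; the whole-population PWM is stored in
    ``.attrs["pwm_total"]``.  The stored columns satisfy the identities
    ``d_abs = pwm − pwm_total`` and ``d_rel = d_abs / pwm_total`` exactly.
    """
    pwm_t = pwm_total(pairs, groups)
    rows = {}
    for g in groups:
        pk = pwm(pairs, g)
        da = absolute_disparity(pk, pwm_t)
        rows[g] = {
            "population": float(pairs[g].sum()),
            "pwm": pk,
            "d_abs": da,
            "d_rel": da / pwm_t,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    out.attrs["pwm_total"] = pwm_t
    return out


def fractional_contribution(
    per_source_summaries: Mapping[str, pd.DataFrame],
    total_summary: pd.DataFrame,
) -> pd.DataFrame:
    """f_{j,k} = D_A,j,k / D_A,t,k for every source j and group k.

    Individual fractions may fall outside [0, 1] (a source can counteract
    a group's disparity) but sum to 1 over a true source partition.
    Groups whose total absolute disparity is within ``CONTRIBUTION_TOL``
    of zero are flagged ``unstable`` instead of emitting huge ratios.
    """
    rows = []
    for j, summ in per_source_summaries.items():
        for k in summ.index:
            da_jk = summ.loc[k, "d_abs"]
            da_tk = total_summary.loc[k, "d_abs"]
            unstable = abs(da_tk) < CONTRIBUTION_TOL
            rows.append(
                {
                    "source": j,
                    "group": k,
                    "d_abs_source": da_jk,
                    "fraction": np.nan if unstable else da_jk / da_tk,
                    "unstable": unstable,
                }
            )
    return pd.DataFrame(rows)


def source_relative_disparity(source_summary: pd.DataFrame, group: str) -> float:
    """Relative disparity within one source's own exposure field:
    (PWM_{j,k} − PWM_{j,T}) / PWM_{j,T}.

    Distinguishes "most disparate impact" from "largest aggregate impact"
    (the latter is :func:`fractional_contribution`).
    """
    pwm_t = source_summary.attrs["pwm_total"]
    if pwm_t <= 0:
        raise MetricError("source relative disparity undefined: PWM_T <= 0")
    return float(source_summary.loc[group, "d_rel"])


def exposure_inequality(summary: pd.DataFrame, most: str, least: str) -> float:
    """Percent-difference form of inequality between two groups:
    PWM_most / PWM_least − 1, equivalently (1 + D_R,most)/(1 + D_R,least) − 1.
    """
    pwm_least = summary.loc[least, "pwm"]
    if pwm_least <= 0:
        raise MetricError("exposure inequality undefined: least-exposed PWM <= 0")
    return float(summary.loc[most, "pwm"] / pwm_least - 1.0)


def decile_composition(
    pairs: pd.DataFrame, groups: Sequence[str], n_bins: int = 10
) -> pd.DataFrame:
    """Demographic composition of equal-population exposure bins.

    Fragments are sorted by exposure ascending; the cumulative population
    is cut into ``n_bins`` equal-population bins, splitting proportionally
    at cuts.  Fragments with exactly tied exposures are pooled and split
    proportionally, so a fully uniform field yields the overall
    composition in every bin.  Returns one row per bin with per-group
    population shares (summing to 1), bin population, and the exposure
    range covered.
    """
    groups = list(groups)
    conc = pairs["concentration"].to_numpy(float)
    popm = pairs[groups].to_numpy(float)
    total = popm.sum()
    if total <= 0:
        raise MetricError("decile composition undefined for zero population")
    # pool tied exposures into blocks
    order = np.argsort(conc, kind="stable")
    conc_s = conc[order]
    pop_s = popm[order]
    uniq, starts = np.unique(conc_s, return_index=True)
    blocks = np.add.reduceat(pop_s, starts, axis=0)  # (n_blocks, n_groups)
    block_tot = blocks.sum(axis=1)

    target = total / n_bins
    rows = []
    bi = 0  # current block
    used = 0.0  # fraction of current block already consumed
    for b in range(n_bins):
        need = target
        acc = np.zeros(len(groups))
        lo, hi = None, None
        while need > 1e-9 * total and bi < len(uniq):
            avail = block_tot[bi] * (1.0 - used)
            if lo is None:
                lo = uniq[bi]
            hi = uniq[bi]
            if avail <= need + 1e-9 * total:
                acc += blocks[bi] * (1.0 - used)
                need -= avail
                bi += 1
                used = 0.0
            else:
                frac = need / block_tot[bi]
                acc += blocks[bi] * frac
                used += frac
                need = 0.0
        binpop = acc.sum()
        row = {"bin": b + 1, "population": binpop,
               "exposure_min": lo, "exposure_max": hi}
        for gi, g in enumerate(groups):
            row[f"share_{g}"] = acc[gi] / binpop if binpop > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Population-weighted quantile, left-continuous step convention.

    Returns the smallest value whose cumulative weight share is at least
    ``q/100``; no interpolation.  ``q`` must lie in (0, 100).
    """
    if not 0.0 < q < 100.0:
        raise ConfigError("q must be in (0, 100)")
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    if w.sum() <= 0:
        raise MetricError("weighted quantile undefined for zero total weight")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order]) / w.sum()
    idx = np.searchsorted(cum, q / 100.0, side="left")
    idx = min(idx, len(v) - 1)
    return float(v[order][idx])


def percentile_disparity(
    pairs: pd.DataFrame, group: str, q: float, groups: Sequence[str]
) -> tuple[float, float]:
    """Exposure at a group's q-th population-weighted percentile and its
    ratio−1 to the whole-population PWM.
    """
    w = pairs[group].to_numpy(float)
    if w.sum() <= 0:
        raise MetricError(f"percentile undefined: group {group!r} has zero population")
    quant = weighted_quantile(pairs["concentration"].to_numpy(float), w, q)
    pwm_t = pwm_total(pairs, groups)
    return quant, quant / pwm_t - 1.0


def percent_change(value_start: float, value_end: float) -> float:
    """100 × (end − start) / start; sign retained (decrease = negative)."""
    if value_start == 0:
        raise MetricError("percent change undefined for zero baseline")
    return 100.0 * (value_end - value_start) / value_start
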