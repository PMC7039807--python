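"""Census-division burden runs and the national rollup.

The regional analysis repeats the Monte Carlo burden estimate once per
US census division (nine divisions), with division-specific inputs:

- residential indoor-origin PM2.5 mean (SD), modelled lognormal by
  moment matching;
- residential infiltration factor mean (SD), modelled beta on [0, 1];
- outdoor PM2.5 mean and 10th/90th percentiles, modelled lognormal by
  the mean-and-percentiles fit;
- division baseline over-35 mortality rate and population.

Residential ambient-generated concentrations are formed per iteration as
sampled infiltration factor x sampled outdoor concentration.  Time
activity and non-residential concentration specs are shared nationally.
The national estimate is the *sum of division medians* (and likewise for
the quartile columns) — a deliberate simplification: the sum of medians
is not the median of the national sum, but it is the construction used
for tabulated division totals.

Per-category death quantiles are computed from per-iteration category
deaths (fraction_i x total_i), then summarised; see the methods note for
the alternative (fraction quantiles x median) and why this one is used.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .distributions import (
    fit_beta_to_mean_sd,
    fit_lognormal_to_mean_and_percentiles,
    fit_lognormal_to_mean_sd,
)
from .effect_estimates import SourceType
from .exposure import ExposureProfile, Microenvironment, MicroenvironmentSpecs
from .montecarlo import ScenarioConfig, SummaryStats, run_scenario
from .mortality import CATEGORIES, PopulationInputs

__all__ = [
    "DivisionInputs",
    "RegionalResults",
    "population_weighted_stats",
    "run_regional",
    "national_rollup",
    "CATEGORY_ROWS",
]

#: Row labels of the per-division summary table, in presentation order.
CATEGORY_ROWS = (
    "total",
    "ag_residence",
    "ag_other_indoor",
    "ag_vehicle",
    "ag_outdoor",
    "ag_total",
    "ig_residence",
    "ig_other_indoor",
    "ig_total",
)

_STATS = ("median", "q25", "q75")


@dataclass(frozen=True)
class DivisionInputs:
    """One census division's row of regional model inputs."""

    name: str
    ig_res_mean: float
    ig_res_sd: float
    f_inf_mean: float
    f_inf_sd: float
    outdoor_mean: float
    outdoor_p10: float
    outdoor_p90: float
    y0: float
    pop: int

    def __post_init__(self) -> None:
        for fname in (
            "ig_res_mean",
            "ig_res_sd",
            "f_inf_mean",
            "f_inf_sd",
            "outdoor_mean",
            "outdoor_p10",
            "outdoor_p90",
            "y0",
        ):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{self.name}: {fname} must be positive")
        if self.pop <= 0:
            raise ValueError(f"{self.name}: pop must be a positive integer")


@dataclass(frozen=True)
class RegionalResults:
    """Per-division summary tables plus the national rollup.

    ``tables`` maps division name to a DataFrame indexed by
    :data:`CATEGORY_ROWS` with columns median / q25 / q75 (deaths per
    year); ``summaries`` keeps each division's full
    :class:`~pmburden.montecarlo.SummaryStats`; ``national`` is the
    column-wise sum of the division tables.
    """

    tables: Mapping[str, pd.DataFrame]
    summaries: Mapping[str, SummaryStats]
    national: pd.DataFrame


def population_weighted_stats(values, weights) -> np.ndarray | float:
    """Population-weighted arithmetic mean of per-unit summary statistics.

    ``values`` may be a 1-D sequence (one statistic per unit) or a 2-D
    array / DataFrame (units x statistics); ``weights`` are the unit
    populations.  Used to aggregate state- or city-level summary
    statistics up to a census division.
    """
    vals = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size != vals.shape[0]:
        raise ValueError("weights must be 1-D and match the number of units")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with a positive sum")
    out = np.average(vals, weights=w, axis=0)
    return float(out) if np.ndim(out) == 0 else out


def division_config(
    division: DivisionInputs,
    shared: ScenarioConfig,
    index: int,
) -> ScenarioConfig:
    """Specialise a shared scenario template to one census division.

    The shared config supplies the effect estimate, sum_ft, time
    activity, and non-residential specs; the division supplies its
    residential and outdoor distributions, y0 and population.  The
    division's seed is the shared master seed plus its index.
    """
    outdoor_spec = fit_lognormal_to_mean_and_percentiles(
        division.outdoor_mean, division.outdoor_p10, division.outdoor_p90,
        units="ug/m3",
    )
    res_specs = MicroenvironmentSpecs(
        outdoor=outdoor_spec,
        infiltration=fit_beta_to_mean_sd(
            division.f_inf_mean, division.f_inf_sd, 0.0, 1.0
        ),
        ig_concentration=fit_lognormal_to_mean_sd(
            division.ig_res_mean, division.ig_res_sd, units="ug/m3"
        ),
    )
    micro = dict(shared.exposure.microenvironments)
    micro[Microenvironment.RESIDENCE] = res_specs
    micro[Microenvironment.OUTDOOR] = MicroenvironmentSpecs(
        ag_concentration=outdoor_spec
    )
    profile = ExposureProfile(
        time_activity=shared.exposure.time_activity,
        microenvironments=micro,
        baseline=shared.exposure.baseline,
    )
    return replace(
        shared,
        population=PopulationInputs(y0=division.y0, pop=division.pop),
        exposure=profile,
        residential_mixture=(),
        master_seed=shared.master_seed + index,
    )


def _category_table(records: pd.DataFrame) -> pd.DataFrame:
    """Quantiles of per-iteration category deaths for one division."""
    totals = records["total_deaths"].to_numpy(dtype=float)
    per_iter = {"total": totals}
    ag_cols, ig_cols = [], []
    for (src, m) in CATEGORIES:
        col = records[f"frac_{src.value}_{m.value}"].to_numpy(dtype=float)
        deaths = np.where(np.isnan(col), 0.0, col) * totals
        key = ("ag_" if src is SourceType.AMBIENT_GENERATED else "ig_") + m.value
        per_iter[key] = deaths
        (ag_cols if src is SourceType.AMBIENT_GENERATED else ig_cols).append(key)
    per_iter["ag_total"] = sum(per_iter[k] for k in ag_cols)
    per_iter["ig_total"] = sum(per_iter[k] for k in ig_cols)
    rows = {}
    for key in CATEGORY_ROWS:
        q25, med, q75 = np.percentile(per_iter[key], [25, 50, 75])
        rows[key] = {"median": med, "q25": q25, "q75": q75}
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(CATEGORY_ROWS)]


def run_regional(
    divisions: Sequence[DivisionInputs],
    shared: ScenarioConfig,
    n_iter: Optional[int] = None,
    master_seed: Optional[int] = None,
) -> RegionalResults:
    """Run the Monte Carlo analysis once per census division and roll up.

    ``shared`` provides everything except the division-specific inputs;
    ``n_iter`` / ``master_seed`` override the shared values when given.
    Division seeds are ``master_seed + division index`` in input order.
    """
    if not divisions:
        raise ValueError("no divisions supplied")
    names = [d.name for d in divisions]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate division names: {names}")
    if n_iter is not None or master_seed is not None:
        shared = replace(
            shared,
            n_iterations=n_iter if n_iter is not None else shared.n_iterations,
            master_seed=master_seed if master_seed is not None else shared.master_seed,
        )
    tables: dict[str, pd.DataFrame] = {}
    summaries: dict[str, SummaryStats] = {}
    for i, division in enumerate(divisions):
        config = division_config(division, shared, i)
        records, summary = run_scenario(config)
        tables[division.name] = _category_table(records)
        summaries[division.name] = summary
    national = national_rollup(tables)
    return RegionalResults(tables=tables, summaries=summaries, national=national)


def national_rollup(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Sum division summary tables into the national block.

    The national median (and each quartile column) is the plain sum of
    the division entries, category by category — exact conservation by
    construction.
    """
    if not tables:
        raise ValueError("no division tables to roll up")
    total = None
    for name, tbl in tables.items():
        missing = set(CATEGORY_ROWS) - set(tbl.index)
        if missing:
            raise ValueError(f"division {name} missing categories {sorted(missing)}")
        aligned = tbl.loc[list(CATEGORY_ROWS), list(_STATS)]
        total = aligned if total is None else total + aligned
    return total
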