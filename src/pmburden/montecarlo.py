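"""Monte Carlo scenario engine for the national burden estimate.

Each iteration draws one value of every uncertain model input — the
concentration-response slope (divided by the time-weighted infiltration
sum), time-activity fractions, and microenvironmental concentrations of
indoor and outdoor origin — evaluates the exposure-response function,
and records total deaths together with the per-category exposure shares.
The run summary reports the empirical median as the central estimate and
the interquartile range as its bounds, the convention used throughout
this framework.

Residential concentrations may be sampled from a *mixture* of
alternative spec-sets (e.g. two field studies sampled equally): each
iteration selects one component by its weight and uses that component's
residential draws.  All randomness descends from one master seed through
named substreams, so runs are bit-reproducible and a component's draws
do not depend on which other components exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .distributions import DistributionSpec, sample, substream_seed
from .effect_estimates import EffectEstimate
from .exposure import (
    ConcentrationSet,
    ExposureProfile,
    Microenvironment,
    MicroenvironmentSpecs,
    normalize_time_fractions,
)
from .mortality import CATEGORIES, PopulationInputs, burden, exposure_fractions

__all__ = [
    "MixtureComponent",
    "ScenarioConfig",
    "SummaryStats",
    "run_scenario",
    "summarize",
    "shapiro_wilk_log",
    "median_bootstrap_ci",
]

#: Default number of Monte Carlo iterations.
DEFAULT_ITERATIONS = 10_000

#: Cap on the subsample handed to the Shapiro-Wilk test.
SHAPIRO_MAX_N = 5_000


@dataclass(frozen=True)
class MixtureComponent:
    """One residential spec-set with its sampling weight."""

    label: str
    weight: float
    residence: MicroenvironmentSpecs

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"mixture weight must be >= 0, got {self.weight}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed for one national Monte Carlo run.

    ``effect`` is the *raw* (unmodified) effect estimate; it is divided
    by ``sum_ft`` internally.  ``sum_ft`` may be a fixed scalar (the
    default treatment, 0.60 for the US population) or a
    DistributionSpec to sample it per iteration.  When
    ``residential_mixture`` is given it overrides the residence entry of
    ``exposure``; weights are normalised to 1.  ``equal_toxicity=True``
    (default) reuses the modified ambient slope for indoor-generated
    exposure; an explicit ``ig_beta_override`` supplies a distinct one.
    """

    population: PopulationInputs
    effect: EffectEstimate
    exposure: ExposureProfile
    sum_ft: Union[float, DistributionSpec] = 0.60
    equal_toxicity: bool = True
    ig_beta_override: Optional[EffectEstimate] = None
    residential_mixture: Sequence[MixtureComponent] = ()
    n_iterations: int = DEFAULT_ITERATIONS
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if self.effect.modified:
            raise ValueError("pass the raw effect estimate; it is modified internally")
        if self.residential_mixture:
            w = np.array([c.weight for c in self.residential_mixture], dtype=float)
            if w.sum() <= 0:
                raise ValueError("mixture weights sum to zero")
            labels = [c.label for c in self.residential_mixture]
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate mixture labels: {labels}")
        if isinstance(self.sum_ft, (int, float)) and not 0 < self.sum_ft <= 1.5:
            raise ValueError(f"sum_ft must be in (0, 1.5], got {self.sum_ft}")
        if not self.equal_toxicity and self.ig_beta_override is None:
            raise ValueError("equal_toxicity=False requires ig_beta_override")


@dataclass(frozen=True)
class SummaryStats:
    """Summary of a Monte Carlo run.

    ``total`` holds median / q25 / q75 / mean / sd of total deaths;
    ``fractions`` is a DataFrame indexed by (source, microenvironment)
    with the mean, SD and quartiles of the per-iteration exposure
    fractions plus attributed deaths (mean fraction x median total, with
    quartile columns from the fraction quartiles x median total);
    ``shapiro_w`` is the Shapiro-Wilk statistic of the log-transformed
    totals (NaN when undefined); ``n_excluded`` counts all-zero-exposure
    iterations excluded from the fraction averages.
    """

    total: Mapping[str, float]
    fractions: pd.DataFrame
    shapiro_w: float
    n_excluded: int

    def __post_init__(self) -> None:
        t = self.total
        if not t["q25"] <= t["median"] <= t["q75"]:
            raise ValueError("quartiles must bracket the median")
        if t["sd"] < 0:
            raise ValueError("sd must be non-negative")


def _draw_time_fractions(
    profile: ExposureProfile, n: int, master_seed: int
) -> dict[Microenvironment, np.ndarray]:
    raw = {}
    for m, spec in profile.time_activity.items():
        if isinstance(spec, DistributionSpec):
            raw[m] = sample(spec, n, substream_seed(master_seed, "time", m.value))
        else:
            raw[m] = np.full(n, float(spec))
    return normalize_time_fractions(raw)


def _draw_microenv(
    specs: MicroenvironmentSpecs,
    n: int,
    master_seed: int,
    *stream_key: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (AG, IG) concentration arrays for one microenvironment."""
    if specs.ag_concentration is not None:
        ag = sample(
            specs.ag_concentration, n, substream_seed(master_seed, *stream_key, "ag")
        )
    else:
        c_out = sample(
            specs.outdoor, n, substream_seed(master_seed, *stream_key, "outdoor")
        )
        f_inf = sample(
            specs.infiltration, n, substream_seed(master_seed, *stream_key, "finf")
        )
        ag = f_inf * c_out
    if specs.ig_concentration is not None:
        ig = sample(
            specs.ig_concentration, n, substream_seed(master_seed, *stream_key, "ig")
        )
    else:
        ig = np.zeros(n)
    return ag, ig


def run_scenario(config: ScenarioConfig) -> tuple[pd.DataFrame, SummaryStats]:
    """Run one national Monte Carlo scenario.

    Returns the per-iteration record table and its summary.  The record
    table carries total deaths, the two exposure sums, the sampled
    slopes, the selected mixture component, and one fraction column per
    (source, microenvironment) category.
    """
    n = config.n_iterations
    seed = config.master_seed
    pop = config.population

    # concentration-response slope: sample raw, then divide by sum_ft
    if config.effect.sampling is not None:
        beta_raw = sample(config.effect.sampling, n, substream_seed(seed, "beta"))
    else:
        beta_raw = np.full(n, config.effect.beta)
    if isinstance(config.sum_ft, DistributionSpec):
        sum_ft = sample(config.sum_ft, n, substream_seed(seed, "sum_ft"))
    else:
        sum_ft = np.full(n, float(config.sum_ft))
    beta_ag = beta_raw / sum_ft
    if config.equal_toxicity:
        beta_ig = beta_ag
    else:
        ig = config.ig_beta_override
        if ig.sampling is not None:
            beta_ig = sample(ig.sampling, n, substream_seed(seed, "beta_ig"))
        else:
            beta_ig = np.full(n, ig.beta)

    t = _draw_time_fractions(config.exposure, n, seed)

    ag: dict[Microenvironment, np.ndarray] = {}
    ig_conc: dict[Microenvironment, np.ndarray] = {}
    for m, specs in config.exposure.microenvironments.items():
        if m is Microenvironment.RESIDENCE and config.residential_mixture:
            continue
        ag[m], ig_m = _draw_microenv(specs, n, seed, "conc", m.value)
        if m in (Microenvironment.RESIDENCE, Microenvironment.OTHER_INDOOR):
            ig_conc[m] = ig_m

    labels = np.full(n, "", dtype=object)
    if config.residential_mixture:
        comps = config.residential_mixture
        w = np.array([c.weight for c in comps], dtype=float)
        w = w / w.sum()
        pick_rng = np.random.default_rng(substream_seed(seed, "mixture"))
        choice = pick_rng.choice(len(comps), size=n, p=w)
        ag_res = np.zeros(n)
        ig_res = np.zeros(n)
        for i, comp in enumerate(comps):
            # each component keeps its own stream keyed by label, so its
            # draws are invariant to the other components' presence
            a, g = _draw_microenv(comp.residence, n, seed, "conc", "residence", comp.label)
            mask = choice == i
            ag_res[mask] = a[mask]
            ig_res[mask] = g[mask]
            labels[mask] = comp.label
        ag[Microenvironment.RESIDENCE] = ag_res
        ig_conc[Microenvironment.RESIDENCE] = ig_res

    conc = ConcentrationSet(ag=ag, ig=ig_conc, baseline=config.exposure.baseline)
    e_ig = sum(conc.ig[m] * t[m] for m in conc.ig)
    e_ag = sum(conc.ag[m] * t[m] for m in conc.ag)
    totals = burden(pop, beta_ig, beta_ag, e_ig, e_ag)
    fracs = exposure_fractions(beta_ig, beta_ag, conc, t)

    records = pd.DataFrame(
        {
            "iteration": np.arange(n),
            "total_deaths": totals,
            "e_ig": e_ig,
            "e_ag": e_ag,
            "beta_ag": beta_ag,
            "beta_ig": beta_ig,
            "mixture": labels,
        }
    )
    for (src, m) in CATEGORIES:
        records[f"frac_{src.value}_{m.value}"] = fracs[(src, m)]
    return records, summarize(records)


def summarize(records: pd.DataFrame) -> SummaryStats:
    """Summarise an iteration table into a :class:`SummaryStats`.

    Quartiles use linear interpolation between order statistics.
    Iterations whose exposure fractions are undefined (all-zero
    exposure) are excluded from the fraction averages but retained, with
    zero deaths, in the totals.
    """
    totals = records["total_deaths"].to_numpy(dtype=float)
    if totals.size < 1:
        raise ValueError("need at least one iteration record")
    q25, med, q75 = np.percentile(totals, [25, 50, 75])
    total = {
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "mean": float(totals.mean()),
        "sd": float(totals.std(ddof=1)) if totals.size > 1 else 0.0,
    }

    rows = []
    n_excluded = 0
    frac_cols = [c for c in records.columns if c.startswith("frac_")]
    if frac_cols:
        n_excluded = int(records[frac_cols[0]].isna().sum())
    for (src, m) in CATEGORIES:
        col = records.get(f"frac_{src.value}_{m.value}")
        if col is None:
            continue
        vals = col.to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            mean_f = sd_f = f25 = f75 = np.nan
        else:
            mean_f = float(vals.mean())
            sd_f = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            f25, f75 = (float(x) for x in np.percentile(vals, [25, 75]))
        rows.append(
            {
                "source": src.value,
                "microenvironment": m.value,
                "mean_fraction": mean_f,
                "sd_fraction": sd_f,
                "fraction_q25": f25,
                "fraction_q75": f75,
                "attributed_deaths": mean_f * total["median"],
                "deaths_q25": f25 * total["median"],
                "deaths_q75": f75 * total["median"],
            }
        )
    fractions = pd.DataFrame(rows).set_index(["source", "microenvironment"]) if rows else pd.DataFrame()

    if np.all(totals > 0) and totals.size >= 3 and np.ptp(totals) > 0:
        w = shapiro_wilk_log(totals)
    else:
        w = float("nan")
    return SummaryStats(total=total, fractions=fractions, shapiro_w=w, n_excluded=n_excluded)


def shapiro_wilk_log(totals: Sequence[float]) -> float:
    """Shapiro-Wilk W of log-transformed totals (lognormality check).

    For runs larger than 5,000 iterations a deterministic evenly-spaced
    subsample of the order statistics is tested, keeping the statistic
    inside the test's validated sample-size range.
    """
    arr = np.asarray(totals, dtype=float)
    if arr.size < 3:
        raise ValueError(f"need at least 3 values, got {arr.size}")
    if np.any(arr <= 0):
        raise ValueError("totals must be strictly positive for a log transform")
    logs = np.log(arr)
    if np.ptp(logs) == 0:
        raise ValueError("constant sequence: W is undefined")
    if logs.size > SHAPIRO_MAX_N:
        idx = np.linspace(0, logs.size - 1, SHAPIRO_MAX_N).round().astype(int)
        logs = np.sort(logs)[idx]
    return float(sps.shapiro(logs).statistic)


def median_bootstrap_ci(
    totals: Sequence[float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap percentile CI of the median (diagnostic only)."""
    arr = np.asarray(totals, dtype=float)
    rng = np.random.default_rng(substream_seed(seed, "bootstrap"))
    meds = np.median(
        rng.choice(arr, size=(n_boot, arr.size), replace=True), axis=1
    )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(meds, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)
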