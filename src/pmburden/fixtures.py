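"""Packaged model inputs: published constants plus flagged stand-ins.

Everything the national and regional analyses need that was printed in
the source tables ships with the package as machine-readable fixtures
(CSV/YAML under ``pmburden/data``) and is validated at load time:

- ``constants``: national population, baseline mortality rate,
  time-activity fractions, the pooled effect estimate and its Weibull
  fit, the national outdoor PM2.5 summary, and ``sum_ft``;
- ``nhaps``: the national mean time-activity fractions alone;
- ``table1``: the nine census-division input rows;
- ``table2``: the expected national attribution table (fractions and
  attributed deaths);
- ``table3``: the expected regional summary table.

Distributions published only in supplementary material (residential
spec-sets of the two field studies, non-residential concentrations) are
represented by *stand-in* specs whose parameters are this package's own
choices; they carry a ``stand_in`` provenance flag and only qualitative
orderings are sourced.  Headline Monte Carlo medians obtained with
stand-ins are therefore order-of-magnitude estimates, not exact
reproductions.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

from .distributions import (
    DistributionSpec,
    Family,
    fit_beta_to_mean_sd,
    fit_lognormal_to_mean_sd,
    fit_weibull_to_mean_sd,
    point,
)
from .effect_estimates import EffectEstimate, SourceType
from .exposure import ExposureProfile, Microenvironment, MicroenvironmentSpecs
from .montecarlo import MixtureComponent, ScenarioConfig
from .mortality import PopulationInputs
from .regional import DivisionInputs

__all__ = [
    "load_fixture",
    "make_standin_profile",
    "default_effect_estimate",
    "scenario1_config",
    "regional_shared_config",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("constants", "nhaps", "table1", "table2", "table3")

_STANDIN_STYLES = ("riopa_like", "mesa_like", "zeros")


class CorruptedFixtureError(ValueError):
    """A packaged fixture failed its load-time invariant checks."""


def _data_path(name: str):
    return resources.files("pmburden.data").joinpath(name)


def _load_constants() -> dict:
    with _data_path("constants.yaml").open("r", encoding="utf-8") as fh:
        c = yaml.safe_load(fh)
    t = c["time_activity"]
    tsum = t["residence"] + t["other_indoor"] + t["vehicle"] + t["outdoor"]
    if abs(tsum - 1.0) > 1e-9:
        raise CorruptedFixtureError(f"time-activity fractions sum to {tsum}, not 1")
    if c["infiltration_means"]["provenance"] != "stand_in":
        raise CorruptedFixtureError("infiltration_means must be flagged stand_in")
    return c


def _load_table1() -> list[DivisionInputs]:
    with _data_path("table1.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    divisions = [
        DivisionInputs(
            name=row.division,
            ig_res_mean=row.ig_res_mean,
            ig_res_sd=row.ig_res_sd,
            f_inf_mean=row.f_inf_mean,
            f_inf_sd=row.f_inf_sd,
            outdoor_mean=row.outdoor_mean,
            outdoor_p10=row.outdoor_p10,
            outdoor_p90=row.outdoor_p90,
            y0=row.y0_per_100k / 1e5,
            pop=int(row.pop),
        )
        for row in df.itertuples()
    ]
    if len(divisions) != 9:
        raise CorruptedFixtureError(f"expected 9 census divisions, got {len(divisions)}")
    national_pop = _load_constants()["national"]["population"]
    total = sum(d.pop for d in divisions)
    if total != national_pop:
        raise CorruptedFixtureError(
            f"division populations sum to {total}, expected {national_pop}"
        )
    return divisions


def _load_table2() -> pd.DataFrame:
    with _data_path("table2.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    leaf = df[df.microenvironment != "total"]
    if abs(leaf.mean_fraction_pct.sum() - 100.0) > 0.5:
        raise CorruptedFixtureError("attribution fractions do not sum to ~100%")
    return df.set_index(["source", "microenvironment"])


def _load_table3() -> pd.DataFrame:
    with _data_path("table3.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    divisions = [d for d in df.division.unique() if d != "Total"]
    if len(divisions) != 9:
        raise CorruptedFixtureError("expected 9 divisions plus a Total block")
    return df.set_index(["division", "statistic"])


def load_fixture(name: str):
    """Load and validate one packaged fixture by name.

    Names: ``constants`` (dict), ``nhaps`` (time-fraction dict),
    ``table1`` (list of :class:`~pmburden.regional.DivisionInputs`),
    ``table2`` / ``table3`` (DataFrames of expected published values).
    """
    if name == "constants":
        return _load_constants()
    if name == "nhaps":
        t = _load_constants()["time_activity"]
        return {
            Microenvironment.RESIDENCE: t["residence"],
            Microenvironment.OTHER_INDOOR: t["other_indoor"],
            Microenvironment.VEHICLE: t["vehicle"],
            Microenvironment.OUTDOOR: t["outdoor"],
        }
    if name == "table1":
        return _load_table1()
    if name == "table2":
        return _load_table2()
    if name == "table3":
        return _load_table3()
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")


def default_effect_estimate(refit: bool = False) -> EffectEstimate:
    """The pooled all-cause mortality effect estimate with its sampler.

    By default the sampling distribution uses the *published* Weibull
    parameters; ``refit=True`` refits the Weibull to the mean/SD by
    method of moments instead (the two agree to ~1%).
    """
    c = _load_constants()["effect_estimate"]
    if refit:
        mean, sd = c["beta"], 0.0016
        sampling = fit_weibull_to_mean_sd(mean, sd, units="per ug/m3")
    else:
        sampling = DistributionSpec(
            Family.WEIBULL,
            {"shape": c["weibull_shape"], "scale": c["weibull_scale"]},
            units="per ug/m3",
        )
    return EffectEstimate(
        beta=c["beta"],
        ci_low=c["beta_ci"][0],
        ci_high=c["beta_ci"][1],
        sampling=sampling,
        source_type=SourceType.AMBIENT_GENERATED,
    )


def _national_outdoor_spec() -> DistributionSpec:
    c = _load_constants()["outdoor_pm25"]
    return DistributionSpec(
        Family.LOGNORMAL, {"gm": c["gm"], "gsd": c["gsd"]}, units="ug/m3"
    )


def _standin_residence(style: str) -> MicroenvironmentSpecs:
    p = _load_constants()["standin_profiles"][style]
    return MicroenvironmentSpecs(
        outdoor=_national_outdoor_spec(),
        infiltration=fit_beta_to_mean_sd(p["f_inf_mean"], p["f_inf_sd"], 0.0, 1.0),
        ig_concentration=fit_lognormal_to_mean_sd(
            p["ig_mean"], p["ig_sd"], units="ug/m3"
        ),
    )


def make_standin_profile(style: str) -> ExposureProfile:
    """A complete exposure profile built from flagged stand-in specs.

    Styles: ``riopa_like`` and ``mesa_like`` differ in their residential
    spec-set (higher indoor-origin concentrations and lower infiltration
    in ``riopa_like``); ``zeros`` zeroes every non-residential and
    indoor-generated source, leaving only direct outdoor exposure plus a
    placeholder residence, for residential-only analyses.
    """
    if style not in _STANDIN_STYLES:
        raise KeyError(f"unknown stand-in style {style!r}; choose from {_STANDIN_STYLES}")
    c = _load_constants()
    outdoor_spec = _national_outdoor_spec()
    time_activity = load_fixture("nhaps")
    if style == "zeros":
        zero = point(0.0, units="ug/m3")
        micro = {
            Microenvironment.RESIDENCE: MicroenvironmentSpecs(ag_concentration=zero),
            Microenvironment.OTHER_INDOOR: MicroenvironmentSpecs(ag_concentration=zero),
            Microenvironment.VEHICLE: MicroenvironmentSpecs(ag_concentration=zero),
            Microenvironment.OUTDOOR: MicroenvironmentSpecs(
                ag_concentration=outdoor_spec
            ),
        }
        return ExposureProfile(time_activity=time_activity, microenvironments=micro)
    sp = c["standin_profiles"]
    other = MicroenvironmentSpecs(
        outdoor=outdoor_spec,
        infiltration=fit_beta_to_mean_sd(
            sp["other_indoor"]["f_inf_mean"], sp["other_indoor"]["f_inf_sd"], 0.0, 1.0
        ),
        ig_concentration=fit_lognormal_to_mean_sd(
            sp["other_indoor"]["ig_mean"], sp["other_indoor"]["ig_sd"], units="ug/m3"
        ),
    )
    vehicle = MicroenvironmentSpecs(
        outdoor=outdoor_spec,
        infiltration=fit_beta_to_mean_sd(
            sp["vehicle"]["f_inf_mean"], sp["vehicle"]["f_inf_sd"], 0.0, 1.0
        ),
    )
    micro = {
        Microenvironment.RESIDENCE: _standin_residence(style),
        Microenvironment.OTHER_INDOOR: other,
        Microenvironment.VEHICLE: vehicle,
        Microenvironment.OUTDOOR: MicroenvironmentSpecs(ag_concentration=outdoor_spec),
    }
    return ExposureProfile(time_activity=time_activity, microenvironments=micro)


def scenario1_config(
    mixture: Mapping[str, float] | None = None,
    n_iterations: int = 10_000,
    master_seed: int = 0,
) -> ScenarioConfig:
    """National Monte Carlo config with stand-in residential spec-sets.

    ``mixture`` maps stand-in style to weight (default: ``riopa_like``
    and ``mesa_like`` sampled equally).  Uses the packaged national
    population, mortality rate, effect estimate, ``sum_ft`` and NHAPS
    time fractions.
    """
    if mixture is None:
        mixture = {"riopa_like": 0.5, "mesa_like": 0.5}
    c = _load_constants()
    components = tuple(
        MixtureComponent(label=style, weight=w, residence=_standin_residence(style))
        for style, w in mixture.items()
    )
    return ScenarioConfig(
        population=PopulationInputs(
            y0=c["national"]["mortality_rate"], pop=c["national"]["population"]
        ),
        effect=default_effect_estimate(),
        exposure=make_standin_profile("riopa_like"),
        sum_ft=c["sum_ft"]["value"],
        residential_mixture=components,
        n_iterations=n_iterations,
        master_seed=master_seed,
    )


def regional_shared_config(
    nonresidential: str = "standin",
    n_iterations: int = 10_000,
    master_seed: int = 0,
) -> ScenarioConfig:
    """Shared scenario fragments for the regional analysis.

    ``nonresidential='standin'`` uses the national stand-in other-indoor
    and vehicle specs; ``'zeros'`` zeroes them for residential-only
    sensitivity runs.  The residence/outdoor entries and population are
    placeholders replaced per division.
    """
    if nonresidential not in ("standin", "zeros"):
        raise KeyError(f"nonresidential must be 'standin' or 'zeros', got {nonresidential!r}")
    profile = make_standin_profile(
        "riopa_like" if nonresidential == "standin" else "zeros"
    )
    c = _load_constants()
    return ScenarioConfig(
        population=PopulationInputs(
            y0=c["national"]["mortality_rate"], pop=c["national"]["population"]
        ),
        effect=default_effect_estimate(),
        exposure=profile,
        sum_ft=c["sum_ft"]["value"],
        n_iterations=n_iterations,
        master_seed=master_seed,
    )
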