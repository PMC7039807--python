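"""Scenario configuration parsing and results serialization.

Configs are YAML.  Validation is strict: unknown keys are errors and are
reported with their field path, so a typo never silently falls back to a
default.  A results directory always contains one ``manifest.json``
recording the config echo, master seed, iteration count, package version
and a SHA-256 checksum per output file; re-running with the same
manifest inputs reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .distributions import DistributionSpec
from .effect_estimates import EffectEstimate, rr_to_beta
from .exposure import ExposureProfile, Microenvironment, MicroenvironmentSpecs
from .fixtures import (
    load_fixture,
    make_standin_profile,
    default_effect_estimate,
    _standin_residence,
)
from .montecarlo import (
    DEFAULT_ITERATIONS,
    MixtureComponent,
    ScenarioConfig,
    SummaryStats,
)
from .mortality import PopulationInputs
from .regional import DivisionInputs, RegionalResults

__all__ = [
    "ConfigError",
    "RegionalRun",
    "parse_config",
    "write_results",
    "write_regional_results",
]


class ConfigError(ValueError):
    """A configuration schema violation, reported with its field path."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


@dataclass(frozen=True)
class RegionalRun:
    """A parsed regional scenario: division inputs plus shared fragments."""

    divisions: Sequence[DivisionInputs]
    shared: ScenarioConfig


_MICROENV_NAMES = tuple(m.value for m in Microenvironment)


def _check_keys(d: Mapping, allowed: set[str], path: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(path, f"unknown keys {sorted(unknown)}; allowed: {sorted(allowed)}")


def _spec(d: Any, path: str) -> DistributionSpec:
    if not isinstance(d, Mapping):
        raise ConfigError(path, f"expected a distribution-spec mapping, got {type(d).__name__}")
    try:
        return DistributionSpec.from_dict(d)
    except (ValueError, KeyError) as exc:
        raise ConfigError(path, str(exc)) from exc


def _parse_population(d: Mapping, path: str) -> PopulationInputs:
    _check_keys(d, {"y0", "pop"}, path)
    try:
        return PopulationInputs(y0=float(d["y0"]), pop=int(d["pop"]))
    except (KeyError, ValueError) as exc:
        raise ConfigError(path, str(exc)) from exc


def _parse_effect(d: Mapping, path: str) -> EffectEstimate:
    allowed = {"rr", "rr_ci", "per_increment", "beta", "beta_ci", "sampling"}
    _check_keys(d, allowed, path)
    per = float(d.get("per_increment", 10.0))
    if "rr" in d:
        if "rr_ci" not in d:
            raise ConfigError(path, "rr requires rr_ci")
        beta = rr_to_beta(float(d["rr"]), per)
        lo, hi = (rr_to_beta(float(x), per) for x in d["rr_ci"])
    elif "beta" in d:
        beta = float(d["beta"])
        lo, hi = (float(x) for x in d.get("beta_ci", [beta, beta]))
    else:
        raise ConfigError(path, "need either rr or beta")
    sampling = _spec(d["sampling"], f"{path}.sampling") if "sampling" in d else None
    try:
        return EffectEstimate(beta=beta, ci_low=lo, ci_high=hi, sampling=sampling)
    except ValueError as exc:
        raise ConfigError(path, str(exc)) from exc


def _parse_microenv(d: Mapping, path: str) -> MicroenvironmentSpecs:
    allowed = {"ag_concentration", "outdoor", "infiltration", "ig_concentration"}
    _check_keys(d, allowed, path)
    kwargs = {k: _spec(v, f"{path}.{k}") for k, v in d.items()}
    try:
        return MicroenvironmentSpecs(**kwargs)
    except ValueError as exc:
        raise ConfigError(path, str(exc)) from exc


def _parse_exposure(d: Mapping, path: str) -> ExposureProfile:
    _check_keys(d, {"time_activity", "microenvironments", "baseline"}, path)
    ta_raw = d.get("time_activity")
    if ta_raw is None:
        ta = load_fixture("nhaps")
    else:
        _check_keys(ta_raw, set(_MICROENV_NAMES), f"{path}.time_activity")
        ta = {
            Microenvironment(k): (
                _spec(v, f"{path}.time_activity.{k}") if isinstance(v, Mapping) else float(v)
            )
            for k, v in ta_raw.items()
        }
    me_raw = d.get("microenvironments", {})
    _check_keys(me_raw, set(_MICROENV_NAMES), f"{path}.microenvironments")
    me = {
        Microenvironment(k): _parse_microenv(v, f"{path}.microenvironments.{k}")
        for k, v in me_raw.items()
    }
    try:
        return ExposureProfile(
            time_activity=ta,
            microenvironments=me,
            baseline=float(d.get("baseline", 0.0)),
        )
    except ValueError as exc:
        raise ConfigError(path, str(exc)) from exc


def _parse_mixture(items: Sequence, path: str) -> tuple[MixtureComponent, ...]:
    comps = []
    for i, item in enumerate(items):
        p = f"{path}[{i}]"
        _check_keys(item, {"label", "weight", "standin", "residence"}, p)
        if ("standin" in item) == ("residence" in item):
            raise ConfigError(p, "give exactly one of standin or residence")
        if "standin" in item:
            residence = _standin_residence(item["standin"])
        else:
            residence = _parse_microenv(item["residence"], f"{p}.residence")
        comps.append(
            MixtureComponent(
                label=str(item["label"]),
                weight=float(item["weight"]),
                residence=residence,
            )
        )
    return tuple(comps)


def parse_config(path) -> ScenarioConfig | RegionalRun:
    """Parse and validate a YAML scenario config.

    ``kind: national`` yields a :class:`ScenarioConfig`;
    ``kind: regional`` (the default) yields a :class:`RegionalRun` whose
    divisions default to the packaged regional input table and whose
    non-residential specs default to zeros.  Defaults applied:
    10,000 iterations, threshold 0, sum_ft 0.60; the master seed must be
    given in the config or at run time.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(str(path), "top level must be a mapping")
    kind = raw.get("kind", "regional")
    if kind == "national":
        return _parse_national(raw)
    if kind == "regional":
        return _parse_regional(raw)
    raise ConfigError("kind", f"must be 'national' or 'regional', got {kind!r}")


_COMMON_KEYS = {"kind", "sum_ft", "equal_toxicity", "ig_beta_override",
                "n_iterations", "master_seed", "effect", "population"}


def _parse_common(raw: Mapping) -> dict:
    c = load_fixture("constants")
    out: dict[str, Any] = {}
    if "population" in raw:
        out["population"] = _parse_population(raw["population"], "population")
    else:
        out["population"] = PopulationInputs(
            y0=c["national"]["mortality_rate"], pop=c["national"]["population"]
        )
    out["effect"] = (
        _parse_effect(raw["effect"], "effect") if "effect" in raw
        else default_effect_estimate()
    )
    sum_ft = raw.get("sum_ft", c["sum_ft"]["value"])
    out["sum_ft"] = _spec(sum_ft, "sum_ft") if isinstance(sum_ft, Mapping) else float(sum_ft)
    out["equal_toxicity"] = bool(raw.get("equal_toxicity", True))
    if "ig_beta_override" in raw:
        out["ig_beta_override"] = _parse_effect(raw["ig_beta_override"], "ig_beta_override")
    out["n_iterations"] = int(raw.get("n_iterations", DEFAULT_ITERATIONS))
    out["master_seed"] = int(raw.get("master_seed", 0))
    return out


def _parse_national(raw: Mapping) -> ScenarioConfig:
    _check_keys(raw, _COMMON_KEYS | {"exposure", "residential_mixture", "standin_profile"}, "<config>")
    common = _parse_common(raw)
    if "exposure" in raw and "standin_profile" in raw:
        raise ConfigError("<config>", "give exposure or standin_profile, not both")
    if "exposure" in raw:
        exposure = _parse_exposure(raw["exposure"], "exposure")
    else:
        exposure = make_standin_profile(raw.get("standin_profile", "riopa_like"))
    mixture = ()
    if "residential_mixture" in raw:
        mixture = _parse_mixture(raw["residential_mixture"], "residential_mixture")
    try:
        return ScenarioConfig(exposure=exposure, residential_mixture=mixture, **common)
    except ValueError as exc:
        raise ConfigError("<config>", str(exc)) from exc


def _parse_regional(raw: Mapping) -> RegionalRun:
    _check_keys(
        raw, _COMMON_KEYS | {"divisions", "nonresidential", "exposure"}, "<config>"
    )
    common = _parse_common(raw)
    divisions_raw = raw.get("divisions", "table1")
    if divisions_raw == "table1":
        divisions = load_fixture("table1")
    else:
        divisions = []
        for i, row in enumerate(divisions_raw):
            p = f"divisions[{i}]"
            _check_keys(
                row,
                {"name", "ig_res_mean", "ig_res_sd", "f_inf_mean", "f_inf_sd",
                 "outdoor_mean", "outdoor_p10", "outdoor_p90", "y0", "pop"},
                p,
            )
            try:
                divisions.append(DivisionInputs(**row))
            except (TypeError, ValueError) as exc:
                raise ConfigError(p, str(exc)) from exc
    if "exposure" in raw:
        exposure = _parse_exposure(raw["exposure"], "exposure")
    else:
        style = raw.get("nonresidential", "zeros")
        if style not in ("zeros", "standin"):
            raise ConfigError("nonresidential", f"must be 'zeros' or 'standin', got {style!r}")
        exposure = make_standin_profile("zeros" if style == "zeros" else "riopa_like")
    try:
        shared = ScenarioConfig(exposure=exposure, **common)
    except ValueError as exc:
        raise ConfigError("<config>", str(exc)) from exc
    return RegionalRun(divisions=tuple(divisions), shared=shared)


# ---------------------------------------------------------------------
# Results writing
# ---------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out: Path, config_echo: Mapping, seed: int, n_iterations: int) -> Path:
    files = sorted(p for p in out.iterdir() if p.name != "manifest.json" and p.is_file())
    manifest = {
        "package_version": __version__,
        "master_seed": seed,
        "n_iterations": n_iterations,
        "config": dict(config_echo),
        "checksums": {p.name: _sha256(p) for p in files},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def _attribution_frame(summary: SummaryStats) -> pd.DataFrame:
    df = summary.fractions.reset_index()
    # presentation columns rounded to the nearest 100 deaths; raw kept
    for col in ("attributed_deaths", "deaths_q25", "deaths_q75"):
        df[f"{col}_rounded"] = (df[col] / 100).round() * 100
    return df


def write_results(
    records: pd.DataFrame,
    summary: SummaryStats,
    out_dir,
    config_echo: Optional[Mapping] = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Write one national run: iterations, summary, attribution, manifest.

    Full numeric precision is preserved in the data columns; rounded
    presentation columns are added separately.  Returns the written
    paths by logical name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["iterations"] = out / "iterations.csv"
    records.to_csv(paths["iterations"], index=False)
    srow = dict(summary.total, shapiro_w=summary.shapiro_w, n_excluded=summary.n_excluded)
    paths["summary"] = out / "summary.csv"
    pd.DataFrame([srow]).to_csv(paths["summary"], index=False)
    paths["attribution"] = out / "attribution.csv"
    _attribution_frame(summary).to_csv(paths["attribution"], index=False)
    paths["manifest"] = _write_manifest(
        out, config_echo or {}, seed, len(records)
    )
    return paths


def write_regional_results(
    results: RegionalResults,
    out_dir,
    config_echo: Optional[Mapping] = None,
    seed: int = 0,
    n_iterations: int = DEFAULT_ITERATIONS,
) -> dict[str, Path]:
    """Write a regional run as a long-format CSV plus manifest.

    The long table has one row per (division, statistic, category) with
    the full-precision value and a presentation value rounded to the
    nearest 100 deaths; the national rollup appears as division
    ``Total``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    items = list(results.tables.items()) + [("Total", results.national)]
    for division, table in items:
        for category, row in table.iterrows():
            for stat in ("median", "q25", "q75"):
                rows.append(
                    {
                        "division": division,
                        "statistic": stat,
                        "category": category,
                        "value": row[stat],
                        "value_rounded": round(row[stat] / 100) * 100,
                    }
                )
    paths: dict[str, Path] = {"regional": out / "regional.csv"}
    pd.DataFrame(rows).to_csv(paths["regional"], index=False)
    paths["manifest"] = _write_manifest(out, config_echo or {}, seed, n_iterations)
    return paths
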