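"""The modified exposure-response function and death attribution.

Excess annual deaths attributable to PM2.5 exposure follow the
log-linear health impact function

    dy = y0 * [exp(beta_IG * E_IG + beta_AG * E_AG) - 1] * Pop

where ``y0`` is the baseline all-cause mortality rate (per person-year),
``Pop`` the affected population, ``E_IG``/``E_AG`` the time-weighted
indoor- and ambient-generated exposure sums (ug/m3) and
``beta_IG``/``beta_AG`` the (infiltration-modified) slopes per ug/m3.
With a single slope and a single exposure this reduces to the classical
ambient-only burden function.

Attribution apportions total deaths to (microenvironment, source)
categories in proportion to their beta-weighted share of the exponent,
beta_s * dC_{s,j} * t_j; under the default equal-toxicity setting these
are plain exposure shares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np

from .effect_estimates import SourceType
from .exposure import (
    ConcentrationSet,
    INDOOR_SOURCE_MICROENVS,
    Microenvironment,
)

__all__ = [
    "PopulationInputs",
    "BurdenResult",
    "burden",
    "exposure_fractions",
    "attribute",
    "CATEGORIES",
]

ArrayLike = Union[float, np.ndarray]

#: The seven (source, microenvironment) categories with defined exposure.
CATEGORIES: tuple[tuple[SourceType, Microenvironment], ...] = tuple(
    [(SourceType.AMBIENT_GENERATED, m) for m in Microenvironment]
    + [(SourceType.INDOOR_GENERATED, m) for m in INDOOR_SOURCE_MICROENVS]
)


@dataclass(frozen=True)
class PopulationInputs:
    """Population size and baseline mortality rate (per person-year)."""

    y0: float
    pop: int

    def __post_init__(self) -> None:
        if not 0 < self.y0 < 1:
            raise ValueError(f"y0 must be in (0, 1), got {self.y0}")
        if not self.pop > 0:
            raise ValueError(f"pop must be positive, got {self.pop}")


@dataclass(frozen=True)
class BurdenResult:
    """Excess deaths with per-category exposure terms and attribution."""

    delta_y: float
    exposure_terms: Mapping[tuple[SourceType, Microenvironment], float]
    fractions: Mapping[tuple[SourceType, Microenvironment], float]
    attributed_deaths: Mapping[tuple[SourceType, Microenvironment], float]


def burden(
    pop: PopulationInputs,
    beta_ig: ArrayLike,
    beta_ag: ArrayLike,
    e_ig: ArrayLike,
    e_ag: ArrayLike,
) -> ArrayLike:
    """Excess deaths per year from the modified exposure-response function.

    Broadcasts over arrays, so a whole Monte Carlo run can be evaluated
    in one call.  Strictly increasing and convex in each exposure.
    """
    exponent = np.multiply(beta_ig, e_ig) + np.multiply(beta_ag, e_ag)
    return pop.y0 * np.expm1(exponent) * pop.pop


def _exposure_terms(
    beta_ig: ArrayLike,
    beta_ag: ArrayLike,
    conc: ConcentrationSet,
    t: Mapping[Microenvironment, ArrayLike],
) -> dict[tuple[SourceType, Microenvironment], ArrayLike]:
    t = {Microenvironment(k): v for k, v in t.items()}
    terms: dict[tuple[SourceType, Microenvironment], ArrayLike] = {}
    for m in Microenvironment:
        terms[(SourceType.AMBIENT_GENERATED, m)] = np.multiply(
            beta_ag, conc.ag[m]
        ) * np.asarray(t[m], dtype=float)
    for m in INDOOR_SOURCE_MICROENVS:
        terms[(SourceType.INDOOR_GENERATED, m)] = np.multiply(
            beta_ig, conc.ig[m]
        ) * np.asarray(t[m], dtype=float)
    return terms


def exposure_fractions(
    beta_ig: ArrayLike,
    beta_ag: ArrayLike,
    conc: ConcentrationSet,
    t: Mapping[Microenvironment, ArrayLike],
) -> dict[tuple[SourceType, Microenvironment], ArrayLike]:
    """Per-(source, microenvironment) shares of the total exposure exponent.

    share(s, j) = beta_s * dC_{s,j} * t_j / sum over all categories.
    Scale-invariant: doubling every concentration leaves shares unchanged.
    For scalar inputs an all-zero exposure raises ``ValueError``; for
    array inputs all-zero iterations yield NaN shares (excluded from
    averages downstream).
    """
    terms = _exposure_terms(beta_ig, beta_ag, conc, t)
    total = sum(terms.values())
    total_arr = np.asarray(total, dtype=float)
    if total_arr.ndim == 0:
        if total_arr == 0.0:
            raise ValueError("all exposure terms are zero; fractions undefined")
        return {k: float(v / total) for k, v in terms.items()}
    with np.errstate(invalid="ignore", divide="ignore"):
        safe = np.where(total_arr > 0.0, total_arr, np.nan)
        return {k: np.asarray(v, dtype=float) / safe for k, v in terms.items()}


def attribute(
    total_deaths: float,
    mean_fractions: Mapping[tuple[SourceType, Microenvironment], float],
    round_to: int | None = 100,
) -> dict[tuple[SourceType, Microenvironment], float]:
    """Apportion a total death count by mean exposure fractions.

    deaths(s, j) = mean_fraction(s, j) * total_deaths, rounded to the
    nearest ``round_to`` deaths for presentation (pass ``None`` to keep
    full precision).  Conserves the total to within one rounding unit
    per category.
    """
    # printed fraction tables only carry 3 digits, so allow 0.5% slack
    total_frac = float(sum(mean_fractions.values()))
    if not np.isclose(total_frac, 1.0, atol=5e-3):
        raise ValueError(f"fractions must sum to ~1, got {total_frac}")
    out = {}
    for key, frac in mean_fractions.items():
        deaths = frac * total_deaths
        if round_to is not None:
            deaths = round(deaths / round_to) * round_to
        out[key] = float(deaths)
    return out
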