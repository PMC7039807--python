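"""Concentration-response effect estimates and their infiltration adjustment.

Cohort epidemiology reports the mortality association with outdoor PM2.5
as a relative risk (RR) per concentration increment, using the *outdoor*
concentration as the exposure surrogate.  Because people spend most of
their time indoors, where only a fraction of outdoor PM2.5 penetrates and
persists, the underlying personal exposure per unit outdoor concentration
in those cohorts was roughly the population time-weighted infiltration
sum

    sum_ft = sum_j F_j * t_j

over the four microenvironments (residence, other indoor, vehicle,
outdoor; F_outdoor = 1 by definition).  Re-expressing the slope per unit
of *actual* microenvironmental exposure therefore divides it by sum_ft:

    beta_modified = beta / sum_ft

The modified slope applies to exposure sums built from microenvironmental
concentrations rather than to the outdoor concentration alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping, Optional

from .distributions import DistributionSpec, scale_spec

__all__ = [
    "SourceType",
    "EffectEstimate",
    "InfiltrationProfile",
    "rr_to_beta",
    "weighted_infiltration_sum",
    "modify_beta",
]

_MICROENVS = ("residence", "other_indoor", "vehicle", "outdoor")


class SourceType(str, Enum):
    AMBIENT_GENERATED = "ambient_generated"
    INDOOR_GENERATED = "indoor_generated"


@dataclass(frozen=True)
class EffectEstimate:
    """A log-linear mortality slope beta (per ug/m3) with CI and sampler.

    ``modified=True`` marks a slope already divided by ``sum_ft`` and so
    expressed per unit of microenvironmental exposure.
    """

    beta: float
    ci_low: float
    ci_high: float
    sampling: Optional[DistributionSpec] = None
    source_type: SourceType = SourceType.AMBIENT_GENERATED
    modified: bool = False
    sum_ft: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError(
                f"require ci_low <= beta <= ci_high, got "
                f"({self.ci_low}, {self.beta}, {self.ci_high})"
            )
        if self.modified and self.sum_ft is None:
            raise ValueError("modified estimate must carry sum_ft")


@dataclass(frozen=True)
class InfiltrationProfile:
    """Per-microenvironment infiltration factors and time fractions.

    ``infiltration`` maps microenvironment name to F_j in [0, 1.5]
    (outdoors is fixed at 1 and may be omitted); ``time_fractions`` maps
    name to t_j.  Time fractions are normalised to sum to 1 on
    construction.
    """

    infiltration: Mapping[str, float]
    time_fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        f = dict(self.infiltration)
        f.setdefault("outdoor", 1.0)
        unknown = set(f) - set(_MICROENVS)
        if unknown:
            raise ValueError(f"unknown microenvironments: {sorted(unknown)}")
        if not math.isclose(f["outdoor"], 1.0, abs_tol=1e-12):
            raise ValueError("outdoor infiltration factor is 1 by definition")
        for name, val in f.items():
            if not 0.0 <= val <= 1.5:
                raise ValueError(f"infiltration factor {name}={val} outside [0, 1.5]")
        t = {k: float(v) for k, v in self.time_fractions.items()}
        unknown = set(t) - set(_MICROENVS)
        if unknown:
            raise ValueError(f"unknown microenvironments: {sorted(unknown)}")
        if any(v < 0 for v in t.values()):
            raise ValueError(f"time fractions must be non-negative, got {t}")
        total = sum(t.values())
        if total <= 0:
            raise ValueError("time fractions sum to zero")
        t = {k: v / total for k, v in t.items()}
        missing = set(_MICROENVS) - set(t)
        if missing:
            t.update({k: 0.0 for k in missing})
        object.__setattr__(self, "infiltration", f)
        object.__setattr__(self, "time_fractions", t)


def rr_to_beta(rr: float, per: float = 10.0) -> float:
    """Convert a relative risk per ``per`` ug/m3 to a slope per ug/m3.

    ``beta = ln(rr) / per``; e.g. the pooled all-cause RR of 1.073 per
    10 ug/m3 gives beta = 0.0070 per ug/m3.
    """
    if rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    if per <= 0:
        raise ValueError(f"concentration increment must be positive, got {per}")
    return math.log(rr) / per


def weighted_infiltration_sum(profile: InfiltrationProfile) -> float:
    """Population time-weighted infiltration sum, sum_j F_j * t_j.

    With national time-activity fractions and typical building stock
    this evaluates to ~0.60 for the US population.
    """
    f = profile.infiltration
    t = profile.time_fractions
    return sum(f.get(j, 0.0) * t[j] for j in _MICROENVS)


def modify_beta(raw: EffectEstimate, sum_ft: float) -> EffectEstimate:
    """Divide an effect estimate by the time-weighted infiltration sum.

    The central slope, both CI endpoints, and the scale of the sampling
    distribution are all divided by ``sum_ft``; the CI is transformed,
    not refit.
    """
    if not sum_ft > 0:
        raise ValueError(f"sum_ft must be positive, got {sum_ft}")
    if sum_ft > 1.5:
        raise ValueError(f"sum_ft {sum_ft} exceeds the physical bound 1.5")
    sampling = None
    if raw.sampling is not None:
        sampling = scale_spec(raw.sampling, 1.0 / sum_ft)
    return replace(
        raw,
        beta=raw.beta / sum_ft,
        ci_low=raw.ci_low / sum_ft,
        ci_high=raw.ci_high / sum_ft,
        sampling=sampling,
        modified=True,
        sum_ft=sum_ft,
    )
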