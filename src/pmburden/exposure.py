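"""Microenvironmental PM2.5 concentrations and time-weighted exposure sums.

Total PM2.5 exposure is decomposed over four microenvironments —
residences, other indoor locations (offices, schools, restaurants, ...),
vehicles, and outdoors — and two source classes: ambient-generated (AG,
outdoor-origin particles that infiltrate indoors or are breathed
outdoors) and indoor-generated (IG, particles emitted indoors by cooking,
candles, resuspension, ...).  Vehicles and the outdoors are assumed to
have no indoor-generated sources.

The aggregate exposures entering the exposure-response function are
time-activity weighted sums of above-baseline concentrations:

    E_IG = dC_IG,res * t_res + dC_IG,other * t_other
    E_AG = dC_AG,res * t_res + dC_AG,other * t_other
         + dC_AG,veh * t_veh + dC_out * t_out

Indoor ambient-generated concentrations follow the infiltration-factor
relation dC_AG,j = F_j * C_out.  All functions here broadcast over NumPy
arrays, so a Monte Carlo run can aggregate all iterations at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Union

import numpy as np

from .distributions import DistributionSpec

__all__ = [
    "Microenvironment",
    "INDOOR_SOURCE_MICROENVS",
    "ConcentrationSet",
    "ExposureProfile",
    "MicroenvironmentSpecs",
    "ambient_indoor_concentration",
    "aggregate_exposures",
    "normalize_time_fractions",
]

ArrayLike = Union[float, np.ndarray]


class Microenvironment(str, Enum):
    RESIDENCE = "residence"
    OTHER_INDOOR = "other_indoor"
    VEHICLE = "vehicle"
    OUTDOOR = "outdoor"


#: Microenvironments that can host indoor-generated PM2.5 sources.
INDOOR_SOURCE_MICROENVS = (Microenvironment.RESIDENCE, Microenvironment.OTHER_INDOOR)

_ALL = tuple(Microenvironment)


def _as_nonnegative(x: ArrayLike, name: str) -> ArrayLike:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return x if np.isscalar(x) or isinstance(x, float) else arr


@dataclass(frozen=True)
class ConcentrationSet:
    """Above-baseline concentrations per microenvironment and source.

    ``ag`` maps every microenvironment to its ambient-generated
    concentration (for the outdoor entry this is the outdoor
    concentration itself); ``ig`` maps the two indoor-source
    microenvironments to their indoor-generated concentrations.  Values
    may be scalars or equal-length arrays (one entry per Monte Carlo
    iteration).  ``baseline`` is the threshold concentration already
    subtracted from the stored values; it is recorded for provenance and
    defaults to 0 (no-threshold assumption).
    """

    ag: Mapping[Microenvironment, ArrayLike]
    ig: Mapping[Microenvironment, ArrayLike]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        ag = {Microenvironment(k): v for k, v in self.ag.items()}
        ig = {Microenvironment(k): v for k, v in self.ig.items()}
        missing = set(_ALL) - set(ag)
        if missing:
            raise ValueError(f"missing AG concentrations for {sorted(m.value for m in missing)}")
        bad = set(ig) - set(INDOOR_SOURCE_MICROENVS)
        if bad:
            raise ValueError(
                "indoor-generated concentrations are only defined for "
                f"residence and other_indoor, got {sorted(m.value for m in bad)}"
            )
        for m in INDOOR_SOURCE_MICROENVS:
            ig.setdefault(m, 0.0)
        for name, mapping in (("AG", ag), ("IG", ig)):
            for m, v in mapping.items():
                _as_nonnegative(v, f"{name} concentration in {m.value}")
        if self.baseline < 0:
            raise ValueError(f"baseline must be non-negative, got {self.baseline}")
        object.__setattr__(self, "ag", ag)
        object.__setattr__(self, "ig", ig)


@dataclass(frozen=True)
class MicroenvironmentSpecs:
    """Sampling specs for one microenvironment's concentrations.

    Ambient-generated concentrations may be specified either directly
    (``ag_concentration``) or as the product of an outdoor concentration
    and an infiltration factor (``outdoor`` x ``infiltration``); exactly
    one route must be given.  ``ig_concentration`` is allowed only for
    residences and other indoor locations.
    """

    ag_concentration: Optional[DistributionSpec] = None
    outdoor: Optional[DistributionSpec] = None
    infiltration: Optional[DistributionSpec] = None
    ig_concentration: Optional[DistributionSpec] = None

    def __post_init__(self) -> None:
        direct = self.ag_concentration is not None
        via_inf = self.outdoor is not None and self.infiltration is not None
        if direct == via_inf:
            raise ValueError(
                "give exactly one of ag_concentration or "
                "(outdoor + infiltration)"
            )


@dataclass(frozen=True)
class ExposureProfile:
    """Time-activity fractions plus per-microenvironment sampling specs.

    ``time_activity`` maps microenvironment to either a fixed fraction or
    a DistributionSpec; sampled fractions are renormalised to sum to 1 in
    each iteration.  ``microenvironments`` maps microenvironment to its
    :class:`MicroenvironmentSpecs`.
    """

    time_activity: Mapping[Microenvironment, Union[float, DistributionSpec]]
    microenvironments: Mapping[Microenvironment, MicroenvironmentSpecs]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        ta = {Microenvironment(k): v for k, v in self.time_activity.items()}
        me = {Microenvironment(k): v for k, v in self.microenvironments.items()}
        if set(ta) != set(_ALL):
            raise ValueError("time_activity must cover all four microenvironments")
        if set(me) != set(_ALL):
            raise ValueError("microenvironments must cover all four microenvironments")
        for m in (Microenvironment.VEHICLE, Microenvironment.OUTDOOR):
            if me[m].ig_concentration is not None:
                raise ValueError(f"{m.value} cannot have an indoor-generated source")
        fixed = {
            k: float(v) for k, v in ta.items() if not isinstance(v, DistributionSpec)
        }
        if any(v < 0 for v in fixed.values()):
            raise ValueError("time fractions must be non-negative")
        object.__setattr__(self, "time_activity", ta)
        object.__setattr__(self, "microenvironments", me)


def ambient_indoor_concentration(c_out: ArrayLike, f_inf: ArrayLike) -> ArrayLike:
    """Indoor concentration of ambient origin: F_inf x C_outdoor."""
    _as_nonnegative(c_out, "outdoor concentration")
    _as_nonnegative(f_inf, "infiltration factor")
    return f_inf * np.asarray(c_out, dtype=float) if isinstance(
        c_out, np.ndarray
    ) or isinstance(f_inf, np.ndarray) else f_inf * c_out


def normalize_time_fractions(
    t: Mapping[Microenvironment, ArrayLike]
) -> dict[Microenvironment, ArrayLike]:
    """Renormalise time fractions to sum to 1 (elementwise for arrays)."""
    t = {Microenvironment(k): np.asarray(v, dtype=float) for k, v in t.items()}
    if set(t) != set(_ALL):
        raise ValueError("time fractions must cover all four microenvironments")
    total = sum(t.values())
    if np.any(np.asarray(total) <= 0):
        raise ValueError("time fractions sum to zero")
    return {k: v / total for k, v in t.items()}


def aggregate_exposures(
    conc: ConcentrationSet, t: Mapping[Microenvironment, ArrayLike]
) -> tuple[ArrayLike, ArrayLike]:
    """Time-weighted exposure sums (E_IG, E_AG) in ug/m3.

    ``t`` must cover all four microenvironments and sum to 1 (use
    :func:`normalize_time_fractions` for sampled fractions).  Linear and
    monotone in every concentration and time fraction.
    """
    t = {Microenvironment(k): v for k, v in t.items()}
    missing = set(_ALL) - set(t)
    if missing:
        raise ValueError(f"missing time fractions for {sorted(m.value for m in missing)}")
    e_ig = sum(conc.ig[m] * t[m] for m in INDOOR_SOURCE_MICROENVS)
    e_ag = sum(conc.ag[m] * t[m] for m in _ALL)
    return e_ig, e_ag
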