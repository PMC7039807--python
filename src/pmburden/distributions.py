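"""Parametric distribution specs fitted to published summary statistics.

Model inputs for the burden framework (microenvironmental PM2.5
concentrations, infiltration factors, concentration-response slopes) are
available only as summary statistics — arithmetic means and SDs,
percentiles, or confidence intervals.  This module fits the small set of
distribution families the framework uses to those summaries and draws
reproducible (optionally truncated) samples from them.

Families
--------
``lognormal``
    Parameterised by geometric mean (GM) and geometric SD (GSD); the
    natural choice for strictly positive, right-skewed concentration data.
``weibull``
    Shape/scale; used for the mortality effect estimate because it is
    near-normal in shape for shape parameters around 4-5 yet strictly
    positive.
``beta``
    Two shape parameters on a bounded support (default [0, 1]); used for
    infiltration factors, which are physically confined fractions.
``normal``
    Mean/SD, usually combined with zero-truncation for concentrations.
``point``
    A degenerate spike; used for fixed scalars and for degenerate
    Monte Carlo runs.

Truncation
----------
Negative draws of concentration-valued quantities are *replaced with
zero* (not resampled), so the post-truncation distribution has an atom at
zero.  This keeps the sampled mean below the untruncated mean, which is
the conservative direction for burden estimates.

Reproducibility
---------------
All sampling flows from a single integer master seed through named
substreams (:func:`substream_seed`), so that each model parameter has an
independent, reproducible stream and adding a parameter never perturbs
the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "Family",
    "Truncation",
    "DistributionSpec",
    "substream_seed",
    "fit_lognormal_to_mean_and_percentiles",
    "fit_lognormal_to_mean_sd",
    "fit_weibull_to_mean_sd",
    "fit_beta_to_mean_sd",
    "sample",
    "spec_mean",
    "scale_spec",
]

_Z10 = stats.norm.ppf(0.10)
_Z90 = stats.norm.ppf(0.90)

#: Below this absolute SD a moment fit collapses to a point spec.
DEGENERATE_SD = 1e-9


class Family(str, Enum):
    LOGNORMAL = "lognormal"
    WEIBULL = "weibull"
    BETA = "beta"
    NORMAL = "normal"
    POINT = "point"


class Truncation(str, Enum):
    NONE = "none"
    REPLACE_NEGATIVE_WITH_ZERO = "replace_negative_with_zero"


@dataclass(frozen=True)
class DistributionSpec:
    """A parametric distribution plus its truncation rule and units.

    Parameters are family-specific:

    - lognormal: ``gm`` (geometric mean) and ``gsd`` (geometric SD > 1)
    - weibull: ``shape`` and ``scale`` (both > 0)
    - beta: ``a``, ``b`` (both > 0) and optional ``lower``/``upper``
      support bounds (default [0, 1])
    - normal: ``mean`` and ``sd`` (sd >= 0)
    - point: ``value``
    """

    family: Family
    params: Mapping[str, float]
    truncation: Truncation = Truncation.NONE
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "truncation", Truncation(self.truncation))
        object.__setattr__(self, "params", dict(self.params))
        self._validate()

    def _validate(self) -> None:
        p = self.params
        try:
            if self.family is Family.LOGNORMAL:
                if not (p["gm"] > 0 and p["gsd"] > 1):
                    raise ValueError(
                        f"lognormal requires gm > 0 and gsd > 1, got {p}"
                    )
            elif self.family is Family.WEIBULL:
                if not (p["shape"] > 0 and p["scale"] > 0):
                    raise ValueError(
                        f"weibull requires shape, scale > 0, got {p}"
                    )
            elif self.family is Family.BETA:
                lower = p.setdefault("lower", 0.0)
                upper = p.setdefault("upper", 1.0)
                if not (p["a"] > 0 and p["b"] > 0):
                    raise ValueError(f"beta requires a, b > 0, got {p}")
                if not lower < upper:
                    raise ValueError(
                        f"beta support must satisfy lower < upper, got {p}"
                    )
            elif self.family is Family.NORMAL:
                if not p["sd"] >= 0:
                    raise ValueError(f"normal requires sd >= 0, got {p}")
            elif self.family is Family.POINT:
                float(p["value"])
        except KeyError as exc:
            raise ValueError(
                f"missing parameter {exc} for family {self.family.value}"
            ) from exc

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "params": dict(self.params),
            "truncation": self.truncation.value,
            "units": self.units,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionSpec":
        known = {"family", "params", "truncation", "units"}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown distribution-spec keys: {sorted(extra)}")
        return cls(
            family=d["family"],
            params=d["params"],
            truncation=d.get("truncation", Truncation.NONE),
            units=d.get("units", ""),
        )


def point(value: float, units: str = "") -> DistributionSpec:
    """Shorthand for a degenerate spec at ``value``."""
    return DistributionSpec(Family.POINT, {"value": float(value)}, units=units)


# ---------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------

def substream_seed(master_seed: int, *keys) -> np.random.SeedSequence:
    """Derive an independent, reproducible substream from a master seed.

    String keys are hashed with CRC32 so that streams are keyed by stable
    parameter names rather than by declaration order; integer keys pass
    through unchanged.  Distinct key tuples give statistically
    independent streams (``numpy.random.SeedSequence`` guarantees).
    """
    ints = []
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode("utf-8")))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(ints))


# ---------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------

def fit_lognormal_to_mean_and_percentiles(
    mean: float, p10: float, p90: float, units: str = ""
) -> DistributionSpec:
    """Fit a lognormal to an arithmetic mean and 10th/90th percentiles.

    The three summary statistics over-determine the two lognormal
    parameters, so the fit minimises the summed squared *relative* error
    of (mean, p10, p90) with equal weights.  Deterministic: a Nelder-Mead
    polish from a moment-based start with tight tolerances.

    Used for outdoor PM2.5 concentrations, for which monitoring networks
    report annual mean and percentiles.

    Raises
    ------
    ValueError
        If the inputs are non-positive or not ordered ``p10 < mean`` and
        ``p10 < p90``.
    """
    if not (0 < p10 < mean and p10 < p90):
        raise ValueError(
            f"require 0 < p10 < mean and p10 < p90, got mean={mean}, "
            f"p10={p10}, p90={p90}"
        )
    obs = np.array([mean, p10, p90], dtype=float)

    def implied(theta: np.ndarray) -> np.ndarray:
        mu, logsig = theta
        sig = np.exp(logsig)
        return np.exp([mu + sig * sig / 2.0, mu + sig * _Z10, mu + sig * _Z90])

    def objective(theta: np.ndarray) -> float:
        return float(np.sum(((implied(theta) - obs) / obs) ** 2))

    # moment-flavoured start: centre near the mean, spread from the
    # percentile ratio
    sig0 = max(np.log(p90 / p10) / (_Z90 - _Z10), 1e-3)
    x0 = np.array([np.log(mean) - sig0**2 / 2.0, np.log(sig0)])
    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 5000},
    )
    mu, sig = res.x[0], float(np.exp(res.x[1]))
    return DistributionSpec(
        Family.LOGNORMAL,
        {"gm": float(np.exp(mu)), "gsd": float(np.exp(sig))},
        units=units,
    )


def fit_lognormal_to_mean_sd(mean: float, sd: float, units: str = "") -> DistributionSpec:
    """Moment-matched lognormal from an arithmetic mean and SD.

    Closed form: ``sigma^2 = ln(1 + (sd/mean)^2)``,
    ``mu = ln(mean) - sigma^2/2``.  Collapses to a point spec when the SD
    is negligible.  Used for residential indoor-origin concentrations
    reported as mean (SD) per census division.
    """
    if mean <= 0 or sd < 0:
        raise ValueError(f"require mean > 0 and sd >= 0, got {mean}, {sd}")
    if sd < DEGENERATE_SD:
        return point(mean, units)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return DistributionSpec(
        Family.LOGNORMAL,
        {"gm": float(np.exp(mu)), "gsd": float(np.exp(np.sqrt(sigma2)))},
        units=units,
    )


def _weibull_cv(k: float) -> float:
    g1 = special.gamma(1.0 + 1.0 / k)
    g2 = special.gamma(1.0 + 2.0 / k)
    return float(np.sqrt(max(g2 - g1 * g1, 0.0)) / g1)


def fit_weibull_to_mean_sd(mean: float, sd: float, units: str = "") -> DistributionSpec:
    """Method-of-moments Weibull from mean and SD.

    Solves ``scale * Gamma(1 + 1/shape) = mean`` and the matching variance
    identity by a bracketed root-find on the coefficient of variation,
    which is strictly decreasing in the shape parameter.

    Used for the concentration-response slope: a Weibull with shape ~5 is
    close to normal in shape but never produces negative slopes.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError(f"require mean, sd > 0, got {mean}, {sd}")
    cv = sd / mean
    k_lo, k_hi = 0.05, 500.0
    if not (_weibull_cv(k_hi) < cv < _weibull_cv(k_lo)):
        raise ValueError(
            f"coefficient of variation {cv:.4g} unattainable by a Weibull "
            f"in the searched shape range [{k_lo}, {k_hi}]"
        )
    k = optimize.brentq(lambda x: _weibull_cv(x) - cv, k_lo, k_hi, xtol=1e-13)
    lam = mean / special.gamma(1.0 + 1.0 / k)
    return DistributionSpec(
        Family.WEIBULL, {"shape": float(k), "scale": float(lam)}, units=units
    )


def fit_beta_to_mean_sd(
    mean: float,
    sd: float,
    lower: float = 0.0,
    upper: float = 1.0,
    units: str = "",
) -> DistributionSpec:
    """Method-of-moments beta on ``[lower, upper]`` from mean and SD.

    Used for infiltration factors, which are fractions confined to a
    physical range.  Returns a point spec in the zero-variance limit.

    Raises
    ------
    ValueError
        If the mean lies outside the support or the variance is
        infeasible for it (``sd^2 >= (mean-lower)(upper-mean)``).
    """
    if not lower <= mean <= upper:
        raise ValueError(f"mean {mean} outside support [{lower}, {upper}]")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    if sd < DEGENERATE_SD:
        return point(mean, units)
    span = upper - lower
    m = (mean - lower) / span
    v = (sd / span) ** 2
    if v >= m * (1.0 - m):
        raise ValueError(
            f"variance {sd**2:.4g} infeasible for mean {mean} on "
            f"[{lower}, {upper}]"
        )
    nu = m * (1.0 - m) / v - 1.0
    a, b = m * nu, (1.0 - m) * nu
    return DistributionSpec(
        Family.BETA,
        {"a": float(a), "b": float(b), "lower": float(lower), "upper": float(upper)},
        units=units,
    )


# ---------------------------------------------------------------------
# Moments, sampling, rescaling
# ---------------------------------------------------------------------

def spec_mean(spec: DistributionSpec) -> float:
    """Closed-form (pre-truncation) mean of a spec."""
    p = spec.params
    if spec.family is Family.LOGNORMAL:
        return p["gm"] * float(np.exp(np.log(p["gsd"]) ** 2 / 2.0))
    if spec.family is Family.WEIBULL:
        return p["scale"] * float(special.gamma(1.0 + 1.0 / p["shape"]))
    if spec.family is Family.BETA:
        frac = p["a"] / (p["a"] + p["b"])
        return p["lower"] + frac * (p["upper"] - p["lower"])
    if spec.family is Family.NORMAL:
        return p["mean"]
    return p["value"]


def sample(spec: DistributionSpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` values; deterministic given ``(spec, n, seed)``.

    ``seed`` may be an integer or a :class:`numpy.random.SeedSequence`
    (e.g. from :func:`substream_seed`).  The truncation rule is applied
    after drawing: negative values are replaced with zero, not resampled.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    p = spec.params
    if spec.family is Family.LOGNORMAL:
        out = rng.lognormal(np.log(p["gm"]), np.log(p["gsd"]), size=n)
    elif spec.family is Family.WEIBULL:
        out = p["scale"] * rng.weibull(p["shape"], size=n)
    elif spec.family is Family.BETA:
        out = p["lower"] + (p["upper"] - p["lower"]) * rng.beta(
            p["a"], p["b"], size=n
        )
    elif spec.family is Family.NORMAL:
        out = rng.normal(p["mean"], p["sd"], size=n)
    else:
        out = np.full(n, p["value"], dtype=float)
    if spec.truncation is Truncation.REPLACE_NEGATIVE_WITH_ZERO:
        out = np.where(out < 0.0, 0.0, out)
    return out


def scale_spec(spec: DistributionSpec, factor: float) -> DistributionSpec:
    """Rescale a spec so every draw is multiplied by ``factor`` (> 0).

    Lognormal, Weibull, normal and point families are closed under
    positive scaling; the beta family is rescaled through its support
    bounds.  Used when dividing an effect-estimate sampling distribution
    by the time-weighted infiltration sum.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    p = dict(spec.params)
    if spec.family is Family.LOGNORMAL:
        p["gm"] *= factor
    elif spec.family is Family.WEIBULL:
        p["scale"] *= factor
    elif spec.family is Family.BETA:
        p["lower"] *= factor
        p["upper"] *= factor
    elif spec.family is Family.NORMAL:
        p["mean"] *= factor
        p["sd"] *= factor
    else:
        p["value"] *= factor
    return replace(spec, params=p)
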