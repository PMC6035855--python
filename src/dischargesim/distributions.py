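"""Activity-duration models.

Every activity in the discharge process carries a :class:`DurationModel`
describing how long it takes, in minutes.  Six families are supported:

``weibull``
    shape ``beta`` and scale ``eta`` (minutes); the convention used for the
    medical-records processing time W(1.7374, 22.091).
``normal``
    mean and standard deviation of the variate, truncated at zero by
    resampling (negative service times are physically meaningless).
``lognormal``
    mean and standard deviation **of the variate itself** (not of its log);
    the convention used for the accounting attention time L(2.3975, 2.2456).
``exponential``
    mean.
``triangular``
    (left, mode, right).
``fixed``
    a degenerate point mass; useful for deterministic verification runs.

Negative draws under truncation are resampled, not clipped: clipping piles
probability mass at zero and biases the mean downward asymmetrically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats

FAMILIES = ("weibull", "normal", "lognormal", "exponential", "triangular", "fixed")

_N_PARAMS = {
    "weibull": 2,
    "normal": 2,
    "lognormal": 2,
    "exponential": 1,
    "triangular": 3,
    "fixed": 1,
}


class InvalidModelError(ValueError):
    """Raised for an unknown family or inconsistent parameters."""


@dataclass(frozen=True)
class DurationModel:
    family: str
    params: Tuple[float, ...]
    truncate_at_zero: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidModelError(f"unknown duration family {self.family!r}")
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        if len(params) != _N_PARAMS[self.family]:
            raise InvalidModelError(
                f"{self.family} expects {_N_PARAMS[self.family]} parameters, got {len(params)}"
            )
        if self.family == "weibull":
            if params[0] <= 0 or params[1] <= 0:
                raise InvalidModelError("weibull shape and scale must be > 0")
        elif self.family in ("normal", "lognormal"):
            if params[1] <= 0:
                raise InvalidModelError(f"{self.family} sd must be > 0")
            if self.family == "lognormal" and params[0] <= 0:
                raise InvalidModelError("lognormal mean must be > 0")
        elif self.family == "exponential":
            if params[0] <= 0:
                raise InvalidModelError("exponential mean must be > 0")
        elif self.family == "triangular":
            a, m, b = params
            if not (a <= m <= b) or a == b:
                raise InvalidModelError("triangular requires left <= mode <= right, left < right")
        elif self.family == "fixed":
            if params[0] < 0:
                raise InvalidModelError("fixed value must be >= 0")

    # -- analytic moments ---------------------------------------------------

    def mean(self) -> float:
        """Analytic mean of the sampled variate (accounting for truncation)."""
        p = self.params
        if self.family == "fixed":
            return p[0]
        if self.family == "weibull":
            beta, eta = p
            return eta * math.gamma(1.0 + 1.0 / beta)
        if self.family == "normal":
            mu, sd = p
            if not self.truncate_at_zero:
                return mu
            a = (0.0 - mu) / sd
            return float(stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd))
        if self.family == "lognormal":
            return p[0]
        if self.family == "exponential":
            return p[0]
        if self.family == "triangular":
            a, m, b = p
            return (a + m + b) / 3.0
        raise InvalidModelError(self.family)  # pragma: no cover

    def _lognormal_log_params(self) -> Tuple[float, float]:
        m, s = self.params
        sigma2 = math.log1p((s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)

    # -- sampling -----------------------------------------------------------

    def sample(self, rng: np.random.Generator, size: int | None = None) -> float | np.ndarray:
        """Draw one value (``size=None``) or an array of values."""
        n = 1 if size is None else int(size)
        out = self._raw(rng, n)
        if self.truncate_at_zero:
            bad = out < 0.0
            tries = 0
            while bad.any():
                out[bad] = self._raw(rng, int(bad.sum()))
                bad = out < 0.0
                tries += 1
                if tries > 1000:  # pragma: no cover - unreachable for valid models
                    raise InvalidModelError("truncation resampling failed to converge")
        return float(out[0]) if size is None else out

    def _raw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.family == "fixed":
            return np.full(n, p[0])
        if self.family == "weibull":
            beta, eta = p
            return eta * rng.weibull(beta, n)
        if self.family == "normal":
            return rng.normal(p[0], p[1], n)
        if self.family == "lognormal":
            mu, sigma = self._lognormal_log_params()
            return rng.lognormal(mu, sigma, n)
        if self.family == "exponential":
            return rng.exponential(p[0], n)
        if self.family == "triangular":
            a, m, b = p
            return rng.triangular(a, m, b, n)
        raise InvalidModelError(self.family)  # pragma: no cover

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = {"family": self.family, "params": list(self.params)}
        if not self.truncate_at_zero:
            d["truncate_at_zero"] = False
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DurationModel":
        return cls(d["family"], tuple(d["params"]), d.get("truncate_at_zero", True))


def sample_duration(model: DurationModel, rng: np.random.Generator) -> float:
    """Draw a single non-negative duration (minutes) from ``model``."""
    if not isinstance(model, DurationModel):
        raise InvalidModelError(f"not a DurationModel: {model!r}")
    return model.sample(rng)


# convenience constructors -------------------------------------------------

def weibull(shape: float, scale: float) -> DurationModel:
    return DurationModel("weibull", (shape, scale))


def normal(mean: float, sd: float) -> DurationModel:
    return DurationModel("normal", (mean, sd))


def lognormal(mean: float, sd: float) -> DurationModel:
    return DurationModel("lognormal", (mean, sd))


def exponential(mean: float) -> DurationModel:
    return DurationModel("exponential", (mean,))


def triangular(left: float, mode: float, right: float) -> DurationModel:
    return DurationModel("triangular", (left, mode, right))


def fixed(value: float) -> DurationModel:
    return DurationModel("fixed", (value,))
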