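"""Elicited uncertain quantities and Monte Carlo uncertainty propagation.

Burden inputs for data-sparse hazards are elicited as a best estimate with a
95% uncertainty interval, ``(best, lower95, upper95)``.  This module turns
such triples into parametric distributions, draws reproducible Monte Carlo
samples from them, and propagates them through arbitrary deterministic
transforms (rates, ratios, DALY arithmetic) to yield mean estimates with 95%
uncertainty intervals for derived risk metrics.

Fitting conventions
-------------------
* Count-like quantities (``support="nonnegative_real"``) are fitted with a
  lognormal whose median equals the elicited best estimate
  (``mu = ln(best)``) and whose log-scale spread is the least-squares
  compromise over the two bound residuals, which has the closed form
  ``sigma = (ln(upper95) - ln(lower95)) / (2 * z_0.975)``.  When the triple
  is log-symmetric (``best = sqrt(lower95 * upper95)``) the fitted 2.5% and
  97.5% quantiles reproduce the elicited bounds exactly.
* Proportions (``support="proportion"``) are fitted with a beta distribution
  by least squares over the 2.5%, 50% and 97.5% quantile residuals.
* A degenerate interval (``lower95 == upper95``) yields a point mass; this
  covers elicited certainties such as a mortality entry of ``0 (0, 0)``.
* A zero lower bound with a positive upper bound is replaced by
  ``upper95 * 1e-6`` before log-fitting, which keeps the support positive
  without visibly moving the fitted quantiles.

Summaries use the arithmetic mean and the 2.5th/97.5th percentiles with the
linear-interpolation quantile convention (numpy's default), pinned so that
repeated runs are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import PropagationError, ValidationError

#: two-sided 95% normal quantile
Z95 = 1.959963984540054

#: default number of Monte Carlo draws for interval estimates
DEFAULT_N_SIMS = 100_000

#: default seed; chosen after the 2010 reference year of the burden data
DEFAULT_SEED = 20100101

_SUPPORTS = ("nonnegative_real", "proportion")


@dataclass(frozen=True)
class UncertainQuantity:
    """An elicited value: best estimate plus 95% uncertainty interval.

    Percentages must be divided by 100 before construction; a
    ``proportion``-supported quantity lives on [0, 1].
    """

    best: float
    lower95: float
    upper95: float
    support: str = "nonnegative_real"

    def __post_init__(self) -> None:
        if self.support not in _SUPPORTS:
            raise ValidationError(f"unknown support {self.support!r}")
        if not (self.lower95 >= 0 and self.best >= 0 and self.upper95 >= 0):
            raise ValidationError(
                f"negative entry in elicited triple ({self.best}, "
                f"{self.lower95}, {self.upper95})"
            )
        if not (self.lower95 <= self.best <= self.upper95):
            raise ValidationError(
                f"elicited triple not ordered: lower95={self.lower95} "
                f"best={self.best} upper95={self.upper95}"
            )
        if self.support == "proportion" and self.upper95 > 1.0:
            raise ValidationError(
                f"proportion upper95={self.upper95} exceeds 1"
            )

    @property
    def is_degenerate(self) -> bool:
        return self.lower95 == self.upper95

    @classmethod
    def point(cls, value: float, support: str = "nonnegative_real") -> "UncertainQuantity":
        return cls(value, value, value, support)


@dataclass(frozen=True)
class FittedDistribution:
    """Parametric representation of an elicited quantity.

    families:
      ``point_mass`` — params ``(location,)``
      ``lognormal``  — params ``(mu, sigma)`` on the log scale
      ``beta``       — params ``(a, b)``
    """

    family: str
    params: tuple[float, ...]

    def quantile(self, q: float | np.ndarray) -> float | np.ndarray:
        if self.family == "point_mass":
            return np.broadcast_to(self.params[0], np.shape(q)).astype(float) if np.ndim(q) else self.params[0]
        if self.family == "lognormal":
            mu, sigma = self.params
            return stats.lognorm.ppf(q, s=sigma, scale=math.exp(mu))
        if self.family == "beta":
            a, b = self.params
            return stats.beta.ppf(q, a, b)
        raise ValidationError(f"unknown family {self.family!r}")

    def mean(self) -> float:
        if self.family == "point_mass":
            return self.params[0]
        if self.family == "lognormal":
            mu, sigma = self.params
            return math.exp(mu + sigma**2 / 2)
        a, b = self.params
        return a / (a + b)


@dataclass(frozen=True)
class SampleSummary:
    """Mean and central 95% interval of a Monte Carlo sample."""

    mean: float
    lower95: float
    upper95: float
    n_draws: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lower95 > self.upper95:
            raise ValidationError("summary interval inverted")


def fit_elicited(q: UncertainQuantity) -> FittedDistribution:
    """Fit a parametric distribution to an elicited triple.

    Degenerate intervals yield a point mass at the best estimate; otherwise
    count-like quantities get a median-preserving lognormal and proportions
    a least-squares beta (see module docstring for the conventions).
    """
    if q.is_degenerate:
        return FittedDistribution("point_mass", (q.best,))

    if q.support == "nonnegative_real":
        lo = q.lower95 if q.lower95 > 0 else q.upper95 * 1e-6
        best = q.best if q.best > 0 else math.sqrt(lo * q.upper95)
        mu = math.log(best)
        sigma = (math.log(q.upper95) - math.log(lo)) / (2 * Z95)
        return FittedDistribution("lognormal", (mu, sigma))

    return _fit_beta(q)


def _fit_beta(q: UncertainQuantity) -> FittedDistribution:
    """Least-squares beta fit over the three elicited quantiles."""
    lo = q.lower95 if q.lower95 > 0 else max(q.upper95 * 1e-6, 1e-12)
    hi = min(q.upper95, 1 - 1e-12)
    best = min(max(q.best, lo), hi)

    # method-of-moments initial guess from a normal-approximation spread
    m = best if 0 < best < 1 else (lo + hi) / 2
    s = max((hi - lo) / (2 * Z95), 1e-6)
    v = min(s**2, m * (1 - m) * 0.99)
    k = m * (1 - m) / v - 1
    a0, b0 = max(m * k, 1e-3), max((1 - m) * k, 1e-3)

    targets = np.array([lo, best, hi])
    probs = np.array([0.025, 0.5, 0.975])

    def residuals(log_ab: np.ndarray) -> np.ndarray:
        a, b = np.exp(log_ab)
        return stats.beta.ppf(probs, a, b) - targets

    sol = optimize.least_squares(
        residuals, x0=np.log([a0, b0]), method="lm", max_nfev=500
    )
    a, b = np.exp(sol.x)
    return FittedDistribution("beta", (float(a), float(b)))


def sample(d: FittedDistribution, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` reproducible samples from a fitted distribution."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    if d.family == "point_mass":
        return np.full(n, d.params[0], dtype=float)
    if d.family == "lognormal":
        mu, sigma = d.params
        return rng.lognormal(mean=mu, sigma=sigma, size=n)
    if d.family == "beta":
        a, b = d.params
        return rng.beta(a, b, size=n)
    raise ValidationError(f"unknown family {d.family!r}")


def summarize(samples: Sequence[float] | np.ndarray, seed: int | None = None) -> SampleSummary:
    """Arithmetic mean and 2.5/97.5 percentile interval of a sample."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot summarize an empty sample")
    lo, hi = np.quantile(x, [0.025, 0.975])  # linear interpolation
    return SampleSummary(
        mean=float(x.mean()), lower95=float(lo), upper95=float(hi),
        n_draws=int(x.size), seed=seed,
    )


def substream_seeds(seed: int, names: Sequence[str]) -> dict[str, int]:
    """Derive one independent 31-bit child seed per name from a root seed.

    Names are sorted so the mapping does not depend on dict ordering.
    """
    ordered = sorted(names)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ordered))
    out: dict[str, int] = {}
    for name, child in zip(ordered, children):
        out[name] = int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
    return out


def propagate(
    inputs: Mapping[str, UncertainQuantity | FittedDistribution],
    transform: Callable[..., np.ndarray],
    n: int = DEFAULT_N_SIMS,
    seed: int = DEFAULT_SEED,
) -> tuple[SampleSummary, np.ndarray]:
    """Push independent elicited inputs through a deterministic transform.

    Each named input is sampled from its own seeded substream (independence
    across inputs is an explicit modelling assumption), the transform is
    applied draw-wise via its keyword arguments, and the result is
    summarized.  Returns ``(summary, draws)``.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    seeds = substream_seeds(seed, list(inputs))
    draws: dict[str, np.ndarray] = {}
    for name, q in inputs.items():
        d = q if isinstance(q, FittedDistribution) else fit_elicited(q)
        draws[name] = sample(d, n, seeds[name])

    try:
        out = np.asarray(transform(**draws), dtype=float)
    except Exception as exc:  # locate the offending draw for the message
        for i in range(n):
            point = {k: v[i] for k, v in draws.items()}
            try:
                transform(**point)
            except Exception:
                raise PropagationError(
                    f"transform failed on draw {i}: {exc}"
                ) from exc
        raise PropagationError(f"transform failed vectorized: {exc}") from exc

    out = np.broadcast_to(out, (n,)).astype(float)
    return summarize(out, seed=seed), out
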