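"""Per-hazard burden metrics with Monte Carlo uncertainty.

Computes the selected risk metrics — incidence rate, mortality rate,
case-fatality ratio, and DALY rate (with its YLL and YLD components) — per
hazard and reference population.  DALYs are computed without age-weighting
or time-discounting (post-2010 WHO practice):

    YLL  = deaths x residual life expectancy at death
    YLD  = cases x disability weight x duration (years)
    DALY = YLL + YLD

Joint coherence between independently elicited cases and deaths is enforced
by rejection sampling: draws with deaths > cases are redrawn; the rejection
fraction is tracked, warned above 1% and treated as a model inconsistency
above 50%.  YLD for fatal cases is not subtracted — deaths also contribute
cases — a documented simplification.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import uncertainty as unc
from .errors import ModelInconsistencyError, ValidationError
from .uncertainty import SampleSummary, UncertainQuantity

#: standard rate denominator
PER = 100_000

#: precedence for which metric survives a redundancy flag (most aggregated first)
METRIC_PRECEDENCE = [
    "daly_rate", "yll_rate", "yld_rate",
    "mortality_rate", "incidence_rate", "case_fatality_pct",
]


@dataclass(frozen=True)
class BurdenRecord:
    """Elicited burden inputs for one hazard in a reference population."""

    hazard_id: str
    cases: UncertainQuantity
    deaths: UncertainQuantity
    disability_weight: UncertainQuantity
    duration_years: UncertainQuantity
    residual_life_expectancy_years: UncertainQuantity
    population: int
    reference_year: int = 2010

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValidationError(f"population must be positive, got {self.population}")
        if self.cases.best > 0 and self.deaths.best > self.cases.best:
            raise ValidationError(
                f"hazard {self.hazard_id!r}: best deaths "
                f"{self.deaths.best} exceed best cases {self.cases.best}"
            )
        if self.disability_weight.support != "proportion":
            raise ValidationError("disability_weight must have proportion support")


@dataclass(frozen=True)
class MetricSet:
    """Summarized risk metrics for one hazard, per 100,000 population
    (case-fatality in percent)."""

    hazard_id: str
    incidence_rate: SampleSummary
    mortality_rate: SampleSummary
    case_fatality_pct: SampleSummary
    yll_rate: SampleSummary
    yld_rate: SampleSummary
    daly_rate: SampleSummary
    n_rejected: int = 0

    def as_rows(self) -> list[dict]:
        rows = []
        for metric in ("incidence_rate", "mortality_rate", "case_fatality_pct",
                       "yll_rate", "yld_rate", "daly_rate"):
            s: SampleSummary = getattr(self, metric)
            rows.append({
                "hazard_id": self.hazard_id, "metric": metric,
                "mean": s.mean, "lower95": s.lower95, "upper95": s.upper95,
            })
        return rows


def rate_per_100k(count: float, population: int) -> float:
    """Convert an annual count to a rate per 100,000 population."""
    if population <= 0:
        raise ValidationError(f"population must be positive, got {population}")
    if count < 0:
        raise ValidationError(f"count must be nonnegative, got {count}")
    return count * PER / population


def case_fatality_pct(deaths: float, cases: float) -> float:
    """Case-fatality ratio in percent; NaN marks the 0/0 undefined case."""
    if deaths < 0 or cases < 0:
        raise ValidationError("deaths and cases must be nonnegative")
    if cases == 0:
        if deaths == 0:
            return math.nan
        raise ValidationError(f"{deaths} deaths with zero cases is incoherent")
    return 100.0 * deaths / cases


def daly_components(
    cases: float, deaths: float, dw: float, duration: float, rle: float
) -> tuple[float, float, float]:
    """Return (YLL, YLD, DALY) from counts and severity inputs."""
    if min(cases, deaths, dw, duration, rle) < 0:
        raise ValidationError("all DALY inputs must be nonnegative")
    if dw > 1:
        raise ValidationError(f"disability weight {dw} exceeds 1")
    yll = deaths * rle
    yld = cases * dw * duration
    return yll, yld, yll + yld


def compute_metric_set(
    r: BurdenRecord,
    n: int = unc.DEFAULT_N_SIMS,
    seed: int = unc.DEFAULT_SEED,
) -> MetricSet:
    """Joint Monte Carlo over a record's elicited inputs.

    All five uncertain inputs are sampled independently on seeded
    substreams; incoherent draws (deaths > cases) are rejected and redrawn.
    Each metric is summarized per 100,000 (case-fatality in percent, defined
    as 0 on draws with zero cases, which coherence forces to zero deaths).
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    names = ["cases", "deaths", "dw", "duration", "rle"]
    seeds = unc.substream_seeds(seed, names)
    fits = {
        "cases": unc.fit_elicited(r.cases),
        "deaths": unc.fit_elicited(r.deaths),
        "dw": unc.fit_elicited(r.disability_weight),
        "duration": unc.fit_elicited(r.duration_years),
        "rle": unc.fit_elicited(r.residual_life_expectancy_years),
    }
    draws = {k: unc.sample(fits[k], n, seeds[k]) for k in names}

    bad = draws["deaths"] > draws["cases"]
    n_bad0 = int(bad.sum())
    if n_bad0 > 0.5 * n:
        raise ModelInconsistencyError(
            f"hazard {r.hazard_id!r}: {n_bad0}/{n} draws have deaths > cases; "
            "elicited cases and deaths are mutually inconsistent"
        )
    n_rejected = 0
    rng_c = np.random.default_rng(seeds["cases"] + 1)
    rng_d = np.random.default_rng(seeds["deaths"] + 1)
    for _ in range(1000):
        idx = np.flatnonzero(draws["deaths"] > draws["cases"])
        if idx.size == 0:
            break
        n_rejected += idx.size
        draws["cases"][idx] = _redraw(fits["cases"], idx.size, rng_c)
        draws["deaths"][idx] = _redraw(fits["deaths"], idx.size, rng_d)
    else:  # pragma: no cover - pathological elicitation
        raise ModelInconsistencyError(
            f"hazard {r.hazard_id!r}: rejection sampling did not converge"
        )
    if n_rejected > 0.01 * n:
        warnings.warn(
            f"hazard {r.hazard_id!r}: {n_rejected} rejected draws "
            f"({100 * n_rejected / n:.1f}% of {n}) for deaths <= cases coherence",
            stacklevel=2,
        )

    cases, deaths = draws["cases"], draws["deaths"]
    yll = deaths * draws["rle"]
    yld = cases * draws["dw"] * draws["duration"]
    daly = yll + yld
    with np.errstate(divide="ignore", invalid="ignore"):
        cfr = np.where(cases > 0, 100.0 * deaths / np.where(cases > 0, cases, 1.0), 0.0)

    def per100k(x: np.ndarray) -> np.ndarray:
        return x * PER / r.population

    return MetricSet(
        hazard_id=r.hazard_id,
        incidence_rate=unc.summarize(per100k(cases), seed=seed),
        mortality_rate=unc.summarize(per100k(deaths), seed=seed),
        case_fatality_pct=unc.summarize(cfr, seed=seed),
        yll_rate=unc.summarize(per100k(yll), seed=seed),
        yld_rate=unc.summarize(per100k(yld), seed=seed),
        daly_rate=unc.summarize(per100k(daly), seed=seed),
        n_rejected=n_rejected,
    )


def _redraw(fit: unc.FittedDistribution, size: int, rng: np.random.Generator) -> np.ndarray:
    if fit.family == "point_mass":
        return np.full(size, fit.params[0])
    if fit.family == "lognormal":
        mu, sigma = fit.params
        return rng.lognormal(mu, sigma, size)
    a, b = fit.params
    return rng.beta(a, b, size)


def metrics_table(metric_sets: list[MetricSet]) -> pd.DataFrame:
    """Tidy long-format table (hazard, metric, mean, lower95, upper95)."""
    rows = list(itertools.chain.from_iterable(ms.as_rows() for ms in metric_sets))
    return pd.DataFrame(rows)


def metric_redundancy(
    metrics_table: pd.DataFrame, threshold: float = 0.9
) -> list[dict]:
    """Flag metric pairs whose Spearman rank correlation reaches a threshold.

    ``metrics_table`` is wide: hazards in rows, metric point estimates in
    columns.  For each flagged pair the more aggregated metric (DALY before
    YLL before the raw rates) is marked ``retain`` and the other ``drop`` —
    this is the rule by which a YLL column tracking mortality is removed as
    redundant.  Constant columns are skipped with a warning.
    """
    if not (0 < threshold <= 1):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    if len(metrics_table) < 3:
        raise ValidationError("metric redundancy needs at least 3 hazards")
    flagged: list[dict] = []
    cols = list(metrics_table.columns)
    for a, b in itertools.combinations(cols, 2):
        xa, xb = metrics_table[a].to_numpy(float), metrics_table[b].to_numpy(float)
        if np.all(xa == xa[0]) or np.all(xb == xb[0]):
            warnings.warn(
                f"metric pair ({a}, {b}) skipped: constant column", stacklevel=2
            )
            continue
        rho = stats.spearmanr(xa, xb).statistic
        if rho >= threshold:
            ranked = sorted(
                (a, b),
                key=lambda m: METRIC_PRECEDENCE.index(m) if m in METRIC_PRECEDENCE else len(METRIC_PRECEDENCE),
            )
            flagged.append({
                "metric_a": a, "metric_b": b, "spearman": float(rho),
                "retain": ranked[0], "drop": ranked[1],
            })
    return flagged
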