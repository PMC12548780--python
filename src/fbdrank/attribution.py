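"""Delphi aggregation of expert attributions and conversion to deaths.

A panel of experts attributes each high-risk hazard's foodborne burden to
food groups in up to two anonymous rounds; second-round revisions replace
that expert's first-round answer hazard by hazard.  Aggregation is the
arithmetic mean of normalized expert vectors (mean preserves additivity
when proportions are later multiplied into death counts), optionally
combined with a study-team literature estimate treated as one extra
pseudo-expert with configurable weight.

Death attribution assumes deaths split across food groups proportionally to
cases.  Single-route hazards (e.g. a pathogen transmitted only through
dairy) bypass elicitation entirely: their rows are point masses on the
fixed food group.  Food groups rarely consumed in the study setting can be
dropped, with rows renormalized over the remaining groups.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AttributionError
from .hazard_registry import Hazard

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class ExpertResponse:
    """One expert's food-group proportions for one hazard in one round."""

    expert_id: str
    round: int
    hazard_id: str
    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.round not in (1, 2):
            raise AttributionError(f"round must be 1 or 2, got {self.round}")
        vals = list(self.proportions.values())
        if any(v < 0 for v in vals):
            raise AttributionError(
                f"expert {self.expert_id!r} hazard {self.hazard_id!r}: "
                "negative proportion"
            )


@dataclass
class AttributionMatrix:
    """Hazards x food-groups proportions (rows sum to 1) with optional
    per-hazard total foodborne deaths."""

    proportions: pd.DataFrame
    deaths: pd.Series | None = None

    def __post_init__(self) -> None:
        p = self.proportions
        if ((p < -_ROW_TOL) | (p > 1 + _ROW_TOL)).any().any():
            raise AttributionError("proportions outside [0, 1]")
        row_sums = p.sum(axis=1)
        off = row_sums[(row_sums - 1).abs() > 1e-6]
        if len(off):
            raise AttributionError(
                f"rows not summing to 1: {dict(off.round(6))}"
            )
        if self.deaths is not None:
            self.deaths = self.deaths.reindex(p.index)
            if self.deaths.isna().any():
                missing = list(self.deaths[self.deaths.isna()].index)
                raise AttributionError(f"missing death totals for {missing}")
            if (self.deaths < 0).any():
                raise AttributionError("negative death totals")

    @property
    def hazards(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def food_groups(self) -> list[str]:
        return list(self.proportions.columns)


@dataclass(frozen=True)
class AttributedDeaths:
    """Hazards x food-groups death counts with conserved marginals."""

    deaths: pd.DataFrame

    @property
    def by_food_group(self) -> pd.Series:
        return self.deaths.sum(axis=0)

    @property
    def by_hazard(self) -> pd.Series:
        return self.deaths.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.deaths.to_numpy().sum())


def normalize_response(r: ExpertResponse) -> ExpertResponse:
    """Rescale an expert's proportions to sum to one."""
    total = sum(r.proportions.values())
    if total <= 0:
        raise AttributionError(
            f"expert {r.expert_id!r} hazard {r.hazard_id!r}: all-zero response"
        )
    return replace(r, proportions={g: v / total for g, v in r.proportions.items()})


def delphi_aggregate(
    responses: Sequence[ExpertResponse],
    team_estimates: Mapping[str, Mapping[str, float]] | None = None,
    team_weight: float = 1.0,
    aggregator: str = "mean",
) -> AttributionMatrix:
    """Combine multi-round expert responses into one attribution matrix.

    Per expert, round-2 answers override round-1 answers hazard-wise; per
    hazard, the normalized vectors are combined across experts by the
    arithmetic mean (or median), with an optional study-team estimate
    entering as a pseudo-expert of weight ``team_weight``.  The result is
    renormalized row-wise.
    """
    if aggregator not in ("mean", "median"):
        raise AttributionError(f"unknown aggregator {aggregator!r}")
    latest: dict[tuple[str, str], ExpertResponse] = {}
    for r in responses:
        key = (r.expert_id, r.hazard_id)
        if key not in latest or r.round > latest[key].round:
            latest[key] = r

    groups: list[str] = []
    for r in latest.values():
        for g in r.proportions:
            if g not in groups:
                groups.append(g)
    if team_estimates:
        for vec in team_estimates.values():
            for g in vec:
                if g not in groups:
                    groups.append(g)

    by_hazard: dict[str, list[tuple[np.ndarray, float]]] = {}
    for r in latest.values():
        norm = normalize_response(r)
        vec = np.array([norm.proportions.get(g, 0.0) for g in groups])
        by_hazard.setdefault(r.hazard_id, []).append((vec, 1.0))
    if team_estimates:
        for hz, raw in team_estimates.items():
            total = sum(raw.values())
            if total <= 0:
                raise AttributionError(f"all-zero team estimate for {hz!r}")
            vec = np.array([raw.get(g, 0.0) / total for g in groups])
            by_hazard.setdefault(hz, []).append((vec, team_weight))

    if not by_hazard:
        raise AttributionError("no responses to aggregate")

    rows = {}
    for hz, entries in sorted(by_hazard.items()):
        vecs = np.stack([v for v, _ in entries])
        wts = np.array([w for _, w in entries])
        if aggregator == "mean":
            combined = (vecs * wts[:, None]).sum(axis=0) / wts.sum()
        else:
            combined = np.median(vecs, axis=0)
        rows[hz] = combined / combined.sum()
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=groups)
    return AttributionMatrix(proportions=frame)


def apply_fixed_attributions(
    m: AttributionMatrix, registry: Iterable[Hazard]
) -> AttributionMatrix:
    """Force single-route hazards onto their fixed food group.

    Hazards with ``fixed_food_group`` set become point-mass rows on that
    group, overriding any elicited values.
    """
    p = m.proportions.copy()
    for hz in registry:
        if hz.fixed_food_group is None or hz.id not in p.index:
            continue
        if hz.fixed_food_group not in p.columns:
            raise AttributionError(
                f"fixed food group {hz.fixed_food_group!r} for hazard "
                f"{hz.id!r} not among matrix columns {list(p.columns)}"
            )
        p.loc[hz.id] = 0.0
        p.loc[hz.id, hz.fixed_food_group] = 1.0
    return AttributionMatrix(proportions=p, deaths=m.deaths)


def restrict_food_groups(
    m: AttributionMatrix, excluded: Iterable[str]
) -> AttributionMatrix:
    """Drop rarely-consumed food groups and renormalize the rows."""
    excluded = set(excluded)
    unknown = excluded - set(m.proportions.columns)
    if unknown:
        raise AttributionError(f"excluded groups not in matrix: {sorted(unknown)}")
    if excluded >= set(m.proportions.columns):
        raise AttributionError("cannot exclude every food group")
    p = m.proportions.drop(columns=sorted(excluded))
    row_sums = p.sum(axis=1)
    dead = row_sums[row_sums <= 0]
    if len(dead):
        raise AttributionError(
            f"rows lose all mass under exclusion: {list(dead.index)}"
        )
    return AttributionMatrix(proportions=p.div(row_sums, axis=0), deaths=m.deaths)


def attribute_deaths(m: AttributionMatrix) -> AttributedDeaths:
    """Convert proportions to death counts: deaths[h, g] = total[h] * p[h, g]."""
    if m.deaths is None:
        raise AttributionError("attribution matrix carries no death totals")
    deaths = m.proportions.mul(m.deaths, axis=0)
    return AttributedDeaths(deaths=deaths)


def aggregate_by_category(
    a: AttributedDeaths, registry: Iterable[Hazard]
) -> pd.DataFrame:
    """Sum attributed deaths into a food-group x ecology-category table.

    Rows are food groups, columns the three hazard-ecology categories
    (anthroponotic, zoonotic, chemical) plus a ``total`` column.  Every
    hazard in the deaths table must have an assigned ecology.
    """
    index = {hz.id: hz for hz in registry}
    cats = ("anthroponotic", "zoonotic", "chemical")
    out = pd.DataFrame(
        0.0, index=a.deaths.columns, columns=list(cats)
    )
    for hz_id, row in a.deaths.iterrows():
        hz = index.get(hz_id)
        if hz is None:
            raise AttributionError(f"hazard {hz_id!r} absent from registry")
        if hz.ecology not in cats:
            raise AttributionError(
                f"hazard {hz_id!r} has ecology {hz.ecology!r}; prioritization "
                "requires anthroponotic, zoonotic or chemical"
            )
        out[hz.ecology] += row
    out["total"] = out.sum(axis=1)
    out.index.name = "food_group"
    return out


def bootstrap_attribution(
    responses: Sequence[ExpertResponse],
    n_boot: int = 1000,
    seed: int = 0,
    **aggregate_kwargs,
) -> dict[str, pd.DataFrame]:
    """Percentile intervals on the aggregate by resampling experts.

    Experts are resampled with replacement ``n_boot`` times; returns
    ``{"lower95": ..., "upper95": ...}`` DataFrames aligned to the point
    aggregate.
    """
    point = delphi_aggregate(responses, **aggregate_kwargs)
    experts = sorted({r.expert_id for r in responses})
    by_expert = {e: [r for r in responses if r.expert_id == e] for e in experts}
    rng = np.random.default_rng(seed)
    stack = []
    for _ in range(n_boot):
        chosen = rng.choice(experts, size=len(experts), replace=True)
        resampled: list[ExpertResponse] = []
        for j, e in enumerate(chosen):
            # clone under a fresh id so duplicates count as distinct experts
            for r in by_expert[e]:
                resampled.append(replace(r, expert_id=f"boot{j}"))
        agg = delphi_aggregate(resampled, **aggregate_kwargs)
        stack.append(
            agg.proportions.reindex(
                index=point.proportions.index, columns=point.proportions.columns
            ).fillna(0.0)
        )
    cube = np.stack([f.to_numpy() for f in stack])
    lo = pd.DataFrame(np.quantile(cube, 0.025, axis=0),
                      index=point.proportions.index,
                      columns=point.proportions.columns)
    hi = pd.DataFrame(np.quantile(cube, 0.975, axis=0),
                      index=point.proportions.index,
                      columns=point.proportions.columns)
    return {"lower95": lo, "upper95": hi}
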