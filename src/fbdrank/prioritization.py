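"""Preventable-deaths scoring of supply-chain control points.

For each food value chain, stakeholders allocate points to supply-chain
control points (SCCPs) — places where an action can prevent, reduce or
eliminate contamination — separately per hazard-ecology category
(anthroponotic, zoonotic, chemical).  The preventable deaths credited to an
SCCP are its share of the category's points times the chain's attributable
deaths in that category:

    value[s, c] = points[s, c] / sum_s' points[s', c] * chain_deaths[c]

so per-category point rescaling changes nothing and deaths are conserved at
every aggregation level.  Chains may merge food groups (eggs into poultry,
small-ruminant meat into beef), and the results serialize as a nested
chain -> stage -> SCCP -> category hierarchy for sunburst plotting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import PrioritizationError

CATEGORIES = ("anthroponotic", "zoonotic", "chemical")


@dataclass(frozen=True)
class SCCP:
    sccp_id: str
    stage: str
    description: str = ""


@dataclass(frozen=True)
class ValueChain:
    """A food value chain: member food groups, ordered stages, SCCPs."""

    chain_id: str
    food_groups: tuple[str, ...]
    stages: tuple[str, ...]
    sccps: tuple[SCCP, ...]

    def __post_init__(self) -> None:
        if not self.food_groups:
            raise PrioritizationError(
                f"chain {self.chain_id!r} covers no food groups"
            )
        stage_set = set(self.stages)
        for s in self.sccps:
            if s.stage not in stage_set:
                raise PrioritizationError(
                    f"chain {self.chain_id!r}: SCCP {s.sccp_id!r} references "
                    f"unknown stage {s.stage!r}"
                )
        ids = [s.sccp_id for s in self.sccps]
        if len(ids) != len(set(ids)):
            raise PrioritizationError(f"chain {self.chain_id!r}: duplicate SCCP ids")

    @property
    def sccp_ids(self) -> list[str]:
        return [s.sccp_id for s in self.sccps]


@dataclass(frozen=True)
class PointAllocation:
    """Stakeholder point weights per (SCCP, hazard category)."""

    chain_id: str
    points: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (sccp, cat), v in self.points.items():
            if v < 0:
                raise PrioritizationError(
                    f"negative points for ({sccp!r}, {cat!r})"
                )

    def category_total(self, category: str, sccp_ids: Sequence[str]) -> float:
        return sum(self.points.get((s, category), 0.0) for s in sccp_ids)


@dataclass(frozen=True)
class PreventableDeaths:
    """Preventable deaths per (SCCP, category) with conserved totals."""

    chain_id: str
    values: Mapping[tuple[str, str], float]
    sccp_order: tuple[str, ...]

    def sccp_total(self, sccp_id: str) -> float:
        return sum(v for (s, _), v in self.values.items() if s == sccp_id)

    def category_total(self, category: str) -> float:
        return sum(v for (_, c), v in self.values.items() if c == category)

    @property
    def total(self) -> float:
        return sum(self.values.values())


def merge_food_groups(
    category_table: pd.DataFrame, chains: Sequence[ValueChain], top_k: int | None = None
) -> pd.DataFrame:
    """Collapse the food-group x category table onto value chains.

    Each chain's row is the element-wise sum over its member food groups
    (e.g. poultry + eggs).  Every member group must exist in the table.
    """
    import warnings

    rows = {}
    claimed: set[str] = set()
    for chain in chains:
        missing = [g for g in chain.food_groups if g not in category_table.index]
        if missing:
            raise PrioritizationError(
                f"chain {chain.chain_id!r}: food groups {missing} absent from table"
            )
        rows[chain.chain_id] = category_table.loc[list(chain.food_groups)].sum(axis=0)
        claimed.update(chain.food_groups)
    unclaimed = set(category_table.index) - claimed
    if unclaimed and (top_k is None or top_k >= len(chains)):
        warnings.warn(
            f"food groups not claimed by any chain: {sorted(unclaimed)}",
            stacklevel=2,
        )
    out = pd.DataFrame(rows).T
    out.index.name = "chain_id"
    return out


def select_top_chains(
    chain_table: pd.DataFrame, chains: Sequence[ValueChain], k: int
) -> list[ValueChain]:
    """Pick the k chains with the largest total attributable deaths.

    Descending by total; ties keep the chains' input order (stable sort).
    """
    if k > len(chains):
        raise PrioritizationError(f"k={k} exceeds number of chains {len(chains)}")
    totals = chain_table["total"] if "total" in chain_table.columns \
        else chain_table.sum(axis=1)
    order = sorted(
        range(len(chains)),
        key=lambda i: -float(totals[chains[i].chain_id]),
    )
    return [chains[i] for i in order[:k]]


def preventable_deaths(
    chain: ValueChain,
    alloc: PointAllocation,
    chain_deaths: Mapping[str, float],
    categories: Sequence[str] = CATEGORIES,
) -> PreventableDeaths:
    """Distribute each category's chain deaths over SCCPs by point share."""
    if alloc.chain_id != chain.chain_id:
        raise PrioritizationError(
            f"allocation for {alloc.chain_id!r} applied to chain {chain.chain_id!r}"
        )
    for (sccp_id, _cat) in alloc.points:
        if sccp_id not in chain.sccp_ids:
            raise PrioritizationError(
                f"allocation references unknown SCCP {sccp_id!r}"
            )
    values: dict[tuple[str, str], float] = {}
    for cat in categories:
        deaths = float(chain_deaths.get(cat, 0.0))
        if deaths < 0:
            raise PrioritizationError(f"negative deaths for category {cat!r}")
        total_points = alloc.category_total(cat, chain.sccp_ids)
        if total_points <= 0:
            if deaths > 0:
                raise PrioritizationError(
                    f"chain {chain.chain_id!r}: category {cat!r} has "
                    f"{deaths} attributable deaths but zero allocated points"
                )
            for s in chain.sccp_ids:
                values[(s, cat)] = 0.0
            continue
        for s in chain.sccp_ids:
            share = alloc.points.get((s, cat), 0.0) / total_points
            values[(s, cat)] = share * deaths
    return PreventableDeaths(
        chain_id=chain.chain_id, values=values, sccp_order=tuple(chain.sccp_ids)
    )


def rank_sccps(p: PreventableDeaths) -> list[tuple[str, float]]:
    """SCCPs by total preventable deaths, descending, stable on ties."""
    totals = [(s, p.sccp_total(s)) for s in p.sccp_order]
    return sorted(totals, key=lambda t: -t[1])


def sunburst_hierarchy(chain: ValueChain, p: PreventableDeaths) -> dict:
    """Nested chain -> stage -> SCCP -> category tree with conserved values.

    Leaf values are the per-(SCCP, category) preventable deaths; every
    internal node's value is the sum of its children.  The returned dict is
    JSON-serializable as name/value/children records.
    """
    if p.chain_id != chain.chain_id:
        raise PrioritizationError("preventable deaths belong to a different chain")
    known = set(chain.sccp_ids)
    orphans = {s for (s, _) in p.values if s not in known}
    if orphans:
        raise PrioritizationError(f"orphan SCCPs in values: {sorted(orphans)}")

    stage_nodes = []
    for stage in chain.stages:
        sccp_nodes = []
        for sccp in chain.sccps:
            if sccp.stage != stage:
                continue
            leaves = []
            for cat in CATEGORIES:
                v = p.values.get((sccp.sccp_id, cat), 0.0)
                leaves.append({"name": cat, "value": v})
            sccp_nodes.append({
                "name": sccp.sccp_id,
                "value": sum(l["value"] for l in leaves),
                "children": leaves,
            })
        if sccp_nodes:
            stage_nodes.append({
                "name": stage,
                "value": sum(n["value"] for n in sccp_nodes),
                "children": sccp_nodes,
            })
    return {
        "name": chain.chain_id,
        "value": sum(n["value"] for n in stage_nodes),
        "children": stage_nodes,
    }


def write_sunburst(tree: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree, indent=2, sort_keys=False) + "\n")


def read_sunburst(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
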