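"""Readers, writers and pipeline configuration.

All tabular interchange uses UTF-8 comma-separated files with a header row
and "." decimals, so outputs are diffable and bit-reproducible.  Files
written by the pipeline carry the run's configuration hash in a leading
``#`` comment line; all readers here skip ``#`` comments.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .attribution import AttributedDeaths, ExpertResponse
from .burden import BurdenRecord
from .errors import ParseError, ValidationError
from .prioritization import SCCP, PointAllocation, ValueChain
from .ranking import GroupRound, RankCategory
from .uncertainty import DEFAULT_N_SIMS, DEFAULT_SEED, UncertainQuantity


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return frame


# -- group rankings ---------------------------------------------------------

RANKINGS_COLUMNS = ["group_id", "round", "assigned_metric", "hazard_id", "category"]


def read_rankings_csv(path: str | Path) -> list[GroupRound]:
    frame = _read_csv(path, RANKINGS_COLUMNS)
    rounds: list[GroupRound] = []
    for (group_id, round_no), block in frame.groupby(["group_id", "round"], sort=True):
        metrics = block["assigned_metric"].unique()
        if len(metrics) != 1:
            raise ParseError(
                f"{path}: group {group_id!r} round {round_no} has mixed "
                f"assigned metrics {list(metrics)}"
            )
        ranks = {}
        for _, row in block.iterrows():
            hz = str(row["hazard_id"])
            if hz in ranks:
                raise ParseError(
                    f"{path}: hazard {hz!r} ranked twice by group "
                    f"{group_id!r} round {round_no}"
                )
            ranks[hz] = RankCategory.parse(row["category"])
        rounds.append(GroupRound(
            group_id=str(group_id), round=int(round_no),
            assigned_metric=str(metrics[0]), ranks=ranks,
        ))
    return rounds


def write_rankings_csv(rounds: Sequence[GroupRound], path: str | Path,
                       header_comment: str | None = None) -> None:
    rows = []
    for gr in rounds:
        for hz, cat in gr.ranks.items():
            rows.append({
                "group_id": gr.group_id, "round": gr.round,
                "assigned_metric": gr.assigned_metric,
                "hazard_id": hz, "category": cat.label,
            })
    _write_frame(pd.DataFrame(rows, columns=RANKINGS_COLUMNS), path, header_comment)


def read_votes_csv(path: str | Path) -> dict[str, list[RankCategory]]:
    """Plenary votes: columns hazard_id, category, votes (a count)."""
    frame = _read_csv(path, ["hazard_id", "category", "votes"])
    votes: dict[str, list[RankCategory]] = {}
    for _, row in frame.iterrows():
        n = int(row["votes"])
        if n < 0:
            raise ParseError(f"{path}: negative vote count for {row['hazard_id']!r}")
        cat = RankCategory.parse(row["category"])
        votes.setdefault(str(row["hazard_id"]), []).extend([cat] * n)
    return votes


# -- expert responses -------------------------------------------------------

RESPONSES_COLUMNS = ["expert_id", "round", "hazard_id", "food_group", "value"]


def read_responses_csv(path: str | Path) -> list[ExpertResponse]:
    frame = _read_csv(path, RESPONSES_COLUMNS)
    out: list[ExpertResponse] = []
    keys = ["expert_id", "round", "hazard_id"]
    for (expert_id, round_no, hazard_id), block in frame.groupby(keys, sort=True):
        proportions = dict(zip(block["food_group"].astype(str), block["value"].astype(float)))
        out.append(ExpertResponse(
            expert_id=str(expert_id), round=int(round_no),
            hazard_id=str(hazard_id), proportions=proportions,
        ))
    return out


def write_responses_csv(responses: Sequence[ExpertResponse], path: str | Path,
                        header_comment: str | None = None) -> None:
    rows = [
        {"expert_id": r.expert_id, "round": r.round, "hazard_id": r.hazard_id,
         "food_group": g, "value": v}
        for r in responses for g, v in r.proportions.items()
    ]
    _write_frame(pd.DataFrame(rows, columns=RESPONSES_COLUMNS), path, header_comment)


# -- attributed deaths ------------------------------------------------------


def read_attributed_deaths_csv(path: str | Path) -> AttributedDeaths:
    frame = _read_csv(path, ["hazard_id", "food_group", "deaths"])
    if (frame["deaths"].astype(float) < 0).any():
        raise ParseError(f"{path}: negative death counts")
    wide = frame.pivot_table(
        index="hazard_id", columns="food_group", values="deaths",
        aggfunc="sum", fill_value=0.0,
    )
    wide.index.name = None
    wide.columns.name = None
    return AttributedDeaths(deaths=wide)


def write_attributed_deaths_csv(a: AttributedDeaths, path: str | Path,
                                header_comment: str | None = None) -> None:
    long = a.deaths.stack().rename("deaths").reset_index()
    long.columns = ["hazard_id", "food_group", "deaths"]
    _write_frame(long, path, header_comment)


def read_attribution_matrix_csv(path: str | Path) -> "pd.DataFrame":
    """A finished attribution matrix: hazard_id column + one column per
    food group; rows must sum to one."""
    frame = _read_csv(path, ["hazard_id"])
    wide = frame.set_index("hazard_id").astype(float)
    wide.index.name = None
    sums = wide.sum(axis=1)
    off = sums[(sums - 1).abs() > 1e-6]
    if len(off):
        raise ParseError(
            f"{path}: attribution rows not summing to 1: "
            f"{dict(off.round(6))}"
        )
    return wide


def read_hazard_deaths_csv(path: str | Path) -> pd.Series:
    frame = _read_csv(path, ["hazard_id", "deaths"])
    s = frame.set_index("hazard_id")["deaths"].astype(float)
    if (s < 0).any():
        raise ParseError(f"{path}: negative death totals")
    return s


# -- elicited burden inputs -------------------------------------------------

BURDEN_QUANTITIES = ("cases", "deaths", "disability_weight",
                     "duration_years", "residual_life_expectancy_years")


def read_burden_inputs_csv(
    path: str | Path, population: int, reference_year: int = 2010
) -> list[BurdenRecord]:
    """Elicited triples, one row per hazard x quantity.

    Columns: hazard_id, quantity, best, lower95, upper95, support[, units].
    Rows for the same hazard and quantity are summed over outcomes
    (multiple outcome rows per hazard are allowed for extensibility).
    """
    frame = _read_csv(path, ["hazard_id", "quantity", "best", "lower95",
                             "upper95", "support"])
    records: list[BurdenRecord] = []
    for hazard_id, block in frame.groupby("hazard_id", sort=False):
        quantities: dict[str, UncertainQuantity] = {}
        for qty, rows in block.groupby("quantity", sort=False):
            if qty not in BURDEN_QUANTITIES:
                raise ParseError(f"{path}: unknown quantity {qty!r}")
            supports = rows["support"].unique()
            if len(supports) != 1:
                raise ParseError(f"{path}: mixed support for {hazard_id}/{qty}")
            agg = rows[["best", "lower95", "upper95"]].astype(float).sum()
            try:
                quantities[str(qty)] = UncertainQuantity(
                    best=agg["best"], lower95=agg["lower95"],
                    upper95=agg["upper95"], support=str(supports[0]),
                )
            except ValidationError as exc:
                raise ParseError(f"{path}: {hazard_id}/{qty}: {exc}") from exc
        missing = [q for q in BURDEN_QUANTITIES if q not in quantities]
        if missing:
            raise ParseError(f"{path}: hazard {hazard_id!r} missing {missing}")
        records.append(BurdenRecord(
            hazard_id=str(hazard_id),
            cases=quantities["cases"],
            deaths=quantities["deaths"],
            disability_weight=quantities["disability_weight"],
            duration_years=quantities["duration_years"],
            residual_life_expectancy_years=quantities["residual_life_expectancy_years"],
            population=population,
            reference_year=reference_year,
        ))
    return records


def read_metrics_wide(path: str | Path, value: str = "best") -> pd.DataFrame:
    """Pivot a long metrics table (hazard_id, metric, best/mean, ...) wide."""
    frame = _read_csv(path, ["hazard_id", "metric"])
    if value not in frame.columns:
        raise ParseError(f"{path}: no {value!r} column")
    wide = frame.pivot(index="hazard_id", columns="metric", values=value)
    wide.index.name = None
    wide.columns.name = None
    return wide.astype(float)


# -- value chains -----------------------------------------------------------


def read_chains_yaml(
    path: str | Path,
) -> tuple[list[ValueChain], dict[str, PointAllocation]]:
    """Chain configuration: stages, SCCPs and point allocations.

    Points may be given per category (mapping) or as a single number that
    is replicated across the three categories.
    """
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except Exception as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if not isinstance(doc, dict) or "chains" not in doc:
        raise ParseError(f"{path}: expected a top-level 'chains' list")
    from .prioritization import CATEGORIES

    chains: list[ValueChain] = []
    allocations: dict[str, PointAllocation] = {}
    for entry in doc["chains"]:
        sccps = tuple(
            SCCP(sccp_id=str(s["id"]), stage=str(s["stage"]),
                 description=str(s.get("description", "")))
            for s in entry.get("sccps", [])
        )
        chain = ValueChain(
            chain_id=str(entry["chain_id"]),
            food_groups=tuple(entry.get("food_groups", [])),
            stages=tuple(entry.get("stages", [])),
            sccps=sccps,
        )
        chains.append(chain)
        points: dict[tuple[str, str], float] = {}
        for sccp_id, val in (entry.get("points") or {}).items():
            if isinstance(val, Mapping):
                for cat, v in val.items():
                    points[(str(sccp_id), str(cat))] = float(v)
            else:  # single weight replicated across categories
                for cat in CATEGORIES:
                    points[(str(sccp_id), cat)] = float(val)
        if points:
            allocations[chain.chain_id] = PointAllocation(
                chain_id=chain.chain_id, points=points
            )
    return chains, allocations


# -- configuration ----------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything a deterministic pipeline run needs."""

    population: int = 87_640_000
    reference_year: int = 2010
    n_sims: int = DEFAULT_N_SIMS
    seed: int = DEFAULT_SEED
    metrics: tuple[str, ...] = (
        "incidence_rate", "mortality_rate", "case_fatality_pct", "daly_rate",
    )
    consensus_tie: str = "medium"  # Low/Medium settle tie
    plenary_tie_high: bool = True
    aggregator: str = "mean"
    excluded_food_groups: tuple[str, ...] = ()
    bootstrap_reps: int = 0
    top_k_chains: int = 4
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValidationError("population must be positive")
        if self.n_sims < 1:
            raise ValidationError("n_sims must be >= 1")
        if self.n_sims < 1000:
            import warnings

            warnings.warn(
                f"n_sims={self.n_sims} below 1000: interval outputs will be "
                "noisy", stacklevel=2,
            )

    def path(self, key: str, base: Path | None = None) -> Path | None:
        raw = self.inputs.get(key)
        if raw is None:
            return None
        p = Path(raw)
        if not p.is_absolute() and base is not None:
            p = base / p
        return p

    def to_dict(self) -> dict:
        return {
            "population": self.population,
            "reference_year": self.reference_year,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "metrics": list(self.metrics),
            "consensus_tie": self.consensus_tie,
            "plenary_tie_high": self.plenary_tie_high,
            "aggregator": self.aggregator,
            "excluded_food_groups": list(self.excluded_food_groups),
            "bootstrap_reps": self.bootstrap_reps,
            "top_k_chains": self.top_k_chains,
            "inputs": {k: str(v) for k, v in self.inputs.items()},
        }


def load_config(path: str | Path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    for tup_key in ("metrics", "excluded_food_groups"):
        if tup_key in doc and doc[tup_key] is not None:
            doc[tup_key] = tuple(doc[tup_key])
    return PipelineConfig(**doc)


def config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _write_frame(frame: pd.DataFrame, path: str | Path,
                 header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)


def write_table(frame: pd.DataFrame, path: str | Path, cfg_hash: str,
                index: bool = False) -> None:
    """Write a pipeline output CSV stamped with the config hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        frame.to_csv(fh, index=index)
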