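"""Synthetic scenario generators with known ground truth.

The study's raw elicitation data (workshop score sheets, Delphi responses,
SCCP point sheets) are not public, so every pipeline stage is exercised on
generated inputs whose truth is known, enabling parameter-recovery tests:

* burden panels — true per-hazard rates drawn log-uniform over the orders
  of magnitude real burden tables span (incidence 1e-3 to 1e3 per 100k),
  elicited as multiplicative-spread triples (truth/f, truth, truth*f) that
  the lognormal fit represents exactly;
* Delphi panels — expert rows drawn Dirichlet(concentration * truth_row),
  with a subset of experts revising toward the truth in round 2
  (concentration x4), emulating a 15-expert / 3-reviser panel;
* group rankings — each group thresholds its assigned metric against the
  true cutpoints, with optional neighbor-flip label noise;
* SCCP scenarios — random chains and point allocations with the expected
  preventable deaths computed by an independent plain-loop oracle.

Defaults mirror the Ethiopia case: 37 hazards, 4 ranking groups, 15
experts, population 87.64 million, reference year 2010.  Every generator is
a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .burden import BurdenRecord
from .errors import ValidationError
from .prioritization import SCCP, PointAllocation, PreventableDeaths, ValueChain
from .ranking import GroupRound, RankCategory
from .attribution import ExpertResponse
from .uncertainty import UncertainQuantity

ETHIOPIA_POPULATION = 87_640_000
REFERENCE_YEAR = 2010

DEFAULT_N_HAZARDS = 37
DEFAULT_N_GROUPS = 4
DEFAULT_N_EXPERTS = 15
DEFAULT_N_REVISING = 3


@dataclass
class ScenarioTruth:
    """Ground-truth parameters behind a generated scenario."""

    burden: pd.DataFrame  # per-hazard true cases, deaths, dw, duration, rle
    attribution: pd.DataFrame | None = None  # hazards x food groups, rows sum 1
    rank_thresholds: tuple[float, ...] = ()  # strictly increasing cutpoints
    rank_metric: str = "mortality_rate"
    sccp_shares: pd.DataFrame | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attribution is not None:
            sums = self.attribution.sum(axis=1)
            if ((sums - 1).abs() > 1e-9).any():
                raise ValidationError("truth attribution rows must sum to 1")
        if list(self.rank_thresholds) != sorted(set(self.rank_thresholds)):
            raise ValidationError("rank thresholds must be strictly increasing")


def generate_hazard_panel(
    n_hazards: int = DEFAULT_N_HAZARDS,
    seed: int = 0,
    spread: tuple[float, float] = (2.0, 8.0),
    population: int = ETHIOPIA_POPULATION,
) -> tuple[ScenarioTruth, list[BurdenRecord]]:
    """Generate true burden parameters and their elicited triples.

    True incidence rates are log-uniform on [1e-3, 1e3] per 100k; deaths
    follow from a per-hazard case-fatality fraction.  Elicited triples are
    (truth/f, truth, truth*f) with the spread factor f drawn uniformly from
    ``spread`` — log-symmetric, hence exactly representable by the
    lognormal fit.  ``spread=(1, 1)`` yields point-mass elicitations.
    """
    if n_hazards < 3:
        raise ValidationError("need at least 3 hazards")
    f_lo, f_hi = spread
    if not (1.0 <= f_lo <= f_hi):
        raise ValidationError(f"invalid spread {spread}; factors must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"hz{i:02d}" for i in range(n_hazards)]

    inc_rate = 10 ** rng.uniform(-3, 3, n_hazards)  # per 100k
    cases = inc_rate * population / 1e5
    cfr = 10 ** rng.uniform(-4, -1, n_hazards)  # fraction of cases fatal
    deaths = cases * cfr
    dw = rng.uniform(0.05, 0.5, n_hazards)
    duration = 10 ** rng.uniform(-2, 0, n_hazards)  # 3.65 days .. 1 year
    rle = rng.uniform(30, 70, n_hazards)

    truth = pd.DataFrame({
        "cases": cases, "deaths": deaths, "dw": dw,
        "duration": duration, "rle": rle,
    }, index=pd.Index(ids, name="hazard_id"))

    records = []
    factors = rng.uniform(f_lo, f_hi, n_hazards)
    for i, hid in enumerate(ids):
        f = factors[i]

        def elicit(x: float, support: str = "nonnegative_real") -> UncertainQuantity:
            if f == 1.0:
                return UncertainQuantity.point(x, support)
            hi = min(x * f, 1.0) if support == "proportion" else x * f
            return UncertainQuantity(x, x / f, hi, support)

        records.append(BurdenRecord(
            hazard_id=hid,
            cases=elicit(cases[i]),
            deaths=elicit(deaths[i]),
            disability_weight=elicit(dw[i], "proportion"),
            duration_years=elicit(duration[i]),
            residual_life_expectancy_years=elicit(rle[i]),
            population=population,
            reference_year=REFERENCE_YEAR,
        ))
    return ScenarioTruth(burden=truth, seed=seed), records


def generate_expert_panel(
    truth: pd.DataFrame,
    n_experts: int = DEFAULT_N_EXPERTS,
    concentration: float = 100.0,
    seed: int = 0,
    n_revising: int = DEFAULT_N_REVISING,
) -> list[ExpertResponse]:
    """Simulate a two-round Delphi panel around a true attribution matrix.

    Each expert's row-1 answer is Dirichlet(concentration * truth_row); the
    first ``n_revising`` experts submit round-2 revisions drawn at four
    times the concentration (closer to truth).  ``concentration=inf``
    returns the truth exactly (noise-free panel).
    """
    if concentration <= 0:
        raise ValidationError("concentration must be positive")
    if (truth.sum(axis=1) <= 0).any():
        raise ValidationError("truth matrix has a zero row")
    rng = np.random.default_rng(seed)
    groups = list(truth.columns)
    responses: list[ExpertResponse] = []

    def draw(row: np.ndarray, conc: float) -> np.ndarray:
        if not np.isfinite(conc):
            return row.copy()
        # zero-truth groups stay zero: Dirichlet over the positive support
        pos = row > 0
        out = np.zeros_like(row)
        out[pos] = rng.dirichlet(conc * row[pos])
        return out

    for e in range(n_experts):
        for hz, row in truth.iterrows():
            vec = draw(row.to_numpy(float), concentration)
            responses.append(ExpertResponse(
                expert_id=f"expert{e:02d}", round=1, hazard_id=str(hz),
                proportions=dict(zip(groups, vec)),
            ))
    for e in range(min(n_revising, n_experts)):
        for hz, row in truth.iterrows():
            vec = draw(row.to_numpy(float), concentration * 4)
            responses.append(ExpertResponse(
                expert_id=f"expert{e:02d}", round=2, hazard_id=str(hz),
                proportions=dict(zip(groups, vec)),
            ))
    return responses


def generate_attribution_truth(
    hazard_ids: list[str],
    food_groups: list[str],
    seed: int = 0,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Random true attribution matrix: rows ~ Dirichlet(alpha)."""
    rng = np.random.default_rng(seed)
    rows = rng.dirichlet(np.full(len(food_groups), alpha), size=len(hazard_ids))
    return pd.DataFrame(rows, index=pd.Index(hazard_ids, name="hazard_id"),
                        columns=food_groups)


def generate_group_rankings(
    metric_table: pd.DataFrame,
    thresholds: tuple[float, float],
    flip_prob: float = 0.0,
    n_groups: int = DEFAULT_N_GROUPS,
    seed: int = 0,
    assigned_metrics: list[str] | None = None,
) -> list[GroupRound]:
    """Threshold-based group rankings with optional label noise.

    Each group categorizes every hazard by thresholding its assigned metric
    column against the true cutpoints (below t1 -> Low, above t2 -> High),
    then flips each label to a neighboring category with ``flip_prob``.
    Round 2 repeats the same labels (groups confirm their view) so that
    zero-noise scenarios resolve in round 1.  By default group g is
    assigned metric column g mod n_columns; pass ``assigned_metrics`` to
    control this (e.g. the same metric for every group).
    """
    if n_groups < 2:
        raise ValidationError("need at least 2 groups")
    t1, t2 = thresholds
    if not t1 < t2:
        raise ValidationError("thresholds must be strictly increasing")
    rng = np.random.default_rng(seed)
    cols = list(metric_table.columns)
    if assigned_metrics is None:
        assigned_metrics = [cols[g % len(cols)] for g in range(n_groups)]
    rounds: list[GroupRound] = []
    for g in range(n_groups):
        metric = assigned_metrics[g]
        ranks: dict[str, RankCategory] = {}
        for hz, value in metric_table[metric].items():
            if value < t1:
                cat = RankCategory.LOW
            elif value < t2:
                cat = RankCategory.MEDIUM
            else:
                cat = RankCategory.HIGH
            if flip_prob > 0 and rng.random() < flip_prob:
                neighbors = {
                    RankCategory.LOW: [RankCategory.MEDIUM],
                    RankCategory.MEDIUM: [RankCategory.LOW, RankCategory.HIGH],
                    RankCategory.HIGH: [RankCategory.MEDIUM],
                }[cat]
                cat = neighbors[rng.integers(len(neighbors))]
            ranks[str(hz)] = cat
        for round_no, assigned in ((1, metric), (2, "free")):
            rounds.append(GroupRound(
                group_id=f"group{g + 1}", round=round_no,
                assigned_metric=assigned, ranks=dict(ranks),
            ))
    return rounds


def preventable_deaths_oracle(
    chain: ValueChain,
    alloc: PointAllocation,
    chain_deaths: dict[str, float],
    categories: tuple[str, ...],
) -> dict[tuple[str, str], float]:
    """Straightforward independent loop computing expected values.

    Kept deliberately naive (explicit sums, no shared code with the
    production implementation) so it can serve as an oracle in tests.
    """
    expected: dict[tuple[str, str], float] = {}
    for cat in categories:
        total = 0.0
        for s in chain.sccp_ids:
            total += alloc.points.get((s, cat), 0.0)
        for s in chain.sccp_ids:
            pts = alloc.points.get((s, cat), 0.0)
            deaths = chain_deaths.get(cat, 0.0)
            expected[(s, cat)] = (pts / total) * deaths if total > 0 else 0.0
    return expected


def generate_sccp_scenario(
    n_stages: int = 4,
    n_sccps: int = 8,
    categories: tuple[str, ...] = ("anthroponotic", "zoonotic", "chemical"),
    chain_deaths: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[ValueChain, PointAllocation, dict[tuple[str, str], float]]:
    """Random value chain, point allocation, and oracle-expected values."""
    if n_sccps < n_stages:
        raise ValidationError("need at least one SCCP per stage")
    rng = np.random.default_rng(seed)
    if chain_deaths is None:
        chain_deaths = {c: float(rng.integers(100, 2000)) for c in categories}
    stages = tuple(f"stage{i + 1}" for i in range(n_stages))
    # every stage gets one SCCP; the rest are spread at random
    assignment = list(stages) + [
        stages[rng.integers(n_stages)] for _ in range(n_sccps - n_stages)
    ]
    sccps = tuple(
        SCCP(sccp_id=f"sccp{i + 1}", stage=assignment[i], description="synthetic")
        for i in range(n_sccps)
    )
    chain = ValueChain(
        chain_id="synthetic_chain", food_groups=("synthetic_group",),
        stages=stages, sccps=sccps,
    )
    points = {
        (s.sccp_id, c): float(rng.uniform(0.5, 10.0))
        for s in sccps for c in categories
    }
    alloc = PointAllocation(chain_id=chain.chain_id, points=points)
    expected = preventable_deaths_oracle(chain, alloc, chain_deaths, categories)
    return chain, alloc, expected


DEFAULT_FOOD_GROUPS = [
    "vegetables", "dairy", "poultry", "eggs", "beef", "small_ruminant_meat",
]


def metric_table_from_truth(truth: pd.DataFrame, population: int) -> pd.DataFrame:
    """Point risk metrics (per 100k, CFR in %) implied by true parameters."""
    per = 1e5 / population
    yll = truth["deaths"] * truth["rle"]
    yld = truth["cases"] * truth["dw"] * truth["duration"]
    return pd.DataFrame({
        "incidence_rate": truth["cases"] * per,
        "mortality_rate": truth["deaths"] * per,
        "case_fatality_pct": 100.0 * truth["deaths"] / truth["cases"],
        "daly_rate": (yll + yld) * per,
    }, index=truth.index)


def write_scenario(
    out_dir,
    seed: int = 0,
    n_hazards: int = DEFAULT_N_HAZARDS,
    n_groups: int = DEFAULT_N_GROUPS,
    n_experts: int = DEFAULT_N_EXPERTS,
    n_revising: int = DEFAULT_N_REVISING,
    flip_prob: float = 0.0,
    concentration: float = 100.0,
    spread: tuple[float, float] = (2.0, 8.0),
    population: int = ETHIOPIA_POPULATION,
) -> "Path":
    """Write a complete, self-consistent scenario directory.

    Emits every pipeline input (registry, elicited burden triples, group
    rankings, plenary votes, expert responses, hazard death totals, chain
    configuration, run config) plus ``truth.json`` recording the generating
    parameters, so a pipeline run on the directory can be checked against
    ground truth.
    """
    import json as _json
    from pathlib import Path

    import yaml as _yaml

    from . import io as fio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.SeedSequence(seed).spawn(4)
    s_panel, s_rank, s_attr, s_chain = (
        int(s.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF) for s in rng_seeds
    )

    truth, records = generate_hazard_panel(
        n_hazards, seed=s_panel, spread=spread, population=population
    )
    burden_truth = truth.burden
    ids = list(burden_truth.index)

    # registry: all foodborne, ecology cycling through the three categories
    ecologies = ["anthroponotic", "zoonotic", "chemical"]
    reg_rows = []
    for i, hid in enumerate(ids):
        reg_rows.append({
            "id": hid, "name": hid, "hazard_class": "bacterium",
            "origin": "FERG", "foodborne": True,
            "is_toxin_producer_only": False, "ecology": ecologies[i % 3],
            "fixed_food_group": "",
        })
    pd.DataFrame(reg_rows).to_csv(out / "registry.csv", index=False)

    burden_rows = []
    for r in records:
        for qty, uq in (
            ("cases", r.cases), ("deaths", r.deaths),
            ("disability_weight", r.disability_weight),
            ("duration_years", r.duration_years),
            ("residual_life_expectancy_years", r.residual_life_expectancy_years),
        ):
            burden_rows.append({
                "hazard_id": r.hazard_id, "quantity": qty, "best": uq.best,
                "lower95": uq.lower95, "upper95": uq.upper95,
                "support": uq.support, "units": "",
            })
    pd.DataFrame(burden_rows).to_csv(out / "burden_inputs.csv", index=False)

    metrics = metric_table_from_truth(burden_truth, population)
    rank_truth, thresholds = generate_rank_truth(metrics, "mortality_rate")
    # all groups threshold the truth metric so zero noise is round-1 unanimous
    rounds = generate_group_rankings(
        metrics, thresholds, flip_prob=flip_prob, n_groups=n_groups,
        seed=s_rank, assigned_metrics=["mortality_rate"] * n_groups,
    )
    fio.write_rankings_csv(rounds, out / "group_rankings.csv")
    votes = pd.DataFrame([
        {"hazard_id": hz, "category": cat.label, "votes": 11}
        for hz, cat in rank_truth.items()
    ])
    votes.to_csv(out / "plenary_votes.csv", index=False)
    metrics.rename_axis("hazard_id").reset_index().melt(
        id_vars="hazard_id", var_name="metric", value_name="best"
    ).to_csv(out / "metrics_table.csv", index=False)

    high = [hz for hz, cat in rank_truth.items() if cat == RankCategory.HIGH]
    attr_hazards = high if len(high) >= 2 else ids[:3]
    attr_truth = generate_attribution_truth(
        attr_hazards, DEFAULT_FOOD_GROUPS, seed=s_attr
    )
    responses = generate_expert_panel(
        attr_truth, n_experts=n_experts, concentration=concentration,
        seed=s_attr, n_revising=n_revising,
    )
    fio.write_responses_csv(responses, out / "responses.csv")
    burden_truth.loc[attr_hazards, "deaths"].rename("deaths").rename_axis(
        "hazard_id"
    ).reset_index().to_csv(out / "hazard_deaths.csv", index=False)

    # two chains splitting the food groups, random per-category points
    rng = np.random.default_rng(s_chain)
    chain_specs = []
    for cid, members in (
        ("produce_and_dairy", DEFAULT_FOOD_GROUPS[:2]),
        ("animal_products", DEFAULT_FOOD_GROUPS[2:]),
    ):
        stages = [f"{cid}_stage{i + 1}" for i in range(3)]
        sccps = [
            {"id": f"{cid}_sccp{i + 1}", "stage": stages[i % 3],
             "description": "synthetic"}
            for i in range(6)
        ]
        points = {
            s["id"]: {c: float(np.round(rng.uniform(1, 10), 3)) for c in ecologies}
            for s in sccps
        }
        chain_specs.append({
            "chain_id": cid, "food_groups": list(members), "stages": stages,
            "sccps": sccps, "points": points,
        })
    (out / "chains.yaml").write_text(_yaml.safe_dump({"chains": chain_specs}))

    config = {
        "population": population, "reference_year": REFERENCE_YEAR,
        "n_sims": 10_000, "seed": seed,
        "inputs": {
            "registry": "registry.csv",
            "burden_inputs": "burden_inputs.csv",
            "metrics_table": "metrics_table.csv",
            "rankings": "group_rankings.csv",
            "plenary_votes": "plenary_votes.csv",
            "responses": "responses.csv",
            "hazard_deaths": "hazard_deaths.csv",
            "chains": "chains.yaml",
        },
        "top_k_chains": 2,
    }
    (out / "config.yaml").write_text(_yaml.safe_dump(config))

    (out / "truth.json").write_text(_json.dumps({
        "seed": seed,
        "thresholds": list(thresholds),
        "rank_metric": "mortality_rate",
        "final_ranks": {hz: cat.label for hz, cat in rank_truth.items()},
        "burden": burden_truth.round(10).to_dict(orient="index"),
        "attribution": attr_truth.round(12).to_dict(orient="index"),
    }, indent=2, sort_keys=True) + "\n")
    return out


def generate_rank_truth(
    metric_table: pd.DataFrame,
    metric: str = "mortality_rate",
    quantiles: tuple[float, float] = (0.5, 0.8),
) -> tuple[dict[str, RankCategory], tuple[float, float]]:
    """True categories by thresholding one metric at its own quantiles."""
    x = metric_table[metric]
    t1, t2 = (float(x.quantile(q)) for q in quantiles)
    if not t1 < t2:  # degenerate spacing; nudge
        t2 = t1 + abs(t1) * 1e-6 + 1e-12
    final = {}
    for hz, v in x.items():
        if v < t1:
            final[str(hz)] = RankCategory.LOW
        elif v < t2:
            final[str(hz)] = RankCategory.MEDIUM
        else:
            final[str(hz)] = RankCategory.HIGH
    return final, (t1, t2)
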