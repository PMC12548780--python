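"""End-to-end pipeline: scope -> burden -> rank -> attribute -> prioritize.

``run_pipeline`` executes whichever stages the configuration provides
inputs for and writes a run directory of machine-readable outputs, each
stamped with the configuration hash.  All randomness flows from the single
config seed through named per-stage substreams, so reruns of the same
configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import attribution as attr
from . import burden as bd
from . import io as fio
from . import prioritization as prio
from . import ranking as rk
from . import uncertainty as unc
from .errors import FBDRankError, ParseError, ValidationError
from .hazard_registry import load_registry, scoping_screen, count_by_origin

logger = logging.getLogger("fbdrank")

STAGE_NAMES = ("burden", "ranking", "attribution", "prioritization")


@dataclass
class PipelineResult:
    run_dir: Path
    cfg_hash: str
    retained: list = field(default_factory=list)
    excluded: list = field(default_factory=list)
    metric_sets: list = field(default_factory=list)
    ranking_outcome: rk.RankingOutcome | None = None
    ordinal_fit: rk.OrdinalFit | None = None
    attributed: attr.AttributedDeaths | None = None
    category_table: pd.DataFrame | None = None
    chain_table: pd.DataFrame | None = None
    preventable: dict[str, prio.PreventableDeaths] = field(default_factory=dict)


def run_pipeline(
    config: fio.PipelineConfig,
    run_dir: str | Path,
    base_dir: str | Path | None = None,
) -> PipelineResult:
    """Run all configured stages; any stage error aborts with its name."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    base = Path(base_dir) if base_dir is not None else None
    cfg_hash = fio.config_hash(config)
    result = PipelineResult(run_dir=run_dir, cfg_hash=cfg_hash)

    log_path = run_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("config hash %s", cfg_hash)

    stage_seeds = unc.substream_seeds(config.seed, STAGE_NAMES)

    try:
        _run_stages(config, base, run_dir, cfg_hash, stage_seeds, result)
    except FBDRankError:
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    (run_dir / "config.json").write_text(
        json.dumps({"config_hash": cfg_hash, **config.to_dict()}, indent=2,
                   sort_keys=True) + "\n"
    )
    return result


def _stage_error(stage: str, exc: Exception) -> FBDRankError:
    return type(exc)(f"stage {stage!r} failed: {exc}") if isinstance(
        exc, FBDRankError
    ) else FBDRankError(f"stage {stage!r} failed: {exc}")


def _run_stages(config, base, run_dir, cfg_hash, stage_seeds, result) -> None:
    # scoping ---------------------------------------------------------------
    registry_path = config.path("registry", base)
    if registry_path is None:
        raise ValidationError("config provides no registry input")
    try:
        candidates = load_registry(registry_path)
        retained, excluded = scoping_screen(candidates)
    except Exception as exc:
        raise _stage_error("scoping", exc) from exc
    result.retained, result.excluded = retained, excluded
    origin_counts = count_by_origin(retained)
    logger.info("scoping: %d candidates, %d retained, %d excluded; origins %s",
                len(candidates), len(retained), len(excluded), origin_counts)
    scope_rows = [
        {"hazard_id": hz.id, "retained": True, "reason": ""} for hz in retained
    ] + [
        {"hazard_id": hz.id, "retained": False, "reason": reason}
        for hz, reason in excluded
    ]
    fio.write_table(pd.DataFrame(scope_rows), run_dir / "scoping.csv", cfg_hash)

    # burden ----------------------------------------------------------------
    burden_path = config.path("burden_inputs", base)
    metrics_wide: pd.DataFrame | None = None
    if burden_path is not None:
        try:
            records = fio.read_burden_inputs_csv(
                burden_path, population=config.population,
                reference_year=config.reference_year,
            )
            per_record = unc.substream_seeds(
                stage_seeds["burden"], [r.hazard_id for r in records]
            )
            result.metric_sets = [
                bd.compute_metric_set(r, n=config.n_sims, seed=per_record[r.hazard_id])
                for r in records
            ]
        except Exception as exc:
            raise _stage_error("burden", exc) from exc
        table = bd.metrics_table(result.metric_sets)
        fio.write_table(table, run_dir / "burden_metrics.csv", cfg_hash)
        metrics_wide = table.pivot(index="hazard_id", columns="metric",
                                   values="mean").astype(float)
        metrics_wide.index.name = None
        metrics_wide.columns.name = None
        logger.info("burden: %d hazards, %d metric rows", len(records), len(table))

    metrics_path = config.path("metrics_table", base)
    if metrics_path is not None:
        try:
            metrics_wide = fio.read_metrics_wide(metrics_path)
        except Exception as exc:
            raise _stage_error("burden", exc) from exc

    # ranking ---------------------------------------------------------------
    rankings_path = config.path("rankings", base)
    if rankings_path is not None:
        try:
            rounds = fio.read_rankings_csv(rankings_path)
            votes_path = config.path("plenary_votes", base)
            votes = fio.read_votes_csv(votes_path) if votes_path else {}
            outcome = rk.finalize_ranking(
                rounds, votes,
                tie_category=rk.RankCategory.parse(config.consensus_tie),
                tie_break_high=config.plenary_tie_high,
            )
        except Exception as exc:
            raise _stage_error("ranking", exc) from exc
        result.ranking_outcome = outcome
        logger.info("ranking: counts %s, resolution %s",
                    outcome.counts, outcome.resolution_counts())
        payload = {
            "config_hash": cfg_hash,
            "final": {h: c.label for h, c in sorted(outcome.final.items())},
            "resolved_in": dict(sorted(outcome.resolved_in.items())),
            "counts": outcome.counts,
            "resolution_counts": outcome.resolution_counts(),
        }
        if metrics_wide is not None:
            try:
                cols = [c for c in config.metrics if c in metrics_wide.columns]
                fit = rk.fit_ordinal_predictors(outcome.final, metrics_wide[cols])
                result.ordinal_fit = fit
                payload["ordinal_driver"] = fit.driver
                payload["ordinal_coefficients"] = {
                    k: float(v) for k, v in fit.coefficients.items()
                }
                logger.info("ranking: ordinal driver %s (%s fit)",
                            fit.driver, fit.method)
            except ValidationError as exc:
                logger.warning("ordinal fit skipped: %s", exc)
        (run_dir / "ranking.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )

    # attribution -----------------------------------------------------------
    registry_idx = {hz.id: hz for hz in result.retained}
    attributed: attr.AttributedDeaths | None = None
    responses_path = config.path("responses", base)
    attributed_path = config.path("attributed_deaths", base)
    try:
        if responses_path is not None:
            responses = fio.read_responses_csv(responses_path)
            matrix = attr.delphi_aggregate(responses, aggregator=config.aggregator)
            matrix = attr.apply_fixed_attributions(matrix, result.retained)
            if config.excluded_food_groups:
                present = [g for g in config.excluded_food_groups
                           if g in matrix.proportions.columns]
                if present:
                    matrix = attr.restrict_food_groups(matrix, present)
            deaths_path = config.path("hazard_deaths", base)
            if deaths_path is None:
                raise ValidationError(
                    "responses given but no hazard_deaths totals input"
                )
            totals = fio.read_hazard_deaths_csv(deaths_path)
            matrix = attr.AttributionMatrix(
                proportions=matrix.proportions,
                deaths=totals.reindex(matrix.proportions.index),
            )
            fio.write_table(
                matrix.proportions.rename_axis("hazard_id"),
                run_dir / "attribution_matrix.csv", cfg_hash, index=True,
            )
            attributed = attr.attribute_deaths(matrix)
        elif config.path("attribution_matrix", base) is not None:
            wide = fio.read_attribution_matrix_csv(
                config.path("attribution_matrix", base)
            )
            deaths_path = config.path("hazard_deaths", base)
            if deaths_path is None:
                raise ValidationError(
                    "attribution_matrix given but no hazard_deaths totals input"
                )
            totals = fio.read_hazard_deaths_csv(deaths_path)
            matrix = attr.AttributionMatrix(
                proportions=wide, deaths=totals.reindex(wide.index)
            )
            matrix = attr.apply_fixed_attributions(matrix, result.retained)
            attributed = attr.attribute_deaths(matrix)
        elif attributed_path is not None:
            attributed = fio.read_attributed_deaths_csv(attributed_path)
    except Exception as exc:
        raise _stage_error("attribution", exc) from exc

    if attributed is not None:
        if result.ranking_outcome is not None:
            high = {h for h, c in result.ranking_outcome.final.items()
                    if c == rk.RankCategory.HIGH}
            keep = [h for h in attributed.deaths.index if h in high]
            dropped = set(attributed.deaths.index) - set(keep)
            if dropped:
                logger.info("attribution: dropping non-High hazards %s",
                            sorted(dropped))
            attributed = attr.AttributedDeaths(deaths=attributed.deaths.loc[keep])
        result.attributed = attributed
        fio.write_table(
            attributed.deaths.stack().rename("deaths").reset_index()
            .set_axis(["hazard_id", "food_group", "deaths"], axis=1),
            run_dir / "attributed_deaths.csv", cfg_hash,
        )
        try:
            category_table = attr.aggregate_by_category(
                attributed, registry_idx.values()
            )
        except Exception as exc:
            raise _stage_error("attribution", exc) from exc
        result.category_table = category_table
        fio.write_table(category_table, run_dir / "category_table.csv",
                        cfg_hash, index=True)
        logger.info("attribution: %d hazards x %d food groups, total %.1f deaths",
                    *attributed.deaths.shape, attributed.total)

    # prioritization --------------------------------------------------------
    chains_path = config.path("chains", base)
    if chains_path is not None and result.category_table is not None:
        try:
            chains, allocations = fio.read_chains_yaml(chains_path)
            chain_table = prio.merge_food_groups(
                result.category_table, chains, top_k=config.top_k_chains
            )
            result.chain_table = chain_table
            selected = prio.select_top_chains(
                chain_table, chains, min(config.top_k_chains, len(chains))
            )
            fio.write_table(chain_table, run_dir / "chain_table.csv",
                            cfg_hash, index=True)
            for chain in selected:
                alloc = allocations.get(chain.chain_id)
                if alloc is None:
                    logger.warning("no point allocation for chain %s; skipped",
                                   chain.chain_id)
                    continue
                deaths = chain_table.loc[chain.chain_id].to_dict()
                p = prio.preventable_deaths(chain, alloc, deaths)
                result.preventable[chain.chain_id] = p
                rows = [
                    {"sccp_id": s, "category": c, "preventable_deaths": v}
                    for (s, c), v in sorted(p.values.items())
                ]
                fio.write_table(
                    pd.DataFrame(rows),
                    run_dir / f"preventable_deaths_{chain.chain_id}.csv",
                    cfg_hash,
                )
                tree = prio.sunburst_hierarchy(chain, p)
                tree["config_hash"] = cfg_hash
                prio.write_sunburst(tree, run_dir / f"sunburst_{chain.chain_id}.json")
                logger.info("prioritization: chain %s total %.1f preventable deaths",
                            chain.chain_id, p.total)
        except Exception as exc:
            raise _stage_error("prioritization", exc) from exc


# -- input validation -------------------------------------------------------


@dataclass
class ValidationReport:
    issues: list[dict] = field(default_factory=list)
    unreadable: list[str] = field(default_factory=list)

    def add(self, source: str, message: str) -> None:
        self.issues.append({"source": source, "message": message})

    @property
    def ok(self) -> bool:
        return not self.issues

    def to_dict(self) -> dict:
        return {"ok": self.ok, "n_issues": len(self.issues),
                "issues": self.issues, "unreadable": self.unreadable}


def validate_inputs(
    config: fio.PipelineConfig, base_dir: str | Path | None = None
) -> ValidationReport:
    """Check every configured input's type invariants without running."""
    base = Path(base_dir) if base_dir is not None else None
    report = ValidationReport()

    def try_read(key: str, reader) -> object | None:
        path = config.path(key, base)
        if path is None:
            return None
        if not Path(path).exists():
            report.unreadable.append(str(path))
            return None
        try:
            return reader(path)
        except FBDRankError as exc:
            report.add(key, str(exc))
            return None

    registry = try_read("registry", load_registry)
    try_read("rankings", fio.read_rankings_csv)
    try_read("plenary_votes", fio.read_votes_csv)
    try_read("metrics_table", fio.read_metrics_wide)
    try_read("burden_inputs", lambda p: fio.read_burden_inputs_csv(
        p, population=config.population, reference_year=config.reference_year))
    try_read("chains", fio.read_chains_yaml)
    try_read("hazard_deaths", fio.read_hazard_deaths_csv)
    try_read("attributed_deaths", fio.read_attributed_deaths_csv)
    try_read("attribution_matrix", fio.read_attribution_matrix_csv)

    responses_path = config.path("responses", base)
    if responses_path is not None and Path(responses_path).exists():
        try:
            responses = fio.read_responses_csv(responses_path)
            for r in responses:
                total = sum(r.proportions.values())
                if abs(total - 1.0) > 1e-6 and total > 0:
                    # raw answers may be unnormalized points; only a zero
                    # vector is fatal
                    continue
                if total <= 0:
                    report.add(
                        "responses",
                        f"expert {r.expert_id} hazard {r.hazard_id}: all-zero",
                    )
        except FBDRankError as exc:
            report.add("responses", str(exc))
    elif responses_path is not None:
        report.unreadable.append(str(responses_path))

    return report
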