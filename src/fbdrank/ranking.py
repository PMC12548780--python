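"""Two-round group risk ranking with consensus, escalation and a vote.

Stakeholder groups independently categorize each hazard as Low, Medium or
High risk in two rounds (round 1 with an assigned burden metric, round 2
free choice).  A hazard is final when all groups agree at the end of either
round.  Remaining disagreements are escalated to a plenary vote only if at
least one group ranked the hazard High; disagreements confined to Low and
Medium are settled by the modal category (tie broken to Medium, the
conservative choice) without further discussion.  Plenary votes resolve by
majority with ties broken toward the higher category (public-health
protective default); both tie rules are configurable.

The module also fits a proportional-odds ordinal regression of the final
categories on the burden metrics to identify which metric drove the
outcome.  Burden metrics span many orders of magnitude, so predictors are
log10-transformed (with a small offset for zeros) and standardized before
fitting; a ridge-penalized fit takes over when maximum likelihood separates.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .errors import RankingError, ValidationError


class RankCategory(IntEnum):
    """Ordinal risk category, Low < Medium < High."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2

    @classmethod
    def parse(cls, text: str) -> "RankCategory":
        key = str(text).strip().lower()
        table = {"low": cls.LOW, "medium": cls.MEDIUM, "high": cls.HIGH}
        if key not in table:
            raise ValidationError(f"unknown rank category {text!r}")
        return table[key]

    @property
    def label(self) -> str:
        return {0: "Low", 1: "Medium", 2: "High"}[int(self)]


@dataclass(frozen=True)
class GroupRound:
    """One group's categorization of every scoped hazard in one round."""

    group_id: str
    round: int
    assigned_metric: str
    ranks: Mapping[str, RankCategory]

    def __post_init__(self) -> None:
        if self.round not in (1, 2):
            raise ValidationError(f"round must be 1 or 2, got {self.round}")


@dataclass
class RankingOutcome:
    """Final categories with per-hazard resolution provenance."""

    final: dict[str, RankCategory]
    resolved_in: dict[str, str]  # round1 | round2 | plenary | mode
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            c = Counter(cat.label for cat in self.final.values())
            self.counts = {"High": c.get("High", 0), "Medium": c.get("Medium", 0),
                           "Low": c.get("Low", 0)}
        for hz, how in self.resolved_in.items():
            if how == "mode" and self.final[hz] == RankCategory.HIGH:
                raise ValidationError(
                    f"hazard {hz!r} settled by mode cannot be High"
                )

    def resolution_counts(self) -> dict[str, int]:
        c = Counter(self.resolved_in.values())
        return {k: c.get(k, 0) for k in ("round1", "round2", "plenary", "mode")}


def _check_same_hazards(rounds: Sequence[GroupRound]) -> set[str]:
    base = set(rounds[0].ranks)
    for gr in rounds[1:]:
        if set(gr.ranks) != base:
            diff = set(gr.ranks) ^ base
            raise RankingError(
                f"group {gr.group_id!r} round {gr.round} ranks a different "
                f"hazard set; difference: {sorted(diff)}"
            )
    return base


def round_consensus(
    rounds: Sequence[GroupRound], round_no: int
) -> tuple[dict[str, RankCategory], set[str]]:
    """Finalize hazards ranked identically by all groups in a round."""
    in_round = [gr for gr in rounds if gr.round == round_no]
    if not in_round:
        raise RankingError(f"no group rankings for round {round_no}")
    if len(in_round) == 1:
        warnings.warn(
            f"single group in round {round_no}: unanimity is vacuous",
            stacklevel=2,
        )
    hazards = _check_same_hazards(in_round)
    final: dict[str, RankCategory] = {}
    unresolved: set[str] = set()
    for hz in hazards:
        cats = {gr.ranks[hz] for gr in in_round}
        if len(cats) == 1:
            final[hz] = next(iter(cats))
        else:
            unresolved.add(hz)
    return final, unresolved


def plenary_escalation(
    unresolved: set[str],
    rounds: Sequence[GroupRound],
    tie_category: RankCategory = RankCategory.MEDIUM,
) -> tuple[set[str], dict[str, RankCategory]]:
    """Split unresolved hazards into plenary-discussion and mode-settled.

    A hazard goes to plenary only if at least one group gave it High in the
    last round; otherwise the disagreement is confined to Low/Medium and the
    hazard is settled at its modal category (Low/Medium tie -> Medium by
    default).  Returns ``(discuss, settled)``.
    """
    last_round = max(gr.round for gr in rounds)
    in_round = [gr for gr in rounds if gr.round == last_round]
    hazards = _check_same_hazards(in_round)
    missing = unresolved - hazards
    if missing:
        raise RankingError(f"unresolved hazards not ranked: {sorted(missing)}")
    discuss: set[str] = set()
    settled: dict[str, RankCategory] = {}
    for hz in unresolved:
        cats = [gr.ranks[hz] for gr in in_round]
        if RankCategory.HIGH in cats:
            discuss.add(hz)
            continue
        counts = Counter(cats)
        n_low, n_med = counts[RankCategory.LOW], counts[RankCategory.MEDIUM]
        if n_low == n_med:
            settled[hz] = tie_category
        else:
            settled[hz] = RankCategory.LOW if n_low > n_med else RankCategory.MEDIUM
    return discuss, settled


def plenary_vote(
    votes: Sequence[RankCategory], tie_break_high: bool = True
) -> RankCategory:
    """Majority vote over individual categorizations.

    Ties go to the higher of the tied categories by default (risk-averse).
    """
    if not votes:
        raise RankingError("plenary vote requires at least one vote")
    counts = Counter(votes)
    top = max(counts.values())
    winners = [cat for cat, c in counts.items() if c == top]
    if len(winners) == 1:
        return winners[0]
    return max(winners) if tie_break_high else min(winners)


def finalize_ranking(
    rounds: Sequence[GroupRound],
    plenary_votes: Mapping[str, Sequence[RankCategory]] | None = None,
    tie_category: RankCategory = RankCategory.MEDIUM,
    tie_break_high: bool = True,
) -> RankingOutcome:
    """Run the full consensus procedure to a final categorization.

    Round-1 consensus -> round-2 consensus on the remainder -> escalation of
    hazards with at least one High to the plenary vote -> modal settlement
    of the Low/Medium disagreements.  Provenance records where each hazard
    was resolved.
    """
    plenary_votes = plenary_votes or {}
    final: dict[str, RankCategory] = {}
    resolved_in: dict[str, str] = {}

    r1_final, r1_open = round_consensus(rounds, 1)
    for hz, cat in r1_final.items():
        final[hz], resolved_in[hz] = cat, "round1"

    has_round2 = any(gr.round == 2 for gr in rounds)
    if has_round2:
        r2_final, r2_open = round_consensus(rounds, 2)
        for hz in r1_open:
            if hz in r2_final:
                final[hz], resolved_in[hz] = r2_final[hz], "round2"
        unresolved = r1_open & r2_open
    else:
        unresolved = r1_open

    discuss, settled = plenary_escalation(unresolved, rounds, tie_category)
    for hz, cat in settled.items():
        final[hz], resolved_in[hz] = cat, "mode"
    for hz in discuss:
        if hz not in plenary_votes or not plenary_votes[hz]:
            raise RankingError(f"no plenary votes for escalated hazard {hz!r}")
        final[hz] = plenary_vote(list(plenary_votes[hz]), tie_break_high)
        resolved_in[hz] = "plenary"
    return RankingOutcome(final=final, resolved_in=resolved_in)


# ---------------------------------------------------------------------------
# ordinal regression: which metric drove the final ranking?


@dataclass(frozen=True)
class OrdinalFit:
    """Proportional-odds fit of final categories on burden metrics."""

    coefficients: "pd.Series"
    driver: str  # predictor with the largest |coefficient|
    method: str  # "mle" or "ridge"
    dropped: tuple[str, ...] = ()


def _log10_standardize(metrics: pd.DataFrame) -> pd.DataFrame:
    """log10(x + eps) then z-score each column; eps is the smallest positive
    observed value in the column scaled by 1e-3 (burden metrics span ~8
    orders of magnitude)."""
    out = {}
    for col in metrics.columns:
        x = metrics[col].to_numpy(float)
        positive = x[x > 0]
        eps = (positive.min() * 1e-3) if positive.size else 1.0
        z = np.log10(x + eps)
        sd = z.std(ddof=0)
        out[col] = (z - z.mean()) / (sd if sd > 0 else 1.0)
    return pd.DataFrame(out, index=metrics.index)


def _ordered_logit_nll(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                       n_cut: int, lam: float) -> float:
    p = X.shape[1]
    beta = params[:p]
    cuts = np.empty(n_cut)
    cuts[0] = params[p]
    if n_cut > 1:
        cuts[1:] = cuts[0] + np.cumsum(np.exp(params[p + 1:]))
    eta = X @ beta
    upper = np.where(y < n_cut, cuts[np.minimum(y, n_cut - 1)] - eta, np.inf)
    lower = np.where(y > 0, cuts[np.maximum(y - 1, 0)] - eta, -np.inf)
    prob = special.expit(upper) - special.expit(lower)
    prob = np.clip(prob, 1e-12, 1.0)
    return -np.log(prob).sum() + lam * float(beta @ beta)


def _fit_ridge_ordered_logit(
    X: np.ndarray, y: np.ndarray, lam: float = 1.0
) -> np.ndarray:
    """Ridge-penalized proportional-odds logit; returns slope coefficients.

    Cutpoints are parametrized as (c1, log-gaps) to keep them ordered; the
    penalty applies to slopes only.
    """
    n_cut = int(y.max())
    x0 = np.zeros(X.shape[1] + n_cut)
    res = optimize.minimize(
        _ordered_logit_nll, x0, args=(X, y, n_cut, lam), method="BFGS",
        options={"maxiter": 2000},
    )
    return res.x[: X.shape[1]]


def fit_ordinal_predictors(
    final: Mapping[str, RankCategory],
    metrics: pd.DataFrame,
    ridge_lambda: float = 1.0,
) -> OrdinalFit:
    """Fit Low<Medium<High on standardized log-metrics; name the driver.

    ``metrics`` is wide (hazards x metric point estimates) and must cover
    every finally-ranked hazard.  Perfectly collinear predictor pairs are
    reduced to one column with a warning.  If maximum likelihood fails to
    converge or separates (runaway coefficients), a ridge-penalized fit is
    used instead and reported as such.
    """
    hazards = [h for h in metrics.index if h in final]
    if len(hazards) < 10:
        raise ValidationError(
            f"ordinal fit needs >= 10 ranked hazards, got {len(hazards)}"
        )
    y = np.array([int(final[h]) for h in hazards])
    present = np.unique(y)
    if present.size < 2:
        raise ValidationError("ordinal fit needs >= 2 categories present")
    # re-code to consecutive 0..K-1 in case a category is absent
    recode = {v: i for i, v in enumerate(sorted(present))}
    y = np.array([recode[v] for v in y])

    Xdf = _log10_standardize(metrics.loc[hazards])
    dropped: list[str] = []
    keep: list[str] = []
    for col in Xdf.columns:
        redundant = False
        for kept in keep:
            r = np.corrcoef(Xdf[col], Xdf[kept])[0, 1]
            if abs(r) > 0.9999:
                redundant = True
                warnings.warn(
                    f"predictor {col!r} collinear with {kept!r}; dropped",
                    stacklevel=2,
                )
                break
        (dropped if redundant else keep).append(col)
    Xdf = Xdf[keep]
    X = Xdf.to_numpy(float)

    coefs, method = None, "mle"
    try:
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(y, X, distr="logit")
            fit = model.fit(method="bfgs", maxiter=500, disp=False)
        est = np.asarray(fit.params[: X.shape[1]], dtype=float)
        if fit.mle_retvals.get("converged", False) and np.all(np.abs(est) < 20):
            coefs = est
    except Exception:
        coefs = None
    if coefs is None:
        coefs = _fit_ridge_ordered_logit(X, y, lam=ridge_lambda)
        method = "ridge"

    series = pd.Series(coefs, index=keep, name="coefficient")
    driver = series.abs().idxmax()
    return OrdinalFit(
        coefficients=series, driver=str(driver), method=method,
        dropped=tuple(dropped),
    )
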