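"""Access to the packaged Ethiopia case-study fixtures.

The packaged files are:

``registry.csv``
    The 39 candidate hazards (37 retained + 2 screened out), with
    nomination origin, foodborne flag, toxin-producer flag, ecology of the
    high-risk hazards, and the fixed single food group for the one
    dairy-only pathogen.
``burden_metrics.csv``
    The published per-hazard best estimates and 95% uncertainty intervals
    for the four selected risk metrics (per 100,000; case-fatality in %).
    These are packaged as published output for validation — the elicited
    inputs behind them are not public.
``group_rankings.csv`` / ``plenary_votes.csv``
    A replay fixture for the two-round consensus procedure.  Per-group
    category sheets were not published; these rows are a synthetic
    reconstruction consistent with every published aggregate (5 hazards
    resolved in round 1, 15 after round 2, 9 escalated to plenary with 7
    voted High and 2 Medium, and final counts of 12 High / 6 Medium /
    19 Low with each hazard at its published final category).
``attributed_deaths_synthetic.csv``
    A synthetic integer decomposition of the published food-group x
    ecology-category death totals across the high-risk hazards of each
    category (the dairy-only pathogen confined to dairy).  Category-level
    aggregates of this table equal the published totals exactly; the
    per-hazard split is illustrative.
``chains.yaml``
    The four prioritized value chains with their published SCCP counts
    (vegetables 7, dairy 10, poultry/eggs 20, beef/small-ruminant 10) and
    illustrative point allocations (the elicited point values were not
    published).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

ETHIOPIA_FILES = (
    "registry.csv",
    "burden_metrics.csv",
    "group_rankings.csv",
    "plenary_votes.csv",
    "attributed_deaths_synthetic.csv",
    "chains.yaml",
    "config.yaml",
)


def ethiopia_path(name: str) -> Path:
    """Filesystem path of a packaged Ethiopia fixture file."""
    if name not in ETHIOPIA_FILES:
        raise KeyError(f"unknown fixture {name!r}; have {ETHIOPIA_FILES}")
    return Path(resources.files("fbdrank").joinpath("data", "ethiopia", name))
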