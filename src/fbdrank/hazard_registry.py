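"""Hazard universe, classification, and the scoping screen.

A national risk-ranking exercise starts from a candidate list of hazards
nominated from global burden estimates (FERG), heavy-metal assessments, and
local stakeholders.  The scoping screen removes candidates that cannot be
transmitted through food and agents that are only the producers of a toxin
already listed in its own right.  The two exclusion reasons are encoded as
data flags rather than hard-coded hazard names so the screen generalizes to
other countries' candidate lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

HAZARD_CLASSES = ("bacterium", "virus", "protozoan", "helminth", "chemical", "biotoxin")
ORIGINS = ("FERG", "metal", "stakeholder")
ECOLOGIES = ("anthroponotic", "zoonotic", "chemical", "unassigned")

#: reasons emitted by :func:`scoping_screen`
REASON_NOT_FOODBORNE = "not foodborne"
REASON_TOXIN_LISTED = "toxin already listed"

REGISTRY_COLUMNS = [
    "id", "name", "hazard_class", "origin", "foodborne",
    "is_toxin_producer_only", "ecology", "fixed_food_group",
]


@dataclass(frozen=True)
class Hazard:
    id: str
    name: str
    hazard_class: str
    origin: str
    foodborne: bool = True
    is_toxin_producer_only: bool = False
    ecology: str = "unassigned"
    fixed_food_group: str | None = None

    def __post_init__(self) -> None:
        if self.hazard_class not in HAZARD_CLASSES:
            raise ValidationError(
                f"hazard {self.id!r}: unknown hazard_class {self.hazard_class!r}"
            )
        if self.origin not in ORIGINS:
            raise ValidationError(f"hazard {self.id!r}: unknown origin {self.origin!r}")
        if self.ecology not in ECOLOGIES:
            raise ValidationError(f"hazard {self.id!r}: unknown ecology {self.ecology!r}")


def _parse_bool(value: object, column: str, hazard_id: str) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ParseError(f"hazard {hazard_id!r}: cannot parse {column}={value!r} as boolean")


def load_registry(source: str | Path) -> list[Hazard]:
    """Read a hazard registry CSV into an ordered list of hazards.

    The file must carry the full header ``id,name,hazard_class,origin,
    foodborne,is_toxin_producer_only,ecology,fixed_food_group``; ids must be
    unique and enums valid, otherwise a :class:`ParseError` names the
    offender.  Row order is preserved.
    """
    try:
        frame = pd.read_csv(source, dtype=str, comment="#", keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"cannot read registry {source}: {exc}") from exc

    missing = [c for c in REGISTRY_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"registry {source}: missing columns {missing}")

    hazards: list[Hazard] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        hid = row["id"].strip()
        if hid in seen:
            raise ParseError(f"registry {source}: duplicate hazard id {hid!r}")
        seen.add(hid)
        ecology = row["ecology"].strip() or "unassigned"
        fixed = row["fixed_food_group"].strip() or None
        try:
            hazards.append(Hazard(
                id=hid,
                name=row["name"].strip(),
                hazard_class=row["hazard_class"].strip(),
                origin=row["origin"].strip(),
                foodborne=_parse_bool(row["foodborne"], "foodborne", hid),
                is_toxin_producer_only=_parse_bool(
                    row["is_toxin_producer_only"], "is_toxin_producer_only", hid
                ),
                ecology=ecology,
                fixed_food_group=fixed,
            ))
        except ValidationError as exc:
            raise ParseError(str(exc)) from exc
    return hazards


def scoping_screen(
    candidates: Sequence[Hazard],
) -> tuple[list[Hazard], list[tuple[Hazard, str]]]:
    """Screen candidates down to the foodborne hazards to be ranked.

    Candidates with ``foodborne=False`` are excluded ("not foodborne");
    agents flagged ``is_toxin_producer_only`` are excluded because the toxin
    they produce is already a listed hazard.  Order is preserved and the
    screen is idempotent on its retained output.
    """
    if not candidates:
        raise ValidationError("scoping_screen requires a non-empty candidate list")
    retained: list[Hazard] = []
    excluded: list[tuple[Hazard, str]] = []
    for hz in candidates:
        if not hz.foodborne:
            excluded.append((hz, REASON_NOT_FOODBORNE))
        elif hz.is_toxin_producer_only:
            excluded.append((hz, REASON_TOXIN_LISTED))
        else:
            retained.append(hz)
    return retained, excluded


def count_by_origin(hazards: Iterable[Hazard]) -> dict[str, int]:
    """Count hazards by nomination origin; all origins present as keys."""
    counts = {origin: 0 for origin in ORIGINS}
    for hz in hazards:
        counts[hz.origin] += 1
    return counts


def registry_index(hazards: Iterable[Hazard]) -> dict[str, Hazard]:
    """Map hazard id to hazard for O(1) lookups downstream."""
    return {hz.id: hz for hz in hazards}
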