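"""Humane-endpoint welfare scoring for laboratory rats.

Implements a 14-parameter clinical score sheet used for weekly welfare
monitoring in a chemically induced (fructose feeding followed by a single
streptozotocin injection) rat model of type 2 diabetes.  Each parameter is
scored on an ordinal scale (a subset of 0-3); the weekly total drives the
endpoint decision:

* total >= 4                        -> critical: re-evaluate the animal;
* any euthanasia-marked level       -> euthanasia indicated, regardless of
                                       the total (e.g. weight loss > 20 %,
                                       stupor/coma, skin necrosis, walking
                                       on the tip of the extremities).

Not every parameter admits all four levels: the rubric encodes exactly the
admissible levels, and a level without a descriptor (e.g. Posture = 2) is a
validation error, never clamped.
"""

from __future__ import annotations

import enum
import json
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ParameterDefinition",
    "RubricDefinition",
    "ScoreSheet",
    "EndpointStatus",
    "EndpointDecision",
    "ScoreSheetError",
    "default_rubric",
    "rubric_to_json",
    "rubric_from_json",
    "validate_sheet",
    "total_score",
    "evaluate_endpoint",
    "score_hydration",
    "score_body_condition",
    "consensus_sheet",
    "consensus_series",
    "max_weekly_score",
    "CRITICAL_TOTAL",
]

#: Weekly total at which an animal must be re-evaluated (and possibly
#: removed from the study).
CRITICAL_TOTAL = 4

#: Skin-pinch recovery time (seconds) strictly above which the animal is
#: scored as dehydrated.
SKIN_PINCH_THRESHOLD_S = 2.0


class ScoreSheetError(ValueError):
    """A score sheet is incomplete or contains inadmissible levels."""


@dataclass(frozen=True)
class ParameterDefinition:
    """One welfare parameter: its admissible levels and their descriptors.

    ``euthanasia_levels`` marks the levels whose observation alone
    indicates euthanasia (independently of the weekly total).
    """

    name: str
    levels: Mapping[int, str]
    euthanasia_levels: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError(f"parameter {self.name!r} defines no levels")
        bad = set(self.levels) - {0, 1, 2, 3}
        if bad:
            raise ValueError(f"parameter {self.name!r}: levels {sorted(bad)} outside 0-3")
        if 0 not in self.levels:
            raise ValueError(f"parameter {self.name!r} must define level 0 (normal state)")
        if not set(self.euthanasia_levels) <= set(self.levels):
            raise ValueError(
                f"parameter {self.name!r}: euthanasia levels "
                f"{sorted(self.euthanasia_levels)} not all admissible"
            )

    @property
    def admissible(self) -> frozenset[int]:
        return frozenset(self.levels)

    @property
    def max_level(self) -> int:
        return max(self.levels)


@dataclass(frozen=True)
class RubricDefinition:
    """An ordered collection of welfare parameters (14 by default)."""

    parameters: tuple[ParameterDefinition, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.parameters]
        if len(names) != len(set(names)):
            raise ValueError("duplicate parameter names in rubric")

    def __getitem__(self, name: str) -> ParameterDefinition:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(p.name == name for p in self.parameters)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    @property
    def max_total(self) -> int:
        """Largest total a valid sheet can reach (33 for the default rubric)."""
        return sum(p.max_level for p in self.parameters)


@dataclass(frozen=True)
class ScoreSheet:
    """One animal x week x observer assignment of levels to all parameters."""

    animal_id: str
    week: int
    observer_id: str
    scores: Mapping[str, int]


class EndpointStatus(enum.IntEnum):
    """Ordered outcome of the endpoint decision (higher = more severe)."""

    CONTINUE = 0
    CRITICAL_REEVALUATE = 1
    EUTHANASIA_INDICATED = 2


@dataclass(frozen=True)
class EndpointDecision:
    """Decision for one sheet: status, weekly total, and the
    (parameter, level) pairs at euthanasia-marked levels, if any."""

    status: EndpointStatus
    total: int
    triggers: tuple[tuple[str, int], ...] = field(default_factory=tuple)


# --------------------------------------------------------------------------
# Default rubric
# --------------------------------------------------------------------------

_DEFAULT_ROWS: tuple[tuple[str, dict[int, str], frozenset[int]], ...] = (
    (
        "BodyCondition",
        {
            0: "Normal",
            1: "Altered body condition/weight loss of <10%",
            2: "Emaciated/weight loss of 10-20%",
            3: "Weight loss of >20%",
        },
        frozenset({3}),
    ),
    ("Posture", {0: "Normal", 1: "Curved"}, frozenset()),
    (
        "Hair",
        {
            0: "Normal",
            1: "Lack of grooming",
            2: "Very bad-looking hair, dirty tail, severe chromodacryorrhea",
        },
        frozenset(),
    ),
    (
        "GrimaceEyes",
        {
            0: "Normal",
            1: "Narrowing of the orbital area",
            2: "Moderate anemia/cataracts, eyes fully closed",
            3: "Severe anemia/corneal ulcers",
        },
        frozenset({3}),
    ),
    (
        "GrimaceEars",
        {
            0: "Normal",
            1: "Dropped ears, forward whiskers (stiffened)",
            2: "Floppy and curved ears, whiskers turned forward and crumpled (clusters)",
        },
        frozenset(),
    ),
    (
        "GrimaceNose",
        {
            0: "Normal",
            1: "Flattening and elongating the tip of the nose",
            2: "Flattening of the cheeks (cheek appearance)",
        },
        frozenset(),
    ),
    ("Walk", {0: "Normal", 3: "Walking on the tip of the extremities"}, frozenset({3})),
    (
        "Skin",
        {
            0: "Absence",
            1: "Skin injuries/infections <5 mm",
            2: "Skin injuries/infections >5 mm",
            3: "Presence of necrosis",
        },
        frozenset({3}),
    ),
    (
        "MentalStatus",
        {0: "Normal", 1: "Inactive", 2: "Moribund", 3: "Stupor/coma"},
        frozenset({3}),
    ),
    (
        "ResponseToStimuli",
        {0: "Normal", 1: "Moderate", 2: "Moderate with vocalization", 3: "Violent"},
        frozenset(),
    ),
    ("Hydration", {0: "Normal", 1: "Abnormal skin pinch test (>2 s)"}, frozenset()),
    ("Stool", {0: "Solid", 1: "Pasty diarrhea", 2: "Liquid diarrhea"}, frozenset()),
    ("Convulsions", {0: "Absence", 3: "Presence"}, frozenset()),
    (
        "Abdomen",
        {0: "Normal", 1: "Vocalization on palpation", 2: "Distended"},
        frozenset(),
    ),
)


def default_rubric() -> RubricDefinition:
    """The 14-parameter humane-endpoint rubric for the fructose + STZ rat
    model, with euthanasia markers on body condition (>20 % weight loss),
    severe ocular signs, walking on the tip of the extremities, skin
    necrosis, and stupor/coma.

    Convulsions (level 3) and a violent response to stimuli contribute to
    the total only; they carry no euthanasia marker.
    """
    return RubricDefinition(
        parameters=tuple(
            ParameterDefinition(name=n, levels=lv, euthanasia_levels=eu)
            for n, lv, eu in _DEFAULT_ROWS
        )
    )


# --------------------------------------------------------------------------
# JSON (de)serialization
# --------------------------------------------------------------------------

def rubric_to_json(rubric: RubricDefinition) -> str:
    """Serialize a rubric to its canonical JSON text (2-space indent,
    trailing newline).  ``rubric_from_json`` inverts it bit-identically."""
    payload = [
        {
            "name": p.name,
            "levels": {str(k): p.levels[k] for k in sorted(p.levels)},
            "euthanasia_levels": sorted(p.euthanasia_levels),
        }
        for p in rubric.parameters
    ]
    return json.dumps(payload, indent=2, ensure_ascii=False) + "\n"


def rubric_from_json(text: str) -> RubricDefinition:
    raw = json.loads(text)
    return RubricDefinition(
        parameters=tuple(
            ParameterDefinition(
                name=entry["name"],
                levels={int(k): v for k, v in entry["levels"].items()},
                euthanasia_levels=frozenset(entry["euthanasia_levels"]),
            )
            for entry in raw
        )
    )


# --------------------------------------------------------------------------
# Validation, totals, decisions
# --------------------------------------------------------------------------

def validate_sheet(sheet: ScoreSheet, rubric: RubricDefinition | None = None) -> ScoreSheet:
    """Check a sheet for completeness and admissibility against the rubric.

    Raises :class:`ScoreSheetError` listing every problem (missing
    parameter, unknown parameter, inadmissible level) with the parameter
    name and offending value; returns the sheet unchanged when valid.
    """
    rubric = rubric if rubric is not None else default_rubric()
    problems: list[str] = []
    for name in rubric.names:
        if name not in sheet.scores:
            problems.append(f"missing parameter {name!r}")
    for name, level in sheet.scores.items():
        if name not in rubric:
            problems.append(f"unknown parameter {name!r}")
            continue
        if level not in rubric[name].admissible:
            problems.append(
                f"inadmissible level {level!r} for parameter {name!r} "
                f"(admissible: {sorted(rubric[name].admissible)})"
            )
    if problems:
        raise ScoreSheetError(
            f"invalid sheet (animal {sheet.animal_id}, week {sheet.week}): "
            + "; ".join(problems)
        )
    return sheet


def total_score(sheet: ScoreSheet, rubric: RubricDefinition | None = None) -> int:
    """Weekly total: the sum of all parameter levels (0..33 for the
    default rubric)."""
    validate_sheet(sheet, rubric)
    return int(sum(sheet.scores.values()))


def evaluate_endpoint(
    sheet: ScoreSheet, rubric: RubricDefinition | None = None
) -> EndpointDecision:
    """Apply the endpoint decision rules to one sheet.

    Any euthanasia-marked level forces EUTHANASIA_INDICATED regardless of
    the total; otherwise a total of :data:`CRITICAL_TOTAL` (4) or more
    yields CRITICAL_REEVALUATE; otherwise CONTINUE.  ``triggers`` holds
    the euthanasia-marked (parameter, level) pairs.
    """
    rubric = rubric if rubric is not None else default_rubric()
    validate_sheet(sheet, rubric)
    total = int(sum(sheet.scores.values()))
    triggers = tuple(
        (name, level)
        for name, level in sheet.scores.items()
        if level in rubric[name].euthanasia_levels
    )
    if triggers:
        status = EndpointStatus.EUTHANASIA_INDICATED
    elif total >= CRITICAL_TOTAL:
        status = EndpointStatus.CRITICAL_REEVALUATE
    else:
        status = EndpointStatus.CONTINUE
    return EndpointDecision(status=status, total=total, triggers=triggers)


def score_hydration(recovery_time_s: float) -> int:
    """Hydration level from the skin-pinch test.

    Dehydration (level 1) when the skin tent takes strictly more than 2 s
    to normalise; exactly 2 s is still normal.
    """
    if recovery_time_s < 0:
        raise ValueError(f"negative skin-pinch recovery time: {recovery_time_s}")
    return 1 if recovery_time_s > SKIN_PINCH_THRESHOLD_S else 0


def score_body_condition(weight_loss_pct: float) -> int:
    """Body-condition level from the percent weight loss since the last
    assessment (negative values mean gain).

    0: no loss; 1: loss below 10 %; 2: loss of 10-20 % inclusive;
    3 (euthanasia-marked): loss above 20 %.
    """
    if weight_loss_pct <= 0:
        return 0
    if weight_loss_pct < 10:
        return 1
    if weight_loss_pct <= 20:
        return 2
    return 3


# --------------------------------------------------------------------------
# Multi-observer combination and per-animal series
# --------------------------------------------------------------------------

def consensus_sheet(
    sheets: Sequence[ScoreSheet], rubric: RubricDefinition | None = None
) -> ScoreSheet:
    """Combine the sheets of several observers for one animal-week.

    With three observers the consensus level per parameter is the median
    (never a tie); with two observers the maximum is used, the
    conservative choice for welfare; a single sheet is returned as-is
    (re-labelled).  The observers were independent in the protocol, so no
    weighting is applied.
    """
    if not sheets:
        raise ValueError("no sheets to combine")
    rubric = rubric if rubric is not None else default_rubric()
    keys = {(s.animal_id, s.week) for s in sheets}
    if len(keys) != 1:
        raise ValueError(f"sheets span several animal-weeks: {sorted(keys)}")
    for s in sheets:
        validate_sheet(s, rubric)
    animal_id, week = next(iter(keys))
    combined: dict[str, int] = {}
    for name in rubric.names:
        levels = [s.scores[name] for s in sheets]
        if len(levels) >= 3:
            combined[name] = int(statistics.median(levels))
        else:
            combined[name] = max(levels)
    return ScoreSheet(
        animal_id=animal_id, week=week, observer_id="consensus", scores=combined
    )


def consensus_series(
    history: Iterable[ScoreSheet], rubric: RubricDefinition | None = None
) -> list[ScoreSheet]:
    """Collapse a multi-observer history for one animal into one consensus
    sheet per week, ordered by week."""
    history = list(history)
    if not history:
        raise ValueError("empty score-sheet history")
    animals = {s.animal_id for s in history}
    if len(animals) != 1:
        raise ValueError(f"history mixes animals: {sorted(animals)}")
    by_week: dict[int, list[ScoreSheet]] = {}
    for s in history:
        by_week.setdefault(s.week, []).append(s)
    return [consensus_sheet(by_week[w], rubric) for w in sorted(by_week)]


def max_weekly_score(
    history: Sequence[ScoreSheet],
    rubric: RubricDefinition | None = None,
    *,
    combine_observers: bool = False,
) -> int:
    """Maximum weekly total over one animal's history.

    By default every sheet in ``history`` is totalled as given (suitable
    for a single observer's series); with ``combine_observers=True`` the
    per-week consensus series is totalled instead.
    """
    history = list(history)
    if not history:
        raise ValueError("empty score-sheet history")
    animals = {s.animal_id for s in history}
    if len(animals) != 1:
        raise ValueError(f"history mixes animals: {sorted(animals)}")
    series = consensus_series(history, rubric) if combine_observers else history
    return max(total_score(s, rubric) for s in series)
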