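"""Rubric structure, sheet validation, totals, and endpoint decisions."""

import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ratwelfare.welfare_scoring import (
    CRITICAL_TOTAL,
    EndpointStatus,
    ScoreSheet,
    ScoreSheetError,
    consensus_sheet,
    default_rubric,
    evaluate_endpoint,
    max_weekly_score,
    rubric_from_json,
    rubric_to_json,
    score_body_condition,
    score_hydration,
    total_score,
    validate_sheet,
)

RUBRIC = default_rubric()


def sheet(levels=None, animal="r1", week=1, observer="obs1"):
    scores = {name: 0 for name in RUBRIC.names}
    scores.update(levels or {})
    return ScoreSheet(animal_id=animal, week=week, observer_id=observer, scores=scores)


def valid_sheets():
    """Hypothesis strategy: a random valid sheet for the default rubric."""
    return st.fixed_dictionaries(
        {p.name: st.sampled_from(sorted(p.admissible)) for p in RUBRIC.parameters}
    ).map(lambda s: ScoreSheet("rX", 1, "obs1", s))


class TestRubric:
    def test_has_14_parameters_with_level_zero(self):
        assert len(RUBRIC.parameters) == 14
        assert all(0 in p.levels for p in RUBRIC.parameters)

    @pytest.mark.parametrize(
        "name,admissible",
        [
            ("Posture", {0, 1}),
            ("Walk", {0, 3}),
            ("Convulsions", {0, 3}),
            ("Hydration", {0, 1}),
            ("Stool", {0, 1, 2}),
            ("BodyCondition", {0, 1, 2, 3}),
        ],
    )
    def test_admissible_level_gaps(self, name, admissible):
        assert set(RUBRIC[name].admissible) == admissible

    def test_euthanasia_marked_levels(self):
        marked = {
            p.name: set(p.euthanasia_levels)
            for p in RUBRIC.parameters
            if p.euthanasia_levels
        }
        assert marked == {
            "BodyCondition": {3},
            "GrimaceEyes": {3},
            "Walk": {3},
            "Skin": {3},
            "MentalStatus": {3},
        }

    def test_max_total_is_33(self):
        assert RUBRIC.max_total == 33

    def test_json_round_trip_bit_identical(self):
        text = rubric_to_json(RUBRIC)
        again = rubric_to_json(rubric_from_json(text))
        assert text == again
        assert rubric_from_json(text) == RUBRIC

    def test_shipped_rubric_file_matches_default(self):
        from importlib import resources

        shipped = (
            resources.files("ratwelfare").joinpath("data/rubric.json").read_text("utf-8")
        )
        assert shipped == rubric_to_json(RUBRIC)
        json.loads(shipped)  # well-formed


class TestValidation:
    def test_all_zero_sheet_is_valid(self):
        assert validate_sheet(sheet(), RUBRIC) is not None

    def test_inadmissible_level_reported_with_name(self):
        with pytest.raises(ScoreSheetError, match="Posture"):
            validate_sheet(sheet({"Posture": 2}), RUBRIC)

    def test_missing_parameter_reported(self):
        s = sheet()
        scores = dict(s.scores)
        del scores["Convulsions"]
        with pytest.raises(ScoreSheetError, match="Convulsions"):
            validate_sheet(ScoreSheet("r1", 1, "obs1", scores), RUBRIC)

    def test_unknown_parameter_reported(self):
        s = sheet()
        scores = dict(s.scores, Whiskers=1)
        with pytest.raises(ScoreSheetError, match="Whiskers"):
            validate_sheet(ScoreSheet("r1", 1, "obs1", scores), RUBRIC)


class TestTotals:
    def test_all_zero_totals_zero(self):
        assert total_score(sheet(), RUBRIC) == 0

    def test_four_singles_total_four(self):
        s = sheet({"Hydration": 1, "Hair": 1, "Posture": 1, "Stool": 1})
        assert total_score(s, RUBRIC) == 4

    def test_maximal_sheet_totals_33(self):
        s = sheet({p.name: p.max_level for p in RUBRIC.parameters})
        assert total_score(s, RUBRIC) == 33

    @given(valid_sheets())
    def test_total_matches_brute_force_sum(self, s):
        assert total_score(s, RUBRIC) == sum(s.scores[n] for n in RUBRIC.names)


class TestEndpointDecision:
    def test_all_zero_continue(self):
        d = evaluate_endpoint(sheet(), RUBRIC)
        assert d.status == EndpointStatus.CONTINUE
        assert d.total == 0 and d.triggers == ()

    def test_total_four_is_critical(self):
        s = sheet({"Hydration": 1, "Hair": 1, "Posture": 1, "Stool": 1})
        d = evaluate_endpoint(s, RUBRIC)
        assert d.status == EndpointStatus.CRITICAL_REEVALUATE
        assert d.total == CRITICAL_TOTAL

    def test_euthanasia_level_overrides_low_total(self):
        d = evaluate_endpoint(sheet({"BodyCondition": 3}), RUBRIC)
        assert d.status == EndpointStatus.EUTHANASIA_INDICATED
        assert d.total == 3
        assert d.triggers == (("BodyCondition", 3),)

    def test_convulsions_present_not_euthanasia_marked(self):
        # Convulsions score 3 counts toward the total only
        d = evaluate_endpoint(sheet({"Convulsions": 3}), RUBRIC)
        assert d.status == EndpointStatus.CONTINUE
        assert d.triggers == ()

    @given(valid_sheets())
    def test_triggers_nonempty_iff_euthanasia(self, s):
        d = evaluate_endpoint(s, RUBRIC)
        assert (d.status == EndpointStatus.EUTHANASIA_INDICATED) == bool(d.triggers)
        if d.status == EndpointStatus.CONTINUE:
            assert d.total <= CRITICAL_TOTAL - 1

    @given(valid_sheets(), st.data())
    def test_raising_one_level_never_downgrades_status(self, s, data):
        name = data.draw(st.sampled_from(RUBRIC.names))
        higher = [lv for lv in RUBRIC[name].admissible if lv > s.scores[name]]
        if not higher:
            return
        raised = ScoreSheet(
            s.animal_id, s.week, s.observer_id, dict(s.scores, **{name: min(higher)})
        )
        assert evaluate_endpoint(raised, RUBRIC).status >= evaluate_endpoint(s, RUBRIC).status


class TestClinicalScoring:
    @pytest.mark.parametrize("t,level", [(1.0, 0), (2.0, 0), (2.5, 1), (10.0, 1)])
    def test_skin_pinch_threshold_strict(self, t, level):
        assert score_hydration(t) == level

    def test_negative_recovery_time_rejected(self):
        with pytest.raises(ValueError):
            score_hydration(-0.1)

    @pytest.mark.parametrize(
        "loss,level",
        [(-5, 0), (0, 0), (5, 1), (9.99, 1), (10, 2), (15, 2), (20, 2), (20.01, 3), (25, 3)],
    )
    def test_body_condition_boundaries(self, loss, level):
        assert score_body_condition(loss) == level


class TestHistoryAndConsensus:
    def test_max_over_weeks(self):
        history = [
            sheet({"Hydration": 1}, week=1),
            sheet(week=2),
            sheet({"Hydration": 1, "Hair": 1, "Posture": 1}, week=3),
            sheet({"Hair": 1, "Stool": 1}, week=4),
        ]
        assert max_weekly_score(history, RUBRIC) == 3

    def test_all_zero_control_history(self):
        assert max_weekly_score([sheet(week=w) for w in range(1, 8)], RUBRIC) == 0

    def test_relapse_pattern(self):
        history = [
            sheet({"Hair": 1, "Posture": 1}, week=1),
            sheet(week=2),
            sheet({"Hydration": 1, "Stool": 1}, week=3),
        ]
        assert max_weekly_score(history, RUBRIC) == 2

    def test_empty_and_mixed_histories_rejected(self):
        with pytest.raises(ValueError):
            max_weekly_score([], RUBRIC)
        with pytest.raises(ValueError):
            max_weekly_score([sheet(animal="a"), sheet(animal="b")], RUBRIC)

    def test_three_observer_consensus_is_median(self):
        sheets = [
            sheet({"Hair": 0}, observer="o1"),
            sheet({"Hair": 1}, observer="o2"),
            sheet({"Hair": 2}, observer="o3"),
        ]
        assert consensus_sheet(sheets, RUBRIC).scores["Hair"] == 1

    def test_two_observer_consensus_is_max(self):
        sheets = [sheet({"Stool": 0}, observer="o1"), sheet({"Stool": 2}, observer="o2")]
        assert consensus_sheet(sheets, RUBRIC).scores["Stool"] == 2

    def test_consensus_combine_in_max_weekly_score(self):
        history = [
            sheet({"Hair": 1}, week=1, observer=o) for o in ("o1", "o2", "o3")
        ] + [sheet(week=2, observer=o) for o in ("o1", "o2", "o3")]
        assert max_weekly_score(history, RUBRIC, combine_observers=True) == 1
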