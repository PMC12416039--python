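"""Imputation, prediction, recommendation rules, and explanations."""

import numpy as np
import pytest
from scipy.special import expit

from adrec import advice
from adrec import knowledgebase as kb
from conftest import make_toy_kb

SCHEMA = ["DX_e0", "RX_e1", "PX_e2", "ADR_e3", "DX_e4"]


def profile(reported=None, severity="moderate", tags=()):
    return advice.PatientProfile(reported or {}, severity, tuple(tags))


class TestImputation:
    def test_fully_reported_profile_unchanged_in_both_modes(self, toy_kb):
        p = profile({ev: ("present" if i % 2 else "absent")
                     for i, ev in enumerate(SCHEMA)})
        for mode in ("expected", "assume-absent"):
            completed = advice.impute_missing(
                p, toy_kb.imputation_models, SCHEMA, mode=mode
            )
            assert completed == {
                ev: (1.0 if i % 2 else 0.0) for i, ev in enumerate(SCHEMA)
            }

    def test_assume_absent_zeroes_unreported(self, toy_kb):
        p = profile({"DX_e0": "present"})
        completed = advice.impute_missing(
            p, toy_kb.imputation_models, SCHEMA, mode="assume-absent"
        )
        assert completed["DX_e0"] == 1.0
        assert all(completed[ev] == 0.0 for ev in SCHEMA if ev != "DX_e0")

    def test_expected_mode_logistic_expectation(self):
        # intercept -1, observed predictor present with weight 0.5
        models = [kb.ImputationModel("ADR_e3", -1.0, {"PX_e2": 0.5})]
        p = profile({"PX_e2": "present"})
        completed = advice.impute_missing(p, models, SCHEMA, mode="expected")
        assert completed["ADR_e3"] == pytest.approx(expit(-0.5), abs=1e-12)
        assert completed["ADR_e3"] == pytest.approx(0.3775, abs=5e-4)

    def test_chained_imputation_uses_upstream_expectation(self):
        models = [
            kb.ImputationModel("ADR_e3", 0.0, {"PX_e2": 1.0}),
            kb.ImputationModel("DX_e4", 0.0, {"ADR_e3": 2.0}),
        ]
        completed = advice.impute_missing(profile({}), models, SCHEMA)
        e3 = expit(0.0)  # PX_e2 unreported, no model -> 0
        assert completed["ADR_e3"] == pytest.approx(e3)
        assert completed["DX_e4"] == pytest.approx(expit(2.0 * e3))

    def test_storage_order_does_not_change_output(self):
        models = [
            kb.ImputationModel("ADR_e3", 0.3, {"PX_e2": 1.0}),
            kb.ImputationModel("DX_e4", -0.2, {"ADR_e3": 2.0, "DX_e0": 1.0}),
        ]
        p = profile({"DX_e0": "present"})
        a = advice.impute_missing(p, models, SCHEMA)
        b = advice.impute_missing(p, models[::-1], SCHEMA)
        assert a == b

    def test_cycle_rejected(self):
        models = [
            kb.ImputationModel("ADR_e3", 0.0, {"DX_e4": 1.0}),
            kb.ImputationModel("DX_e4", 0.0, {"ADR_e3": 1.0}),
        ]
        with pytest.raises(kb.KnowledgebaseError, match="cycle"):
            advice.impute_missing(profile({}), models, SCHEMA)

    def test_self_loop_rejected_at_construction(self):
        with pytest.raises(kb.KnowledgebaseError, match="itself"):
            kb.ImputationModel("DX_e0", 0.0, {"DX_e0": 1.0})


class TestPredictResponses:
    def test_all_zero_vector_gives_logistic_of_intercept(self, toy_kb):
        completed = {ev: 0.0 for ev in SCHEMA}
        probs = advice.predict_responses(completed, toy_kb)
        for drug, model in toy_kb.models.items():
            assert probs[drug] == pytest.approx(expit(model.intercept))

    def test_positive_event_raises_probability(self, toy_kb):
        base = advice.predict_responses({ev: 0.0 for ev in SCHEMA}, toy_kb)
        bumped = advice.predict_responses(
            {ev: (1.0 if ev == "DX_e4" else 0.0) for ev in SCHEMA}, toy_kb
        )
        assert bumped["bupropion"] > base["bupropion"]
        assert bumped["citalopram"] == base["citalopram"]

    def test_hand_evaluated_probabilities(self, toy_kb):
        completed = {"DX_e0": 1.0, "RX_e1": 0.0, "PX_e2": 0.0,
                     "ADR_e3": 0.5, "DX_e4": 1.0}
        probs = advice.predict_responses(completed, toy_kb)
        assert probs["amitriptyline"] == pytest.approx(expit(-0.4 + 1.0), abs=1e-12)
        assert probs["bupropion"] == pytest.approx(expit(-0.9 + 0.5 + 2.0), abs=1e-12)
        assert probs["citalopram"] == pytest.approx(expit(-2.5 + 0.4), abs=1e-12)


class TestRecommendRules:
    def test_low_severity_takes_precedence(self):
        rec = advice.recommend({"a": 0.9, "b": 0.2}, "low")
        assert rec.branch == "no_antidepressant_low_severity"
        assert rec.drugs == ()

    def test_no_drug_above_floor_goes_non_drug(self):
        rec = advice.recommend({"a": 0.10, "b": 0.05}, "moderate")
        assert rec.branch == "non_drug_options"

    def test_close_top_two_recommends_either(self):
        rec = advice.recommend({"A": 0.42, "B": 0.39, "C": 0.12}, "moderate")
        assert rec.branch == "either_of_two"
        assert rec.drugs == ("A", "B")

    def test_clear_winner_single_drug(self):
        rec = advice.recommend({"A": 0.42, "B": 0.30}, "severe")
        assert rec.branch == "single_drug"
        assert rec.drugs == ("A",)

    def test_exact_ties_break_by_drug_name(self):
        rec = advice.recommend({"b": 0.4, "a": 0.4, "c": 0.1}, "moderate")
        assert rec.drugs == ("a", "b")

    def test_pure_function_same_inputs_same_branch(self):
        args = ({"a": 0.3, "b": 0.28}, "moderate")
        assert advice.recommend(*args) == advice.recommend(*args)

    def test_relative_floor_mode(self):
        probs = {"a": 0.25, "b": 0.1}
        absolute = advice.recommend(probs, "moderate")
        relative = advice.recommend(
            probs, "moderate", floor_mode="relative", baseline_rate=0.2
        )
        assert absolute.branch == "single_drug"
        assert relative.branch == "non_drug_options"

    def test_empty_probabilities_error(self):
        with pytest.raises(ValueError):
            advice.recommend({}, "moderate")


class TestExplain:
    def test_zero_coefficient_kb_yields_empty_lists(self):
        null_kb = make_toy_kb(zero_coefficients=True)
        p = profile({"DX_e0": "present"})
        completed = advice.impute_missing(p, null_kb.imputation_models,
                                          null_kb.schema.events)
        probs = advice.predict_responses(completed, null_kb)
        rec = advice.recommend(probs, "moderate")
        expl = advice.explain(p, null_kb, rec)
        assert expl.presence_flips == ()
        assert expl.absence_flips == ()

    def test_decisive_event_listed_as_presence_flip(self, toy_kb):
        # baseline: DX_e0 present makes amitriptyline the clear winner;
        # DX_e4 carries +2 for bupropion only and would overturn it
        p = profile({"DX_e0": "present"})
        completed = advice.impute_missing(
            p, toy_kb.imputation_models, toy_kb.schema.events, mode="assume-absent"
        )
        probs = advice.predict_responses(completed, toy_kb)
        rec = advice.recommend(probs, "moderate")
        expl = advice.explain(p, toy_kb, rec)
        assert "DX_e4" in [ev for ev, _ in expl.presence_flips]

    def test_flip_lists_match_exhaustive_oracle(self, toy_kb):
        p = profile({"DX_e0": "present", "RX_e1": "absent"})
        mode = "assume-absent"
        completed = advice.impute_missing(
            p, toy_kb.imputation_models, toy_kb.schema.events, mode=mode
        )
        rec = advice.recommend(
            advice.predict_responses(completed, toy_kb), "moderate"
        )
        expl = advice.explain(p, toy_kb, rec, imputation_mode=mode)

        # independent exhaustive flip scan
        expected_presence, expected_absence = set(), set()
        for ev in toy_kb.schema.events:
            reported = dict(p.reported)
            to_present = reported.get(ev) != "present"
            reported[ev] = "present" if to_present else "absent"
            q = advice.PatientProfile(reported, "moderate")
            comp = advice.impute_missing(
                q, toy_kb.imputation_models, toy_kb.schema.events, mode=mode
            )
            new = advice.recommend(advice.predict_responses(comp, toy_kb), "moderate")
            if (new.branch, set(new.drugs)) != (rec.branch, set(rec.drugs)):
                (expected_presence if to_present else expected_absence).add(ev)
        assert {ev for ev, _ in expl.presence_flips} == expected_presence
        assert {ev for ev, _ in expl.absence_flips} == expected_absence

    def test_listed_flips_are_sound(self, toy_kb):
        """Every listed event, when actually flipped, changes the advice."""
        p = profile({"DX_e0": "present"})
        completed = advice.impute_missing(
            p, toy_kb.imputation_models, toy_kb.schema.events, mode="assume-absent"
        )
        rec = advice.recommend(
            advice.predict_responses(completed, toy_kb), "moderate"
        )
        expl = advice.explain(p, toy_kb, rec, imputation_mode="assume-absent")
        for ev, _ in expl.presence_flips + expl.absence_flips:
            reported = dict(p.reported)
            reported[ev] = "absent" if reported.get(ev) == "present" else "present"
            q = advice.PatientProfile(reported, "moderate")
            comp = advice.impute_missing(
                q, toy_kb.imputation_models, toy_kb.schema.events,
                mode="assume-absent",
            )
            new = advice.recommend(
                advice.predict_responses(comp, toy_kb), "moderate"
            )
            assert (new.branch, set(new.drugs)) != (rec.branch, set(rec.drugs))

    def test_double_flip_returns_to_baseline(self, toy_kb):
        p = profile({"DX_e0": "present"})
        flipped_once = advice._with_flip(p, "DX_e4", True)
        flipped_back = advice._with_flip(flipped_once, "DX_e4", False)
        for prof in (p, flipped_back):
            comp = advice.impute_missing(
                prof, toy_kb.imputation_models, toy_kb.schema.events,
                mode="assume-absent",
            )
            rec = advice.recommend(
                advice.predict_responses(comp, toy_kb), "moderate"
            )
        # the final recommendation equals the baseline one
        comp0 = advice.impute_missing(
            p, toy_kb.imputation_models, toy_kb.schema.events, mode="assume-absent"
        )
        base = advice.recommend(advice.predict_responses(comp0, toy_kb), "moderate")
        assert rec == base


class TestRenderAdvice:
    def test_either_of_two_names_exactly_two_drugs(self):
        close_kb = kb.Knowledgebase(
            schema=kb.EventSchema({"DX_e0": "DX"}),
            models={
                "paroxetine": kb.DrugModel("paroxetine", 0.0, {}),
                "sertraline": kb.DrugModel("sertraline", 0.1, {}),
            },
        )
        # expit(0.1) - expit(0.0) ≈ 0.025: within the 5-point window
        doc = advice.advise(profile({}), close_kb, with_explanation=False)
        assert doc.recommendation_branch == "either_of_two"
        assert len(doc.recommendation_drugs) == 2

    def test_non_drug_branch_has_empty_link_slots(self, toy_kb):
        doc = advice.advise(
            profile({}, severity="low"), toy_kb, with_explanation=False,
        )
        assert doc.recommendation_branch == "no_antidepressant_low_severity"
        assert doc.information_links == {}

    def test_bar_chart_covers_every_drug(self, toy_kb):
        doc = advice.advise(profile({}), toy_kb, with_explanation=False)
        assert set(doc.bar_chart) == set(toy_kb.models)

    def test_json_round_trip_lossless(self, toy_kb):
        doc = advice.advise(
            profile({"DX_e0": "present"}), toy_kb,
            imputation_mode="assume-absent",
            drug_links={"amitriptyline": "https://example.org/amitriptyline"},
        )
        assert advice.AdviceDocument.from_json(doc.to_json()) == doc

    def test_assume_absent_with_no_reports_gives_identical_advice(self, toy_kb):
        docs = [
            advice.advise(profile({}), toy_kb, imputation_mode="assume-absent",
                          with_explanation=False)
            for _ in range(2)
        ]
        assert docs[0] == docs[1]

    def test_history_summary_lists_relevant_reported_events(self, toy_kb):
        doc = advice.advise(
            profile({"DX_e0": "present", "PX_e2": "present", "RX_e1": "absent"}),
            toy_kb, with_explanation=False,
        )
        # PX_e2 has no coefficient in any drug model, so it is not relevant
        assert doc.history_summary == ["DX_e0"]
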