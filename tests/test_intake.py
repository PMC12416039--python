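"""Prototype derivation, information gain, and the greedy interview."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adrec import intake


def table_from(rows, features, drugs=("a", "b")):
    frame = pd.DataFrame(rows)
    domains = {f: tuple(sorted(frame[f].dropna().unique(), key=str)) for f in features}
    return intake.PrototypeTable(domains, frame, tuple(drugs), min_support=1)


def labeled(rows, features, labels, drugs=("a", "b")):
    t = table_from(rows, features, drugs)
    return t, pd.Series(labels, index=t.rows.index)


class TestDerivePrototypes:
    def _cohort(self, combos, per_combo):
        rows = []
        for combo, n in zip(combos, per_combo):
            for i in range(n):
                rows.append({**combo, "drug": "a" if i % 2 else "b",
                             "response": i % 3 == 0})
        return pd.DataFrame(rows)

    def test_support_filter_drops_rare_combination(self):
        data = self._cohort([{"f": 0}, {"f": 1}], [150, 40])
        t = intake.derive_prototypes(data, ["f"], min_support=100)
        assert len(t.rows) == 1
        assert t.rows.iloc[0]["f"] == 0

    def test_fully_crossed_binary_features(self):
        combos = [{"f": a, "g": b} for a in (0, 1) for b in (0, 1)]
        data = self._cohort(combos, [100] * 4)
        t = intake.derive_prototypes(data, ["f", "g"], min_support=100)
        assert len(t.rows) == 4

    def test_rates_match_stratified_tabulation(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame({
            "f": rng.integers(0, 2, 600),
            "g": rng.integers(0, 3, 600),
            "drug": rng.choice(["a", "b"], 600),
            "response": rng.integers(0, 2, 600),
        })
        t = intake.derive_prototypes(data, ["f", "g"], min_support=20)
        for _, row in t.rows.iterrows():
            strata = data[(data["f"] == row["f"]) & (data["g"] == row["g"])]
            assert row["count"] == len(strata)
            for d in ("a", "b"):
                treated = strata[strata["drug"] == d]
                if len(treated):
                    assert row[f"rate_{d}"] == pytest.approx(treated["response"].mean())

    def test_no_combination_reaching_support_errors(self):
        data = self._cohort([{"f": i} for i in range(5)], [10] * 5)
        with pytest.raises(intake.IntakeError, match="coarser"):
            intake.derive_prototypes(data, ["f"], min_support=100)


class TestInformationGain:
    def test_constant_feature_has_zero_gain(self):
        t, labels = labeled(
            [{"f": 0, "g": 0, "count": 10, "rate_a": 0.5, "rate_b": 0.1},
             {"f": 0, "g": 1, "count": 10, "rate_a": 0.1, "rate_b": 0.5}],
            ["f", "g"], ["A", "B"],
        )
        state = intake.initial_state(t)
        assert intake.information_gain(state, "f", t, labels) == 0.0

    def test_perfect_binary_split_gains_one_bit(self):
        t, labels = labeled(
            [{"f": v, "g": g, "count": 10, "rate_a": 0.5, "rate_b": 0.1}
             for v, g in ((0, 0), (0, 1), (1, 0), (1, 1))],
            ["f", "g"], ["A", "A", "B", "B"],
        )
        state = intake.initial_state(t)
        assert intake.information_gain(state, "f", t, labels) == pytest.approx(1.0)

    def test_matches_brute_force_entropy_oracle(self):
        rng = np.random.default_rng(1)
        rows = []
        for f in (0, 1):
            for g in (0, 1, 2):
                rows.append({"f": f, "g": g, "h": int(rng.integers(0, 2)),
                             "count": int(rng.integers(1, 30)),
                             "rate_a": 0.3, "rate_b": 0.4})
        t = table_from(rows, ["f", "g", "h"])
        labels = pd.Series(list("ABABCA"), index=t.rows.index)
        state = intake.initial_state(t)

        def entropy(weighted):
            total = sum(weighted.values())
            return -sum(w / total * math.log2(w / total)
                        for w in weighted.values() if w)

        for feature in ("f", "g", "h"):
            # independent enumeration of conditional entropies
            prior = {}
            branches = {}
            for i in t.rows.index:
                lab, w = labels[i], t.rows.at[i, "count"]
                prior[lab] = prior.get(lab, 0) + w
                v = t.rows.at[i, feature]
                branches.setdefault(v, {})
                branches[v][lab] = branches[v].get(lab, 0) + w
            total = sum(prior.values())
            expected = entropy(prior) - sum(
                sum(b.values()) / total * entropy(b) for b in branches.values()
            )
            got = intake.information_gain(state, feature, t, labels)
            assert got == pytest.approx(expected)

    def test_gain_nonnegative_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            rows = [
                {"f": int(rng.integers(0, 3)), "count": int(rng.integers(1, 20)),
                 "rate_a": 0.2, "rate_b": 0.8}
                for _ in range(6)
            ]
            frame = pd.DataFrame(rows).drop_duplicates("f")
            t = table_from(frame.to_dict("records"), ["f"])
            labels = pd.Series(rng.choice(["A", "B"], len(t.rows)), index=t.rows.index)
            state = intake.initial_state(t)
            assert intake.information_gain(state, "f", t, labels) >= 0.0

    def test_undefined_values_grouped_under_unknown(self):
        t, labels = labeled(
            [{"f": 0, "count": 10, "rate_a": 0.5, "rate_b": 0.1},
             {"f": None, "count": 10, "rate_a": 0.1, "rate_b": 0.5}],
            ["f"], ["A", "B"],
        )
        state = intake.initial_state(t)
        # NaN rows form their own branch, so the split is perfect
        assert intake.information_gain(state, "f", t, labels) == pytest.approx(1.0)


class TestNextQuestion:
    def _table(self):
        rows = [
            {"sex": "male", "pregnant": None, "age": "young",
             "count": 10, "rate_a": 0.4, "rate_b": 0.1},
            {"sex": "male", "pregnant": None, "age": "old",
             "count": 10, "rate_a": 0.1, "rate_b": 0.4},
            {"sex": "female", "pregnant": "no", "age": "young",
             "count": 10, "rate_a": 0.4, "rate_b": 0.1},
            {"sex": "female", "pregnant": "yes", "age": "young",
             "count": 10, "rate_a": 0.05, "rate_b": 0.02},
        ]
        t = table_from(rows, ["sex", "pregnant", "age"])
        labels = pd.Series(["A", "B", "A", "N"], index=t.rows.index)
        return t, labels

    def test_stop_when_labels_constant(self):
        t, labels = self._table()
        constant = pd.Series(["A"] * 4, index=t.rows.index)
        state = intake.initial_state(t)
        assert intake.next_question(state, t, constant) is intake.STOP

    def test_precluded_feature_never_proposed(self):
        t, labels = self._table()
        preclusions = {("sex", "male"): ["pregnant"]}
        state = intake.apply_answer(intake.initial_state(t), "sex", "male", t)
        while True:
            q = intake.next_question(state, t, labels, preclusions=preclusions)
            if q is intake.STOP:
                break
            assert q != "pregnant"
            state = intake.apply_answer(
                state, q, t.rows.loc[state.surviving[0], q], t
            )

    def test_budget_exhaustion_stops(self):
        t, labels = self._table()
        state = intake.initial_state(t, question_budget=0)
        assert intake.next_question(state, t, labels) is intake.STOP

    def test_maximal_gain_feature_chosen(self):
        t, labels = self._table()
        state = intake.initial_state(t)
        gains = {
            f: intake.information_gain(state, f, t, labels)
            for f in ("sex", "pregnant", "age")
        }
        best = min(gains, key=lambda f: (-gains[f], f))
        assert intake.next_question(state, t, labels) == best

    def test_empty_survivors_error(self):
        t, labels = self._table()
        state = intake.IntakeState(answers={}, surviving=(), asked=())
        with pytest.raises(intake.IntakeError, match="contradictory"):
            intake.next_question(state, t, labels)


class TestApplyAnswer:
    def _simple(self):
        return table_from(
            [{"f": 0, "g": 0, "count": 5, "rate_a": 0.1, "rate_b": 0.1},
             {"f": 0, "g": 1, "count": 5, "rate_a": 0.1, "rate_b": 0.1},
             {"f": 1, "g": 0, "count": 5, "rate_a": 0.1, "rate_b": 0.1}],
            ["f", "g"],
        )

    def test_answer_matching_all_keeps_everything(self):
        t = self._simple()
        state = intake.apply_answer(intake.initial_state(t), "g", 0, t)
        state2 = intake.apply_answer(state, "f", 0, t)
        assert len(state.surviving) == 2
        assert len(state2.surviving) == 1

    def test_answer_matching_none_errors(self):
        t = self._simple()
        state = intake.apply_answer(intake.initial_state(t), "f", 1, t)
        with pytest.raises(intake.IntakeError, match="no surviving"):
            intake.apply_answer(state, "g", 1, t)

    def test_reanswering_errors(self):
        t = self._simple()
        state = intake.apply_answer(intake.initial_state(t), "f", 0, t)
        with pytest.raises(intake.IntakeError, match="already"):
            intake.apply_answer(state, "f", 1, t)

    def test_value_outside_domain_errors(self):
        t = self._simple()
        with pytest.raises(intake.IntakeError, match="domain"):
            intake.apply_answer(intake.initial_state(t), "f", 7, t)

    def test_sequence_equals_one_shot_filter(self):
        t = self._simple()
        s = intake.initial_state(t)
        s = intake.apply_answer(s, "f", 0, t)
        s = intake.apply_answer(s, "g", 1, t)
        direct = [
            i for i in t.rows.index
            if t.rows.at[i, "f"] == 0 and t.rows.at[i, "g"] == 1
        ]
        assert list(s.surviving) == direct

    @given(st.permutations(["f", "g"]))
    @settings(deadline=None)
    def test_order_independence(self, order):
        t = self._simple()
        s = intake.initial_state(t)
        for f in order:
            s = intake.apply_answer(s, f, 0, t)
        assert list(s.surviving) == [0]


class TestInterview:
    def test_survivors_monotone_and_interview_terminates(self):
        rng = np.random.default_rng(3)
        rows = []
        for f in (0, 1):
            for g in (0, 1):
                for h in (0, 1):
                    rows.append({"f": f, "g": g, "h": h,
                                 "count": int(rng.integers(1, 40)),
                                 "rate_a": float(rng.random() * 0.5),
                                 "rate_b": float(rng.random() * 0.5)})
        t = table_from(rows, ["f", "g", "h"])
        labels = intake.recommendation_labels(t)
        for i in t.rows.index:
            answers = {f: t.rows.at[i, f] for f in ("f", "g", "h")}
            result = intake.run_interview(t, answers, labels=labels)
            assert result["n_questions"] <= 3
            assert labels[i] in result["surviving_labels"]
            assert len(result["surviving_labels"]) == 1 or result["n_questions"] == 3

    def test_noninformative_feature_shortens_interviews(self):
        # h never splits the labels, so greedy interviews skip it
        rows = []
        for f in (0, 1):
            for h in (0, 1):
                rows.append({"f": f, "h": h, "count": 10,
                             "rate_a": 0.4 if f else 0.05,
                             "rate_b": 0.1 if f else 0.02})
        t = table_from(rows, ["f", "h"])
        length = intake.expected_interview_length(t)
        assert length < 2  # fewer questions than features
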