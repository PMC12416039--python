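"""Adaptive survey intake driven by expected information gain.

Instead of asking about every medical-history event, the survey intake works
from a *prototype table*: feature-value combinations observed in at least
``min_support`` patients, each carrying per-drug empirical response rates.
Every row induces a recommendation label through the advice rules, and the
interview greedily asks the unasked feature whose answer is expected to
reduce the entropy of that label the most, pruning rows inconsistent with
each answer.  The interview stops when the surviving rows all share one
recommendation, when every feature has been asked, or when the question
budget runs out.  Features logically precluded by earlier answers (pregnancy
after "male", for instance) are never proposed, and "unknown" is a
first-class answer with its own branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from adrec.advice import recommend

UNKNOWN = "unknown"

#: Sentinel returned by :func:`next_question` when the interview should end.
STOP = None


class IntakeError(ValueError):
    pass


@dataclass(frozen=True)
class PrototypeTable:
    """Feature-combination rows with counts and per-drug response rates.

    ``features`` maps each feature name to its finite answer domain.
    ``rows`` holds one column per feature plus ``count`` and one
    ``rate_<drug>`` column per drug; a missing (NaN) rate flags a drug absent
    from that stratum, and a missing feature value means the feature is
    undefined for the row.
    """

    features: Mapping[str, tuple]
    rows: pd.DataFrame
    drugs: tuple[str, ...]
    min_support: int = 100

    def __post_init__(self) -> None:
        for f in self.features:
            if f not in self.rows.columns:
                raise IntakeError(f"feature {f!r} missing from rows")
        if "count" not in self.rows.columns:
            raise IntakeError("rows must carry a 'count' column")
        if (self.rows["count"] < self.min_support).any():
            raise IntakeError(f"all rows must describe >= {self.min_support} patients")
        if self.rows.duplicated(subset=list(self.features)).any():
            raise IntakeError("duplicate feature combinations")
        for d in self.drugs:
            col = f"rate_{d}"
            if col not in self.rows.columns:
                raise IntakeError(f"missing rate column {col!r}")
            vals = self.rows[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise IntakeError("response rates must lie in [0, 1]")

    def rates(self, row_id: Hashable) -> dict[str, float]:
        row = self.rows.loc[row_id]
        return {
            d: float(row[f"rate_{d}"])
            for d in self.drugs
            if pd.notna(row[f"rate_{d}"])
        }


def derive_prototypes(
    data: pd.DataFrame,
    features: Sequence[str],
    *,
    min_support: int = 100,
    drugs: Sequence[str] | None = None,
) -> PrototypeTable:
    """Tabulate observed feature combinations with per-drug response rates.

    ``data`` needs one row per episode with the feature columns plus
    ``drug`` and binary ``response``.  Combinations described by fewer than
    ``min_support`` episodes are dropped; if none survives, the feature set
    is too fine and an error says so.
    """
    for col in (*features, "drug", "response"):
        if col not in data.columns:
            raise IntakeError(f"input data lacks column {col!r}")
    drugs = sorted(drugs if drugs is not None else data["drug"].unique())
    grouped = data.groupby(list(features), dropna=False, sort=True)
    rows = []
    for combo, g in grouped:
        if len(g) < min_support:
            continue
        combo = combo if isinstance(combo, tuple) else (combo,)
        row = dict(zip(features, combo))
        row["count"] = len(g)
        for d in drugs:
            treated = g[g["drug"] == d]
            row[f"rate_{d}"] = (
                float(treated["response"].mean()) if len(treated) else np.nan
            )
        rows.append(row)
    if not rows:
        raise IntakeError(
            "no feature combination reaches the support threshold; "
            "use fewer or coarser features"
        )
    frame = pd.DataFrame(rows).reset_index(drop=True)
    domains = {
        f: tuple(sorted(frame[f].dropna().unique(), key=str)) for f in features
    }
    return PrototypeTable(domains, frame, tuple(drugs), min_support)


def recommendation_labels(
    table: PrototypeTable,
    *,
    severity: str = "moderate",
    label_fn: Callable[[dict[str, float]], str] | None = None,
    **recommend_kwargs,
) -> pd.Series:
    """Recommendation label induced on each prototype row by the advice rules.

    This is the target the interview tries to pin down.  The objective is
    pluggable: supply ``label_fn`` mapping per-drug rates to any label to
    optimize for something other than the advice branch.
    """
    def default_label(rates: dict[str, float]) -> str:
        if not rates:
            return "non_drug_options"
        rec = recommend(rates, severity, **recommend_kwargs)
        return rec.branch + (":" + "|".join(rec.drugs) if rec.drugs else "")

    fn = label_fn or default_label
    return pd.Series(
        [fn(table.rates(i)) for i in table.rows.index], index=table.rows.index
    )


@dataclass(frozen=True)
class IntakeState:
    """Progress of one interview: answers, survivors, asked features."""

    answers: Mapping[str, object] = field(default_factory=dict)
    surviving: tuple = ()
    asked: tuple[str, ...] = ()
    question_budget: int = 25


def initial_state(table: PrototypeTable, question_budget: int = 25) -> IntakeState:
    return IntakeState(
        answers={},
        surviving=tuple(table.rows.index),
        asked=(),
        question_budget=question_budget,
    )


def _matches(cell, value) -> bool:
    if value == UNKNOWN:
        return pd.isna(cell)
    return (not pd.isna(cell)) and cell == value


def _entropy(weights: np.ndarray) -> float:
    total = weights.sum()
    if total <= 0:
        return 0.0
    p = weights / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _label_entropy(labels: pd.Series, counts: pd.Series) -> float:
    grouped = counts.groupby(labels).sum()
    return _entropy(grouped.to_numpy(dtype=float))


def information_gain(
    state: IntakeState,
    feature: str,
    table: PrototypeTable,
    labels: pd.Series,
) -> float:
    """Expected entropy reduction (bits) of the recommendation label.

    Answer probabilities are proportional to surviving patient counts; rows
    with an undefined value for the feature form an explicit "unknown"
    branch.  Gain is nonnegative and zero exactly when the feature does not
    split the survivors.
    """
    if feature in state.asked:
        raise IntakeError(f"feature {feature!r} already asked")
    if feature not in table.features:
        raise IntakeError(f"unknown feature {feature!r}")
    if not state.surviving:
        raise IntakeError("no surviving prototypes (contradictory answers)")
    idx = list(state.surviving)
    sub = table.rows.loc[idx]
    counts = sub["count"].astype(float)
    lab = labels.loc[idx]
    prior = _label_entropy(lab, counts)
    values = sub[feature].map(lambda v: UNKNOWN if pd.isna(v) else v)
    posterior = 0.0
    total = counts.sum()
    for _, branch in counts.groupby(values):
        weight = branch.sum() / total
        posterior += weight * _label_entropy(lab.loc[branch.index], branch)
    return max(0.0, prior - posterior)


def next_question(
    state: IntakeState,
    table: PrototypeTable,
    labels: pd.Series,
    *,
    preclusions: Mapping[tuple[str, object], Sequence[str]] | None = None,
) -> str | None:
    """The unasked feature with maximal expected gain, or ``STOP``.

    Stops when the induced recommendation is already constant across the
    survivors, when the budget is exhausted, or when nothing is left to ask.
    ``preclusions`` maps an (feature, answer) pair to features that answer
    rules out — a precluded feature is never proposed.
    """
    if not state.surviving:
        raise IntakeError("no surviving prototypes (contradictory answers)")
    if len(state.asked) >= state.question_budget:
        return STOP
    idx = list(state.surviving)
    if labels.loc[idx].nunique() <= 1:
        return STOP

    blocked: set[str] = set()
    for (feat, value), ruled_out in (preclusions or {}).items():
        if state.answers.get(feat) == value:
            blocked.update(ruled_out)

    candidates = [
        f for f in table.features if f not in state.asked and f not in blocked
    ]
    if not candidates:
        return STOP
    gains = {f: information_gain(state, f, table, labels) for f in candidates}
    return min(gains, key=lambda f: (-gains[f], f))


def apply_answer(
    state: IntakeState,
    feature: str,
    value,
    table: PrototypeTable,
) -> IntakeState:
    """Record an answer and prune inconsistent prototypes.

    The surviving set never grows, answers are never re-asked, and a
    sequence of answers prunes to exactly the same set as filtering on all
    of them at once.  An answer consistent with no survivor is an error.
    """
    if feature in state.asked:
        raise IntakeError(f"feature {feature!r} was already answered")
    if feature not in table.features:
        raise IntakeError(f"unknown feature {feature!r}")
    if value != UNKNOWN and value not in table.features[feature]:
        raise IntakeError(f"value {value!r} not in domain of {feature!r}")
    surviving = tuple(
        i for i in state.surviving if _matches(table.rows.at[i, feature], value)
    )
    if not surviving:
        raise IntakeError(
            f"answer {feature}={value!r} is consistent with no surviving prototype"
        )
    return IntakeState(
        answers={**dict(state.answers), feature: value},
        surviving=surviving,
        asked=(*state.asked, feature),
        question_budget=state.question_budget,
    )


def run_interview(
    table: PrototypeTable,
    answer_source: Mapping[str, object] | Callable[[str], object],
    *,
    labels: pd.Series | None = None,
    question_budget: int = 25,
    preclusions: Mapping[tuple[str, object], Sequence[str]] | None = None,
) -> dict:
    """Run a greedy interview against a fixed answer source.

    ``answer_source`` is either a mapping feature → answer or a callable;
    missing answers count as "unknown".  Returns a transcript with the
    questions asked, the answers, and the surviving labels.
    """
    if labels is None:
        labels = recommendation_labels(table)
    lookup = (
        answer_source if callable(answer_source)
        else lambda f: answer_source.get(f, UNKNOWN)
    )
    state = initial_state(table, question_budget)
    transcript: list[tuple[str, object]] = []
    while True:
        feature = next_question(state, table, labels, preclusions=preclusions)
        if feature is STOP:
            break
        answer = lookup(feature)
        state = apply_answer(state, feature, answer, table)
        transcript.append((feature, answer))
    surviving_labels = sorted(labels.loc[list(state.surviving)].unique())
    return {
        "questions": transcript,
        "n_questions": len(transcript),
        "surviving_rows": list(state.surviving),
        "surviving_labels": surviving_labels,
        "answers": dict(state.answers),
    }


def expected_interview_length(
    table: PrototypeTable,
    *,
    labels: pd.Series | None = None,
    question_budget: int = 25,
) -> float:
    """Count-weighted expected number of questions under the greedy policy.

    Each prototype row plays the respondent (answering with its own feature
    values); the expectation weights rows by their patient counts.
    """
    if labels is None:
        labels = recommendation_labels(table)
    total = float(table.rows["count"].sum())
    expected = 0.0
    for i in table.rows.index:
        row = table.rows.loc[i]
        answers = {
            f: (UNKNOWN if pd.isna(row[f]) else row[f]) for f in table.features
        }
        result = run_interview(
            table, answers, labels=labels, question_budget=question_budget
        )
        expected += float(row["count"]) / total * result["n_questions"]
    return expected
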