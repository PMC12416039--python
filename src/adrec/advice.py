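"""Rule-based, explained antidepressant recommendations.

Given a patient's reported medical-history events, the advice stage
completes the event vector (imputing unreported events through the linked
regression network, or assuming them absent), predicts a response
probability for every antidepressant through the routed knowledgebase
models, applies a fixed rule cascade to pick a recommendation branch, and
derives a counterfactual explanation: the single event flips that would
change the advice.  The output is a four-section document assembled from
pre-set templates only — nothing is generated free-form.

Rule cascade (in precedence order):

1. low severity → no antidepressant; refer to non-drug care such as exercise;
2. no drug reaches the 10% response floor → non-oral-antidepressant options;
3. top two drugs within 5 percentage points → recommend either of the two;
4. otherwise → the single highest-probability drug.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from adrec.knowledgebase import (
    ImputationModel,
    Knowledgebase,
    KnowledgebaseError,
    _check_acyclic,
)

__all__ = [
    "AdviceDocument",
    "Explanation",
    "ImputationModel",
    "PatientProfile",
    "Recommendation",
    "explain",
    "impute_missing",
    "predict_responses",
    "recommend",
    "render_advice",
]

SEVERITIES = ("low", "moderate", "severe")

ReportStatus = Literal["present", "absent"]
ImputationMode = Literal["expected", "assume-absent"]

RESPONSE_FLOOR = 0.10
TIE_WINDOW = 0.05


@dataclass(frozen=True)
class PatientProfile:
    """Reported medical history plus severity and subgroup tags.

    ``reported`` maps event id to "present"/"absent"; schema events not in
    the map are unreported and subject to imputation.
    """

    reported: Mapping[str, ReportStatus]
    severity: str
    subgroup_tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.severity not in SEVERITIES:
            raise ValueError(f"severity must be one of {SEVERITIES}")
        bad = {v for v in self.reported.values()} - {"present", "absent"}
        if bad:
            raise ValueError(f"invalid report statuses: {sorted(bad)}")


def impute_missing(
    profile: PatientProfile,
    imputation_models: Sequence[ImputationModel],
    schema_ids: Iterable[str],
    mode: ImputationMode = "expected",
) -> dict[str, float]:
    """Complete the event vector over the whole schema.

    Reported events are fixed at 1 (present) / 0 (absent) and never
    overwritten.  In ``expected`` mode, unreported events with an imputation
    model are filled in topological order with the logistic expectation given
    already-available values (still-missing predictors count as 0);
    unreported events without a model fall back to 0.  In ``assume-absent``
    mode every unreported event is 0, matching a deployment that treats
    unmentioned events as not having occurred.
    """
    schema_ids = list(schema_ids)
    unknown = set(profile.reported) - set(schema_ids)
    if unknown:
        raise KnowledgebaseError(
            f"profile reports events outside the schema: {sorted(unknown)[:5]}"
        )
    values: dict[str, float] = {
        ev: (1.0 if status == "present" else 0.0)
        for ev, status in profile.reported.items()
    }
    if mode == "expected":
        for model in _check_acyclic(list(imputation_models)):
            if model.target in values:
                continue  # reported; never overwrite
            values[model.target] = model.expected_value(values)
    elif mode != "assume-absent":
        raise ValueError(f"unknown imputation mode: {mode!r}")
    return {ev: values.get(ev, 0.0) for ev in schema_ids}


def predict_responses(
    completed: Mapping[str, float],
    kb: Knowledgebase,
    subgroup_tags: Iterable[str] = (),
) -> dict[str, float]:
    """Predicted response probability per drug via the routed models."""
    tags = tuple(subgroup_tags)
    return {
        drug: kb.resolve_model(drug, tags).predict_proba(completed)
        for drug in sorted(kb.models)
    }


@dataclass(frozen=True)
class Recommendation:
    """One of the four advice branches with its supporting probabilities."""

    branch: str  # no_antidepressant_low_severity | non_drug_options | either_of_two | single_drug
    drugs: tuple[str, ...]
    probabilities: Mapping[str, float]

    @property
    def top_probability(self) -> float:
        return max(self.probabilities.values()) if self.probabilities else 0.0


def recommend(
    probabilities: Mapping[str, float],
    severity: str,
    *,
    response_floor: float = RESPONSE_FLOOR,
    tie_window: float = TIE_WINDOW,
    floor_mode: Literal["absolute", "relative"] = "absolute",
    baseline_rate: float = 0.0,
) -> Recommendation:
    """Apply the recommendation rule cascade.

    The default (and deployed) reading of the 10% rule is an absolute
    predicted-probability floor; ``floor_mode="relative"`` instead requires
    the best drug to beat ``baseline_rate`` by more than the floor.  Ties
    inside the either-of-two window and among equal probabilities break by
    drug name.
    """
    if not probabilities:
        raise ValueError("empty probability map")
    if severity not in SEVERITIES:
        raise ValueError(f"severity must be one of {SEVERITIES}")
    probs = dict(probabilities)
    ranked = sorted(probs, key=lambda d: (-probs[d], d))

    if severity == "low":
        return Recommendation("no_antidepressant_low_severity", (), probs)

    top = ranked[0]
    if floor_mode == "absolute":
        clears_floor = probs[top] > response_floor
    else:
        clears_floor = probs[top] - baseline_rate > response_floor
    if not clears_floor:
        return Recommendation("non_drug_options", (), probs)

    if len(ranked) > 1 and probs[top] - probs[ranked[1]] <= tie_window:
        pair = tuple(sorted((top, ranked[1])))
        return Recommendation("either_of_two", pair, probs)
    return Recommendation("single_drug", (top,), probs)


@dataclass(frozen=True)
class Explanation:
    """Single-flip counterfactuals that change the recommendation.

    ``presence_flips``: events currently absent/unreported whose presence
    changes the advice; ``absence_flips``: reported-present events whose
    absence changes it.  Each entry pairs the event with the change it
    induces in the top predicted probability; lists are sorted by the
    magnitude of that change.
    """

    presence_flips: tuple[tuple[str, float], ...]
    absence_flips: tuple[tuple[str, float], ...]
    truncated: bool = False


def _with_flip(profile: PatientProfile, event: str, to_present: bool) -> PatientProfile:
    reported = dict(profile.reported)
    reported[event] = "present" if to_present else "absent"
    return PatientProfile(reported, profile.severity, profile.subgroup_tags)


def _advice_key(rec: Recommendation) -> tuple[str, frozenset[str]]:
    return rec.branch, frozenset(rec.drugs)


def explain(
    profile: PatientProfile,
    kb: Knowledgebase,
    recommendation: Recommendation,
    *,
    imputation_mode: ImputationMode = "assume-absent",
    max_events: int | None = None,
    **recommend_kwargs,
) -> Explanation:
    """Exhaustive one-flip counterfactual scan over schema events.

    Every candidate event is flipped (absent/unreported → present, or
    present → absent), the imputation + prediction + recommendation pipeline
    is re-run, and the event is listed iff the branch or the named drug set
    changes.  ``max_events`` caps the scan (in schema order) for very large
    schemas; the result is then flagged truncated.
    """
    schema_ids = sorted(kb.schema.events)
    if max_events is not None and len(schema_ids) > max_events:
        schema_ids, truncated = schema_ids[:max_events], True
    else:
        truncated = False

    base_key = _advice_key(recommendation)
    base_top = recommendation.top_probability
    presence, absence = [], []
    for ev in schema_ids:
        status = profile.reported.get(ev)
        to_present = status != "present"
        flipped_profile = _with_flip(profile, ev, to_present)
        completed = impute_missing(
            flipped_profile, kb.imputation_models, kb.schema.events,
            mode=imputation_mode,
        )
        probs = predict_responses(completed, kb, flipped_profile.subgroup_tags)
        rec = recommend(probs, profile.severity, **recommend_kwargs)
        if _advice_key(rec) != base_key:
            delta = rec.top_probability - base_top
            (presence if to_present else absence).append((ev, delta))

    presence.sort(key=lambda t: (-abs(t[1]), t[0]))
    absence.sort(key=lambda t: (-abs(t[1]), t[0]))
    return Explanation(tuple(presence), tuple(absence), truncated)


# ---------------------------------------------------------------------------
# document assembly — pre-set, non-generative templates only

_BRANCH_TEMPLATES = {
    "no_antidepressant_low_severity": (
        "Your depression severity is low. No antidepressant is recommended; "
        "consider established non-drug care for low-severity depression, "
        "including exercise."
    ),
    "non_drug_options": (
        "No common oral antidepressant reaches a 10% predicted chance of "
        "response for your history. Please discuss treatment options beyond "
        "common oral antidepressants with your clinician."
    ),
    "either_of_two": (
        "Two antidepressants have nearly identical predicted response rates "
        "for your history: {drugs}. Either is a reasonable choice; discuss "
        "both with your clinician."
    ),
    "single_drug": (
        "Based on your medical history, {drugs} has the highest predicted "
        "response rate ({rate:.0%})."
    ),
}


@dataclass
class AdviceDocument:
    """Four-section advice output plus bar-chart data.

    Sections: (1) summary of the relevant reported history, (2) the
    recommendation with predicted rates, (3) the counterfactual explanation,
    (4) per-recommended-drug information link slots.
    """

    history_summary: list[str]
    recommendation_branch: str
    recommendation_drugs: list[str]
    recommendation_text: str
    explanation_presence: list[list]
    explanation_absence: list[list]
    information_links: dict[str, str]
    bar_chart: dict[str, float]
    severity: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AdviceDocument":
        return cls(**json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def render_advice(
    profile: PatientProfile,
    kb: Knowledgebase,
    recommendation: Recommendation,
    explanation: Explanation,
    *,
    drug_links: Mapping[str, str] | None = None,
) -> AdviceDocument:
    """Assemble the four-section advice document from pre-set templates.

    ``drug_links`` is configuration data mapping drug name to a
    patient-facing information URL; link slots exist for every recommended
    drug and stay empty when no link is configured or no drug is recommended.
    """
    drug_links = drug_links or {}
    relevant = sorted(
        ev
        for ev, status in profile.reported.items()
        if status == "present"
        and any(ev in m.coefficients for m in kb.models.values())
    )
    drugs = list(recommendation.drugs)
    text = _BRANCH_TEMPLATES[recommendation.branch].format(
        drugs=" or ".join(drugs),
        rate=recommendation.probabilities.get(drugs[0], 0.0) if drugs else 0.0,
    )
    links = {d: drug_links.get(d, "") for d in drugs}
    return AdviceDocument(
        history_summary=relevant,
        recommendation_branch=recommendation.branch,
        recommendation_drugs=drugs,
        recommendation_text=text,
        explanation_presence=[[ev, delta] for ev, delta in explanation.presence_flips],
        explanation_absence=[[ev, delta] for ev, delta in explanation.absence_flips],
        information_links=links,
        bar_chart={d: float(p) for d, p in sorted(recommendation.probabilities.items())},
        severity=profile.severity,
    )


def advise(
    profile: PatientProfile,
    kb: Knowledgebase,
    *,
    imputation_mode: ImputationMode = "expected",
    drug_links: Mapping[str, str] | None = None,
    with_explanation: bool = True,
    max_explained_events: int | None = None,
    **recommend_kwargs,
) -> AdviceDocument:
    """End-to-end advice: impute, predict, recommend, explain, render."""
    completed = impute_missing(
        profile, kb.imputation_models, kb.schema.events, mode=imputation_mode
    )
    probs = predict_responses(completed, kb, profile.subgroup_tags)
    rec = recommend(probs, profile.severity, **recommend_kwargs)
    if with_explanation:
        expl = explain(
            profile, kb, rec,
            imputation_mode=imputation_mode,
            max_events=max_explained_events,
            **recommend_kwargs,
        )
    else:
        expl = Explanation((), ())
    return render_advice(profile, kb, rec, expl, drug_links=drug_links)
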