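"""Suicide-risk-factor aggregation and referral triage.

Upstream conversation monitoring flags any of 14 named suicide-risk-factor
categories.  This module owns the fixed taxonomy and the count-based triage
map: more than three distinct categories routes to a crisis line, one to
three engages a Safety Plan supporter, and zero needs no referral.  Repeated
mentions of one category count once.  Free-text detection itself happens
upstream; only category ids arrive here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

PATHWAYS = ("no_referral", "safety_plan_supporter", "crisis_line")

_CATEGORIES: tuple[tuple[int, str], ...] = (
    (1, "active suicidal ideation with method and plan"),
    (2, "passive suicidal ideation without a specific plan"),
    (3, "history of suicidal behavior or attempts"),
    (4, "non-suicidal self-injury"),
    (5, "thwarted belongingness or perceived burden to others"),
    (6, "persistent intolerable pain or acute exacerbation of mental illness"),
    (7, "new episode of eating disorder or borderline/antisocial personality disorder"),
    (8, "preparatory suicidal actions such as new access to means"),
    (9, "significant and severe lack of sleep"),
    (10, "adverse life events"),
    (11, "victimization"),
    (12, "poor quality of attachment to parents or nuclear family"),
    (13, "sexual or gender confusion"),
    (14, "increase in recklessness or impulsivity"),
)


class TriageError(ValueError):
    pass


@dataclass(frozen=True)
class RiskTaxonomy:
    """The fixed 14-category suicide-risk-factor catalog."""

    categories: dict[int, str] = field(
        default_factory=lambda: dict(_CATEGORIES)
    )

    def __post_init__(self) -> None:
        if sorted(self.categories) != list(range(1, 15)):
            raise TriageError("taxonomy must have exactly categories 1..14")

    def label(self, category_id: int) -> str:
        try:
            return self.categories[category_id]
        except KeyError:
            raise TriageError(f"unknown risk-factor category id: {category_id}") from None


def taxonomy() -> RiskTaxonomy:
    """The stable 14-category risk-factor catalog."""
    return RiskTaxonomy()


@dataclass(frozen=True)
class RiskAssessment:
    """Deduplicated detected categories, their count, and the pathway."""

    detected: frozenset[int]
    count: int
    pathway: str
    evidence: dict[int, str] = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["detected"] = sorted(self.detected)
        d["evidence"] = {str(k): v for k, v in self.evidence.items()}
        return json.dumps(d, indent=2, sort_keys=True)


def triage(
    detected: Iterable[int],
    *,
    crisis_threshold: int = 3,
    referral_threshold: int = 1,
    evidence: dict[int, str] | None = None,
) -> RiskAssessment:
    """Route a set of detected risk-factor categories to a referral pathway.

    A count exceeding ``crisis_threshold`` (default 3, the boundary that
    near-perfectly separates low from moderate/high risk) routes to the
    crisis line; a count of at least ``referral_threshold`` engages a Safety
    Plan supporter; below that, no referral.  Duplicate category mentions are
    collapsed before counting.
    """
    tax = taxonomy()
    ids = set(int(i) for i in detected)
    for i in ids:
        tax.label(i)  # raises on unknown ids
    count = len(ids)
    if count > crisis_threshold:
        pathway = "crisis_line"
    elif count >= referral_threshold:
        pathway = "safety_plan_supporter"
    else:
        pathway = "no_referral"
    ev = {i: (evidence or {}).get(i, "") for i in ids if evidence and i in evidence}
    return RiskAssessment(frozenset(ids), count, pathway, ev)
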