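"""Topic network and dialogue-state control for the intake conversation.

Long medical-history interviews need a manager that keeps the conversation
on track: it groups schema events into broad topics (demographics,
antidepressant history, comorbidities, ...), derives a directed acyclic
network of topic transitions from the knowledgebase's statistical
dependencies, and at each turn decides whether to *stay* on the current
topic, *advance* to the next one, *redirect* a digression back, or *end*.

The true production topic network is not derivable here; the derivation
implemented is the package's own reproducible stand-in: a cross-topic edge
is added whenever enough imputation-model dependencies (or drug-model
co-occurrences) link events of two topics, and edges are oriented by a fixed
topic priority so the result is acyclic by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from adrec.knowledgebase import Knowledgebase


class DialogueError(ValueError):
    pass


@dataclass(frozen=True)
class TopicNetwork:
    """Directed acyclic graph over conversation topics.

    ``priority`` fixes both the edge orientation (edges always point from
    higher to lower priority) and the advance order; ``edges`` maps
    (from, to) to a dependency weight.  The start topic is the
    highest-priority topic, which by construction has no incoming edges.
    """

    topics: tuple[str, ...]
    edges: Mapping[tuple[str, str], float]
    assignment: Mapping[str, str]  # event id -> topic
    per_topic_cap: int = 6

    def __post_init__(self) -> None:
        order = {t: i for i, t in enumerate(self.topics)}
        for a, b in self.edges:
            if a not in order or b not in order:
                raise DialogueError(f"edge ({a!r}, {b!r}) names unknown topic")
            if order[a] >= order[b]:
                raise DialogueError(
                    f"edge ({a!r}, {b!r}) violates priority orientation"
                )

    @property
    def start_topic(self) -> str:
        return self.topics[0]

    def predecessors(self, topic: str) -> list[str]:
        return [a for (a, b) in self.edges if b == topic]

    def topological_order(self) -> list[str]:
        # Priority order is a topological order by the orientation invariant.
        return list(self.topics)

    def to_dot(self) -> str:
        lines = ["digraph topics {"]
        for t in self.topics:
            lines.append(f'  "{t}";')
        for (a, b), w in sorted(self.edges.items()):
            lines.append(f'  "{a}" -> "{b}" [label="{w:g}"];')
        lines.append("}")
        return "\n".join(lines)

    def edge_list(self) -> str:
        """Plain node/edge list exchange format."""
        lines = [f"node\t{t}" for t in self.topics]
        lines += [f"edge\t{a}\t{b}\t{w:g}" for (a, b), w in sorted(self.edges.items())]
        return "\n".join(lines)


def build_topic_network(
    kb: Knowledgebase,
    assignment: Mapping[str, str],
    *,
    priority: Sequence[str] | None = None,
    threshold: float = 1.0,
    per_topic_cap: int = 6,
) -> TopicNetwork:
    """Derive a topic network from knowledgebase dependencies.

    Every schema event must be assigned to exactly one topic.  The weight
    between two topics counts cross-topic dependency pairs: a predictor in
    an imputation model whose target sits in another topic, and co-occurring
    nonzero predictors within one drug model.  Pairs reaching ``threshold``
    become edges, oriented from the higher-priority topic to the lower
    (priority defaults to first-appearance order in ``assignment``), which
    guarantees acyclicity.
    """
    missing = sorted(set(kb.schema.events) - set(assignment))
    if missing:
        raise DialogueError(f"events without a topic assignment: {missing[:10]}")
    if priority is None:
        seen: list[str] = []
        for t in assignment.values():
            if t not in seen:
                seen.append(t)
        priority = seen
    order = {t: i for i, t in enumerate(priority)}
    unknown = sorted(set(assignment.values()) - set(order))
    if unknown:
        raise DialogueError(f"assignment uses topics missing from priority: {unknown}")

    weights: dict[tuple[str, str], float] = {}

    def bump(t1: str, t2: str) -> None:
        if t1 == t2:
            return
        a, b = sorted((t1, t2), key=lambda t: order[t])
        weights[(a, b)] = weights.get((a, b), 0.0) + 1.0

    for im in kb.imputation_models:
        if im.target not in assignment:
            continue
        for pred in im.coefficients:
            if pred in assignment:
                bump(assignment[pred], assignment[im.target])
    for model in kb.models.values():
        evs = [e for e in model.coefficients if e in assignment]
        for i, e1 in enumerate(evs):
            for e2 in evs[i + 1:]:
                bump(assignment[e1], assignment[e2])

    edges = {pair: w for pair, w in weights.items() if w >= threshold}
    return TopicNetwork(
        topics=tuple(priority),
        edges=edges,
        assignment=dict(assignment),
        per_topic_cap=per_topic_cap,
    )


@dataclass(frozen=True)
class DialogueState:
    """Where the conversation stands: one current topic, coverage statuses."""

    current: str
    status: Mapping[str, str]  # topic -> unvisited | open | resolved
    digression: bool = False
    turns_on_topic: int = 0

    def with_digression(self, flag: bool = True) -> "DialogueState":
        return replace(self, digression=flag)


def start_dialogue(network: TopicNetwork) -> DialogueState:
    status = {t: "unvisited" for t in network.topics}
    status[network.start_topic] = "open"
    return DialogueState(current=network.start_topic, status=status)


@dataclass(frozen=True)
class Decision:
    """Controller output: the action and (for advances) the target topic."""

    action: str  # stay | advance | redirect | end
    topic: str | None = None


def next_topic(
    state: DialogueState,
    network: TopicNetwork,
    *,
    topic_resolved: bool = False,
) -> tuple[Decision, DialogueState]:
    """One controller step; returns the decision and the updated state.

    Precedence: an active digression is redirected back to the current
    topic; an unresolved current topic under the per-topic turn cap gets
    another turn (*stay*); otherwise the current topic is closed and the
    highest-priority unvisited topic whose predecessors are all resolved
    becomes current (*advance*); when everything is resolved the dialogue
    *ends*.  ``topic_resolved`` reports whether the current topic's events
    are now covered.
    """
    status = dict(state.status)
    if state.digression:
        return (
            Decision("redirect", state.current),
            replace(state, digression=False, turns_on_topic=state.turns_on_topic + 1),
        )
    if (
        status.get(state.current) == "open"
        and not topic_resolved
        and state.turns_on_topic < network.per_topic_cap
    ):
        return (
            Decision("stay", state.current),
            replace(state, turns_on_topic=state.turns_on_topic + 1),
        )
    # Current topic is finished (resolved or capped); never reopened.
    if status.get(state.current) == "open":
        status[state.current] = "resolved"
    for topic in network.topics:
        if status[topic] != "unvisited":
            continue
        if all(status[p] == "resolved" for p in network.predecessors(topic)):
            status[topic] = "open"
            return (
                Decision("advance", topic),
                DialogueState(current=topic, status=status),
            )
    return Decision("end", None), DialogueState(state.current, status)
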