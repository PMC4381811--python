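"""Scoring of the health terminology familiarity questionnaire.

The questionnaire has three sections covering the same four health topics,
two items per (section, topic) — six items per topic, 24 per participant.
Section 1 probes surface recognition of a term; sections 2 and 3 probe
conceptual understanding of consumer-friendly and advanced terminology.
A correct answer earns 0.15 points in section 1 and 0.175 in sections 2
and 3, so the per-topic score lies in [0, 1].  Topic familiarity labels:

* L1 (unfamiliar):        points <= 0.3
* L2 (somewhat familiar): 0.3 < points <= 0.65
* L3 (familiar):          points > 0.65

Arithmetic is done in integer milli-points (150 / 175 per correct item;
thresholds 300 and 650) so the inclusive boundaries at 0.3 and 0.65 are
classified exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "STATUSES",
    "SECTION_MILLIPOINTS",
    "QuestionnaireResponse",
    "FamiliarityScore",
    "score_topic",
    "label_participants",
    "group_counts",
]

STATUSES: tuple[str, ...] = ("correct", "incorrect", "unknown")

#: Milli-points awarded per correct item, by section.
SECTION_MILLIPOINTS: dict[int, int] = {1: 150, 2: 175, 3: 175}

_L1_MAX = 300   # points <= 0.3   -> L1
_L2_MAX = 650   # points <= 0.65  -> L2
_N_TOPICS = 4
_ITEMS_PER_SLOT = 2  # items per (section, topic)


@dataclass(frozen=True)
class QuestionnaireResponse:
    """One participant's answer status for one questionnaire item."""

    participant_id: str
    section: int
    topic_id: int
    item_index: int
    status: str

    def __post_init__(self) -> None:
        if self.section not in SECTION_MILLIPOINTS:
            raise ValueError(f"section {self.section!r} not in 1..3")
        if not 1 <= self.topic_id <= _N_TOPICS:
            raise ValueError(f"topic_id {self.topic_id!r} not in 1..4")
        if self.item_index not in (1, 2):
            raise ValueError(f"item_index {self.item_index!r} not in 1..2")
        if self.status not in STATUSES:
            raise ValueError(f"status {self.status!r} not in {STATUSES}")


@dataclass(frozen=True)
class FamiliarityScore:
    participant_id: str
    topic_id: int
    points: float
    label: str
    millipoints: int = 0


def _label_for(millipoints: int) -> str:
    if millipoints <= _L1_MAX:
        return "L1"
    if millipoints <= _L2_MAX:
        return "L2"
    return "L3"


def score_topic(responses: Iterable[QuestionnaireResponse]) -> FamiliarityScore:
    """Score one participant x topic from its six questionnaire items.

    Exactly two items per section must be present.  "unknown" scores 0,
    the same as "incorrect": the instrument asks respondents not to guess,
    and only correct answers earn points.
    """
    responses = list(responses)
    if not responses:
        raise ValueError("no responses supplied")
    pid = responses[0].participant_id
    topic = responses[0].topic_id
    seen: dict[tuple[int, int], QuestionnaireResponse] = {}
    for r in responses:
        if r.participant_id != pid or r.topic_id != topic:
            raise ValueError(
                "score_topic expects responses for a single participant and topic"
            )
        slot = (r.section, r.item_index)
        if slot in seen:
            raise ValueError(f"duplicate item (section {slot[0]}, item {slot[1]})")
        seen[slot] = r
    missing = [
        (sec, item)
        for sec in (1, 2, 3)
        for item in (1, 2)
        if (sec, item) not in seen
    ]
    if missing:
        raise ValueError(
            "incomplete topic questionnaire; missing (section, item) slots: "
            + ", ".join(map(str, missing))
        )
    milli = sum(
        SECTION_MILLIPOINTS[r.section]
        for r in seen.values()
        if r.status == "correct"
    )
    return FamiliarityScore(
        participant_id=pid,
        topic_id=topic,
        points=milli / 1000.0,
        label=_label_for(milli),
        millipoints=milli,
    )


def label_participants(
    all_responses: Iterable[QuestionnaireResponse],
) -> pd.DataFrame:
    """Score every participant x topic; returns a tidy label table.

    Each participant must have a complete 24-item questionnaire (6 items
    for each of the 4 topics); incomplete questionnaires raise with the
    missing slots named rather than being imputed.

    Returns a DataFrame with columns participant_id, topic_id, points,
    label — four rows per participant.
    """
    by_pt: dict[tuple[str, int], list[QuestionnaireResponse]] = {}
    participants: list[str] = []
    for r in all_responses:
        key = (r.participant_id, r.topic_id)
        by_pt.setdefault(key, []).append(r)
        if r.participant_id not in participants:
            participants.append(r.participant_id)
    rows = []
    for pid in participants:
        missing_topics = [t for t in range(1, _N_TOPICS + 1) if (pid, t) not in by_pt]
        if missing_topics:
            raise ValueError(
                f"participant {pid!r}: no responses for topics {missing_topics}"
            )
        for topic in range(1, _N_TOPICS + 1):
            score = score_topic(by_pt[(pid, topic)])
            rows.append(
                {
                    "participant_id": pid,
                    "topic_id": topic,
                    "points": score.points,
                    "label": score.label,
                }
            )
    return pd.DataFrame(rows, columns=["participant_id", "topic_id", "points", "label"])


def group_counts(labels: pd.DataFrame) -> pd.DataFrame:
    """Per-topic counts of L1/L2/L3 labels plus a Total row.

    ``labels`` is the table from :func:`label_participants`.  Row sums
    equal the number of participants per topic.
    """
    cols = ["L1", "L2", "L3"]
    if labels.empty:
        out = pd.DataFrame(0, index=pd.Index(range(1, _N_TOPICS + 1), name="topic_id"),
                           columns=cols)
    else:
        out = (
            labels.pivot_table(index="topic_id", columns="label",
                               values="participant_id", aggfunc="count", fill_value=0)
            .reindex(range(1, _N_TOPICS + 1), fill_value=0)
            .reindex(columns=cols, fill_value=0)
        )
        out.index.name = "topic_id"
    out.loc["Total"] = out.sum()
    return out.astype(int)
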