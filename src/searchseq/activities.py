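"""Activity alphabet, session containers, and descriptive statistics.

The unit of analysis is a *search activity*: one coded action a searcher
performs during a health information search session.  The closed alphabet
has 18 codes grouped into five stages — Querying, Accessing, Evaluating,
Using, Discarding.  A session is an ordered sequence of codes for one
participant working on one health topic; a corpus is a collection of
sessions, optionally partitioned into familiarity groups (L1 unfamiliar,
L2 somewhat familiar, L3 familiar).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "STAGES",
    "ACTIVITY_CODES",
    "CODE_STAGE",
    "STAGE_CODES",
    "USE_CODES",
    "ACCESS_CODES",
    "FAMILIARITY_LABELS",
    "SearchSession",
    "SessionCorpus",
    "FrequencyTable",
    "validate_session",
    "activity_frequencies",
    "search_efficiency",
]

STAGES: tuple[str, ...] = (
    "Querying",
    "Accessing",
    "Evaluating",
    "Using",
    "Discarding",
)

#: Canonical code -> stage map.  Codes are stored exactly as coded in the
#: scheme (stage prefix, colon, mixed case); near-misses are rejected, not
#: normalized, so corpora stay auditable.
CODE_STAGE: dict[str, str] = {
    "Q:AccSE": "Querying",
    "Q:AccHW": "Querying",
    "Q:NewQ": "Querying",
    "Q:ModQ": "Querying",
    "A:SelHI": "Accessing",
    "A:SelGI": "Accessing",
    "A:XplorF": "Accessing",
    "A:AccB": "Accessing",
    "E:ExamSR": "Evaluating",
    "E:DisSR": "Evaluating",
    "E:EvalI": "Evaluating",
    "E:FindQ": "Evaluating",
    "U:UseHI": "Using",
    "U:UseGI": "Using",
    "D:DisHI": "Discarding",
    "D:DisGI": "Discarding",
    "D:UnchkHI": "Discarding",
    "D:UnchkGI": "Discarding",
}

#: Fixed state order used everywhere a matrix or table is indexed by code.
ACTIVITY_CODES: tuple[str, ...] = tuple(CODE_STAGE)

STAGE_CODES: dict[str, tuple[str, ...]] = {
    stage: tuple(c for c in ACTIVITY_CODES if CODE_STAGE[c] == stage)
    for stage in STAGES
}

#: Information-use activities (numerator of search efficiency).
USE_CODES: tuple[str, ...] = ("U:UseHI", "U:UseGI")
#: Item-access activities (denominator of search efficiency).
ACCESS_CODES: tuple[str, ...] = ("A:SelHI", "A:SelGI", "A:XplorF", "A:AccB")

FAMILIARITY_LABELS: tuple[str, ...] = ("L1", "L2", "L3")


@dataclass(frozen=True)
class SearchSession:
    """One participant's ordered activity sequence for one health topic."""

    participant_id: str
    topic_id: int
    activities: tuple[str, ...]
    familiarity_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "activities", tuple(self.activities))

    def __len__(self) -> int:
        return len(self.activities)

    def with_label(self, label: str) -> "SearchSession":
        if label not in FAMILIARITY_LABELS:
            raise ValueError(f"unknown familiarity label: {label!r}")
        return replace(self, familiarity_label=label)


@dataclass
class SessionCorpus:
    """A collection of search sessions, possibly partitioned by label."""

    sessions: list[SearchSession] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self) -> Iterator[SearchSession]:
        return iter(self.sessions)

    @property
    def labels(self) -> tuple[str, ...]:
        """Labels present, in canonical L1/L2/L3 order."""
        present = {s.familiarity_label for s in self.sessions}
        return tuple(l for l in FAMILIARITY_LABELS if l in present)

    def group(self, label: str) -> "SessionCorpus":
        return SessionCorpus([s for s in self.sessions if s.familiarity_label == label])

    def groups(self) -> dict[str, "SessionCorpus"]:
        """Exhaustive, exclusive partition of labeled sessions by label."""
        self._require_labeled()
        return {l: self.group(l) for l in self.labels}

    def total_activities(self) -> int:
        return sum(len(s) for s in self.sessions)

    def _require_labeled(self) -> None:
        for s in self.sessions:
            if s.familiarity_label is None:
                raise ValueError(
                    f"session ({s.participant_id!r}, topic {s.topic_id}) has no "
                    "familiarity label"
                )


def validate_session(session: SearchSession) -> list[str]:
    """Check a session against the closed 18-code alphabet.

    Returns a list of human-readable violation descriptors; an empty list
    means the session is valid.  Violations are returned rather than raised
    so that a corpus reader can exclude and report bad sessions, mirroring
    the restriction of the analysis to qualified session data.
    """
    violations: list[str] = []
    if len(session.activities) == 0:
        violations.append("empty session")
        return violations
    for step, code in enumerate(session.activities, start=1):
        if code not in CODE_STAGE:
            violations.append(f"step {step}: unknown activity code {code!r}")
    if not isinstance(session.topic_id, int) or not 1 <= session.topic_id <= 4:
        violations.append(f"topic_id {session.topic_id!r} not in 1..4")
    return violations


@dataclass
class FrequencyTable:
    """Per-group activity counts and within-group shares.

    ``table`` has one row per activity code (fixed order) and a two-level
    column index ``(group, {count, share})``.  Shares within a group sum
    to 1.
    """

    table: pd.DataFrame

    def count(self, group: str, code: str) -> int:
        return int(self.table.loc[code, (group, "count")])

    def share(self, group: str, code: str) -> float:
        return float(self.table.loc[code, (group, "share")])

    def group_total(self, group: str) -> int:
        return int(self.table[(group, "count")].sum())

    def stage_share(self, group: str, stage: str) -> float:
        """Summed share of all codes in one stage for one group."""
        codes = STAGE_CODES[stage]
        return float(self.table.loc[list(codes), (group, "share")].sum())

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def activity_frequencies(corpus: SessionCorpus) -> FrequencyTable:
    """Tally each activity code per familiarity group, with group shares.

    Every session must be labeled.  The group total equals the sum of that
    group's session lengths (conservation).
    """
    corpus._require_labeled()
    cols = {}
    for label, group in corpus.groups().items():
        tally = Counter()
        for s in group:
            tally.update(s.activities)
        counts = pd.Series([tally.get(c, 0) for c in ACTIVITY_CODES],
                           index=list(ACTIVITY_CODES), dtype=int)
        total = int(counts.sum())
        shares = counts / total if total else counts.astype(float)
        cols[(label, "count")] = counts
        cols[(label, "share")] = shares
    table = pd.DataFrame(cols)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["group", "stat"])
    return FrequencyTable(table)


def _counts(sessions: Iterable[SearchSession]) -> Counter:
    tally: Counter = Counter()
    for s in sessions:
        tally.update(s.activities)
    return tally


def search_efficiency(corpus_group: SessionCorpus | Sequence[SearchSession]) -> float:
    """Ratio of information-use activities to item-access activities.

    efficiency = (#U:UseHI + #U:UseGI) / (#A:SelHI + #A:SelGI + #A:XplorF + #A:AccB)

    Raises ``ValueError`` when the group contains no accessing activity
    (the ratio is undefined).
    """
    tally = _counts(corpus_group)
    uses = sum(tally.get(c, 0) for c in USE_CODES)
    accesses = sum(tally.get(c, 0) for c in ACCESS_CODES)
    if accesses == 0:
        raise ValueError("search efficiency undefined: no accessing-stage activities")
    return uses / accesses
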