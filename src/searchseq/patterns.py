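"""Frequent fixed-length activity patterns and behavioral categories.

After the model order is selected, common behavior is summarized by
counting every contiguous window of n activities inside sessions
(windows are unpadded: listed patterns consist solely of activity
codes), ranking the most frequent windows per familiarity group, and
tagging each pattern with four rule-based behavioral categories:

1. query-then-single-access-and-evaluate: a querying prefix (access a
   search engine or health website, then a new/modified query) followed
   in the window by exactly one health-item selection and an evaluation;
2. query-then-multiple-access: a querying prefix followed by two or more
   consecutive accessing-stage activities;
3. relevancy assessment: an evaluation immediately followed by a use or
   discard judgement of the visited page;
4. search continuation: information use followed later in the window by
   any querying activity or re-examination of the results.

A pattern can match several categories; ``none`` means no rule fired.
The rule set is versioned so tags are reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .activities import CODE_STAGE, SearchSession, SessionCorpus

__all__ = [
    "RULESET_VERSION",
    "PatternTable",
    "PatternCategory",
    "extract_windows",
    "top_patterns",
    "categorize_pattern",
    "group_pattern_summary",
]

RULESET_VERSION = "1"

_QUERY_STARTS = ("Q:AccSE", "Q:AccHW")
_QUERY_SUBMITS = ("Q:NewQ", "Q:ModQ")
_JUDGEMENTS = ("U:UseHI", "U:UseGI", "D:DisHI", "D:DisGI")


@dataclass
class PatternTable:
    """Ranked n-gram windows with frequencies and shares for one group.

    ``rows`` columns: rank, pattern (tuple of codes), frequency,
    share_percent (of all token windows in the group), categories.
    ``distinct_pattern_count`` is the number of distinct window types
    observed; ``window_total`` the number of token windows.
    """

    n: int
    group: str
    rows: pd.DataFrame
    distinct_pattern_count: int
    window_total: int

    def to_frame(self) -> pd.DataFrame:
        out = self.rows.copy()
        out["pattern"] = out["pattern"].map(lambda p: "–".join(p))
        out["categories"] = out["categories"].map(
            lambda cats: ",".join(map(str, cats)) if cats else "none"
        )
        return out


@dataclass(frozen=True)
class PatternCategory:
    categories: tuple[int, ...]
    ruleset_version: str = RULESET_VERSION

    @property
    def is_none(self) -> bool:
        return not self.categories


def extract_windows(
    corpus_group: SessionCorpus | Sequence[SearchSession],
    n: int,
    group: str = "",
) -> PatternTable:
    """Count every contiguous window of n activities within sessions.

    A session of length L contributes max(0, L - n + 1) windows; sessions
    shorter than n contribute none.  Windows never cross session
    boundaries and use no start/end markers.
    """
    if n < 2:
        raise ValueError("window length n must be >= 2")
    tally: Counter = Counter()
    for session in corpus_group:
        acts = session.activities
        for i in range(len(acts) - n + 1):
            tally[acts[i:i + n]] += 1
    total = sum(tally.values())
    rows = pd.DataFrame(
        {
            "pattern": list(tally.keys()),
            "frequency": list(tally.values()),
        }
    )
    if not rows.empty:
        rows["share_percent"] = 100.0 * rows["frequency"] / total
        rows["categories"] = rows["pattern"].map(
            lambda p: categorize_pattern(p).categories
        )
    else:
        rows = pd.DataFrame(
            columns=["pattern", "frequency", "share_percent", "categories"]
        )
    return PatternTable(
        n=n,
        group=group,
        rows=rows,
        distinct_pattern_count=len(tally),
        window_total=total,
    )


def top_patterns(table: PatternTable, k: int = 20) -> PatternTable:
    """Top-k patterns by frequency; ties break lexicographically on codes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = table.rows.copy()
    if not rows.empty:
        order = sorted(
            rows.index, key=lambda i: (-rows.at[i, "frequency"], rows.at[i, "pattern"])
        )
        rows = rows.loc[order[:k]].reset_index(drop=True)
        rows.insert(0, "rank", range(1, len(rows) + 1))
    else:
        rows.insert(0, "rank", [])
    return PatternTable(
        n=table.n,
        group=table.group,
        rows=rows,
        distinct_pattern_count=table.distinct_pattern_count,
        window_total=table.window_total,
    )


def _query_prefix_positions(pattern: Sequence[str]) -> list[int]:
    """Indices i where pattern[i] starts a search-engine/website + query pair."""
    return [
        i
        for i in range(len(pattern) - 1)
        if pattern[i] in _QUERY_STARTS and pattern[i + 1] in _QUERY_SUBMITS
    ]


def categorize_pattern(pattern: Sequence[str]) -> PatternCategory:
    """Deterministic rule-based tagging; total over all patterns."""
    p = tuple(pattern)
    if len(p) < 2:
        raise ValueError("pattern length must be >= 2")
    cats: list[int] = []

    prefixes = _query_prefix_positions(p)

    # Category 1: querying prefix, then exactly one A:SelHI and an E:EvalI.
    for i in prefixes:
        tail = p[i + 2:]
        if tail.count("A:SelHI") == 1 and "E:EvalI" in tail:
            cats.append(1)
            break

    # Category 2: querying prefix, then >= 2 consecutive accessing codes.
    def _has_access_run(tail: tuple[str, ...]) -> bool:
        run = 0
        for code in tail:
            run = run + 1 if CODE_STAGE[code] == "Accessing" else 0
            if run >= 2:
                return True
        return False

    if any(_has_access_run(p[i + 2:]) for i in prefixes):
        cats.append(2)

    # Category 3: E:EvalI immediately followed by a use/discard judgement.
    if any(
        p[i] == "E:EvalI" and p[i + 1] in _JUDGEMENTS
        for i in range(len(p) - 1)
    ):
        cats.append(3)

    # Category 4: information use followed later by querying or E:ExamSR.
    for i, code in enumerate(p[:-1]):
        if code in ("U:UseHI", "U:UseGI") and any(
            CODE_STAGE[later] == "Querying" or later == "E:ExamSR"
            for later in p[i + 1:]
        ):
            cats.append(4)
            break

    return PatternCategory(tuple(cats))


def group_pattern_summary(
    corpus: SessionCorpus, n: int, k: int = 20
) -> tuple[dict[str, PatternTable], pd.DataFrame]:
    """Per-group top-k pattern tables plus a category share comparison.

    The category table reports, per group and category, the summed share
    (percent of all token windows) of top-k patterns matching that
    category.  An empty group yields an empty table.
    """
    tables: dict[str, PatternTable] = {}
    cat_rows = []
    for label, group in corpus.groups().items():
        table = top_patterns(extract_windows(group, n, group=label), k)
        tables[label] = table
        for cat in (1, 2, 3, 4):
            if table.rows.empty:
                share = 0.0
                freq = 0
            else:
                match = table.rows["categories"].map(lambda c: cat in c)
                share = float(table.rows.loc[match, "share_percent"].sum())
                freq = int(table.rows.loc[match, "frequency"].sum())
            cat_rows.append(
                {"group": label, "category": cat, "frequency": freq,
                 "share_percent": share}
            )
    return tables, pd.DataFrame(cat_rows)
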