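"""First-order Markov transition matrices over activity sequences.

Counts f_ij tally observed moves from activity i directly to activity j
within a session (transitions never cross session boundaries); row-wise
normalization gives the first-order transition probabilities p_ij.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .activities import ACTIVITY_CODES, SearchSession, SessionCorpus

__all__ = [
    "TransitionMatrix",
    "TransitionReport",
    "transition_counts",
    "top_transitions",
    "mean_transition_stats",
]


@dataclass
class TransitionMatrix:
    """K x K transition counts and row-stochastic probabilities.

    ``state_order`` fixes the row/column ordering; by default the 18
    activity codes in coding-scheme order.  Rows with zero total have
    all-zero probability rows (the comparison test accounts for the
    resulting structural zeros explicitly).
    """

    counts: np.ndarray
    state_order: tuple[str, ...] = ACTIVITY_CODES
    total_override: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.state_order)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} states"
            )
        if (self.counts < 0).any():
            raise ValueError("negative transition counts")

    @property
    def k(self) -> int:
        return len(self.state_order)

    @property
    def total_transitions(self) -> int:
        """Sum of all counts, unless an externally printed total is supplied.

        An override supports arithmetic on partially published matrices
        (e.g. a top-10 table printed together with its group total).
        """
        if self.total_override is not None:
            return self.total_override
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def probabilities(self) -> np.ndarray:
        totals = self.row_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(totals[:, None] > 0, self.counts / totals[:, None], 0.0)
        return p

    def index_of(self, code: str) -> int:
        return self.state_order.index(code)

    def count(self, from_code: str, to_code: str) -> int:
        return int(self.counts[self.index_of(from_code), self.index_of(to_code)])

    def probability(self, from_code: str, to_code: str) -> float:
        return float(self.probabilities[self.index_of(from_code), self.index_of(to_code)])

    def to_frame(self, probabilities: bool = False) -> pd.DataFrame:
        data = self.probabilities if probabilities else self.counts
        idx = pd.Index(self.state_order, name="from")
        return pd.DataFrame(data, index=idx, columns=list(self.state_order))

    @classmethod
    def from_cells(
        cls,
        cells: dict[tuple[str, str], int],
        state_order: Sequence[str] = ACTIVITY_CODES,
        total_override: int | None = None,
    ) -> "TransitionMatrix":
        """Build a matrix from sparse (from, to) -> count cells."""
        order = tuple(state_order)
        pos = {c: i for i, c in enumerate(order)}
        counts = np.zeros((len(order), len(order)), dtype=int)
        for (a, b), n in cells.items():
            counts[pos[a], pos[b]] = n
        return cls(counts, order, total_override)


@dataclass
class TransitionReport:
    """Ranked transition table (descending frequency) with group shares."""

    rows: pd.DataFrame            # rank, from, to, frequency, share_percent
    total_transitions: int
    cumulative_frequency: int
    cumulative_share_percent: float

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def _session_pairs(session: SearchSession) -> Iterable[tuple[str, str]]:
    acts = session.activities
    return zip(acts[:-1], acts[1:])


def transition_counts(
    corpus_group: SessionCorpus | Sequence[SearchSession],
    state_order: Sequence[str] = ACTIVITY_CODES,
) -> TransitionMatrix:
    """Count first-order transitions over all sessions in a group.

    Each session of length L contributes L - 1 transitions; no transition
    is counted across a session boundary.  Raises if no session has
    length >= 2 (no transitions exist).
    """
    order = tuple(state_order)
    pos = {c: i for i, c in enumerate(order)}
    counts = np.zeros((len(order), len(order)), dtype=int)
    any_pair = False
    for session in corpus_group:
        for a, b in _session_pairs(session):
            counts[pos[a], pos[b]] += 1
            any_pair = True
    if not any_pair:
        raise ValueError("no transitions: every session has length < 2")
    return TransitionMatrix(counts, order)


def top_transitions(
    matrix: TransitionMatrix, k: int, total: int | None = None
) -> TransitionReport:
    """Top-k transitions by frequency, with shares of the group total.

    Ties are broken by (from-code, to-code) lexicographic order on the
    canonical code strings so reports are deterministic.  ``total``
    overrides the share denominator (e.g. a published group total when
    only the top cells of a matrix are known).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    denom = total if total is not None else matrix.total_transitions
    entries = []
    for i, a in enumerate(matrix.state_order):
        for j, b in enumerate(matrix.state_order):
            n = int(matrix.counts[i, j])
            if n > 0:
                entries.append((a, b, n))
    entries.sort(key=lambda e: (-e[2], e[0], e[1]))
    top = entries[:k]
    rows = pd.DataFrame(
        {
            "rank": range(1, len(top) + 1),
            "from": [e[0] for e in top],
            "to": [e[1] for e in top],
            "frequency": [e[2] for e in top],
            "share_percent": [100.0 * e[2] / denom for e in top],
        }
    )
    cum = int(sum(e[2] for e in top))
    return TransitionReport(
        rows=rows,
        total_transitions=denom,
        cumulative_frequency=cum,
        cumulative_share_percent=100.0 * cum / denom,
    )


def mean_transition_stats(
    corpus_group: SessionCorpus | Sequence[SearchSession],
) -> tuple[float, float]:
    """Mean and SD of counts over ordered pairs observed at least once.

    The SD uses the population denominator (ddof=0) over the multiset of
    positive cell counts; the convention is recorded here because either
    choice is defensible for a descriptive table.
    """
    matrix = transition_counts(corpus_group)
    cells = matrix.counts[matrix.counts > 0].astype(float)
    return float(cells.mean()), float(cells.std(ddof=0))
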