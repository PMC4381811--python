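"""Chi-square comparison of two transition-frequency matrices.

Following the Markov-chain comparison procedure of Chen & Cooper, one
sample (A) serves as the reference and the other (B) as the tested
sample.  Expected counts for B under A's kernel are

    E_ij = (B's row-i total) * p_ij^A                              (1)

and the statistic is the Pearson sum over cells with positive
expectation,

    C = sum_{E_ij > 0} (f_ij^B - E_ij)^2 / E_ij.                   (2)

C approximately follows a chi-square distribution with

    df = K^2 - N1 - N2,

where K is the number of states in the state space, N1 the number of
actual states in B, and N2 the number of impossible transitions (cells
excluded because their expected count is zero).  The null hypothesis of
no difference between the transition probability matrices is rejected
when C exceeds the upper-tail critical value at the chosen significance
level.

The chi-square approximation treats the reference kernel as known, so it
is most accurate when sample A is large relative to B; with comparable
sizes the test is anticonservative (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .activities import SessionCorpus
from .transitions import TransitionMatrix, transition_counts

__all__ = [
    "DEFAULT_ALPHA",
    "ExpectedMatrix",
    "ChiSquareComparison",
    "expected_transitions",
    "chi_square_score",
    "degrees_of_freedom",
    "critical_value",
    "compare_matrices",
    "compare_groups",
]

#: Table-style critical values correspond to the 0.001 upper tail.
DEFAULT_ALPHA = 0.001


@dataclass
class ExpectedMatrix:
    """Expected transition counts for sample B under sample A's kernel."""

    expected: np.ndarray
    state_order: tuple[str, ...]
    #: Rows occupied by B for which A has no observed transitions; their
    #: expectations are structurally zero and all their cells are excluded.
    undefined_rows: tuple[str, ...]


def expected_transitions(A: TransitionMatrix, B: TransitionMatrix) -> ExpectedMatrix:
    """E_ij = (B row-i total) x p_ij^A, per Equation (1).

    Rows where A has zero total produce all-zero expectation rows and are
    flagged; each remaining row of E sums to B's observed row total.
    """
    if A.state_order != B.state_order:
        raise ValueError("state orders of A and B differ")
    b_rows = B.row_totals.astype(float)
    expected = b_rows[:, None] * A.probabilities
    undefined = tuple(
        code
        for i, code in enumerate(A.state_order)
        if b_rows[i] > 0 and A.row_totals[i] == 0
    )
    return ExpectedMatrix(expected, A.state_order, undefined)


def chi_square_score(B: TransitionMatrix, E: ExpectedMatrix) -> tuple[float, int]:
    """Pearson sum over cells with positive expectation, per Equation (2).

    Returns ``(C, cells_used)``; cells with E_ij = 0 are excluded from
    the sum (they count toward N2 in the df bookkeeping).
    """
    if B.state_order != E.state_order:
        raise ValueError("state orders of B and E differ")
    mask = E.expected > 0
    diff = B.counts[mask] - E.expected[mask]
    c = float(np.sum(diff * diff / E.expected[mask]))
    return c, int(mask.sum())


def degrees_of_freedom(K: int, N1: int, N2: int) -> int:
    """df = K^2 - N1 - N2; raises on a degenerate (nonpositive) result."""
    df = K * K - N1 - N2
    if df < 1:
        raise ValueError(
            f"degenerate comparison: K^2 - N1 - N2 = {df} (need >= 1)"
        )
    return df


def critical_value(df: int, alpha: float) -> float:
    """Upper-tail chi-square quantile at significance ``alpha``."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.chi2.ppf(1.0 - alpha, df))


@dataclass
class DirectionResult:
    """One direction of the comparison: reference A, tested B."""

    reference: str
    tested: str
    C: float
    K: int
    N1: int
    N2: int
    df: int
    cells_used: int
    critical_value: float
    reject_null: bool


@dataclass
class ChiSquareComparison:
    """Both directions of a pairwise comparison; reported = max-C direction.

    The underlying procedure is directional and the study does not state
    which sample served as reference, so both directions are computed and
    the maximum-C direction is reported by default.
    """

    directions: tuple[DirectionResult, DirectionResult]
    alpha: float

    @property
    def reported(self) -> DirectionResult:
        return max(self.directions, key=lambda d: d.C)

    def __getattr__(self, name):
        # delegate C, df, reject_null, ... to the reported direction
        reported = max(self.__dict__["directions"], key=lambda d: d.C)
        return getattr(reported, name)

    def to_dict(self) -> dict:
        r = self.reported
        return {
            "groups": [r.reference, r.tested],
            "direction": f"{r.reference}->{r.tested}",
            "C": r.C,
            "K": r.K,
            "N1": r.N1,
            "N2": r.N2,
            "df": r.df,
            "alpha": self.alpha,
            "critical_value": r.critical_value,
            "reject_null": r.reject_null,
            "cells_used": r.cells_used,
        }


def _one_direction(
    A: TransitionMatrix,
    B: TransitionMatrix,
    alpha: float,
    name_a: str,
    name_b: str,
) -> DirectionResult:
    E = expected_transitions(A, B)
    C, cells_used = chi_square_score(B, E)
    K = B.k
    occupied = (B.row_totals > 0) | (B.counts.sum(axis=0) > 0)
    N1 = int(occupied.sum())          # actual states appearing in B
    N2 = K * K - cells_used           # impossible (zero-expectation) cells
    df = degrees_of_freedom(K, N1, N2)
    crit = critical_value(df, alpha)
    return DirectionResult(
        reference=name_a,
        tested=name_b,
        C=C,
        K=K,
        N1=N1,
        N2=N2,
        df=df,
        cells_used=cells_used,
        critical_value=crit,
        reject_null=C > crit,
    )


def compare_matrices(
    A: TransitionMatrix,
    B: TransitionMatrix,
    alpha: float = DEFAULT_ALPHA,
    name_a: str = "A",
    name_b: str = "B",
) -> ChiSquareComparison:
    """Pairwise chi-square comparison of two transition matrices."""
    return ChiSquareComparison(
        directions=(
            _one_direction(A, B, alpha, name_a, name_b),
            _one_direction(B, A, alpha, name_b, name_a),
        ),
        alpha=alpha,
    )


def compare_groups(
    corpus_a: SessionCorpus,
    corpus_b: SessionCorpus,
    alpha: float = DEFAULT_ALPHA,
    name_a: str = "A",
    name_b: str = "B",
) -> ChiSquareComparison:
    """Compare the transition structure of two session corpora."""
    return compare_matrices(
        transition_counts(corpus_a),
        transition_counts(corpus_b),
        alpha=alpha,
        name_a=name_a,
        name_b=name_b,
    )
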