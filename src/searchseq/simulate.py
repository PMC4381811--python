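"""Synthetic session and questionnaire generator.

Raw session transcripts from the study are unpublished, so this module
generates labeled corpora with the statistical structure the analysis
assumes.  Per-group first-order kernels are anchored on the published
top-10 transition counts; unpublished cells are filled with plausible
flows consistent with the published per-activity frequencies (item
selections split between health and general websites, information-use
totals, stage shares) and with the narrative structure of a search
session (sessions start at a search engine or a known health website;
discarding leads back to querying or re-examination; sessions end after
an information-use activity).  The fill is calibration, not ground
truth.

Session lengths are controlled by a per-profile stop probability applied
after each information-use activity (with a minimum length of 6 and a
cap of 221, the published range).  Per-group session counts and mean
lengths follow from the published arithmetic: group activity totals
minus group transition totals give 61/51/48 sessions, hence mean lengths
2424/61 = 39.7, 1204/51 = 23.6 and 967/48 = 20.1 (overall 4595/160 =
28.7, the published corpus-level mean).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .activities import (
    ACTIVITY_CODES,
    USE_CODES,
    SearchSession,
    SessionCorpus,
)
from .familiarity import QuestionnaireResponse

__all__ = [
    "GeneratorProfile",
    "SimulationConfig",
    "default_profiles",
    "lagged_profile",
    "simulate_session",
    "simulate_corpus",
    "simulate_questionnaire",
    "DEFAULT_SESSIONS_PER_GROUP",
]

#: Derived from published totals: activities minus transitions per group.
DEFAULT_SESSIONS_PER_GROUP: dict[str, int] = {"L1": 61, "L2": 51, "L3": 48}

_LENGTH_TARGETS: dict[str, tuple[float, float]] = {
    # (mean, sd) targets per group; means follow from published arithmetic,
    # SDs take the published corpus-level dispersion as a common anchor.
    "L1": (2424 / 61, 23.27),
    "L2": (1204 / 51, 23.27),
    "L3": (967 / 48, 23.27),
}

_MIN_LEN, _MAX_LEN = 6, 221


# ---------------------------------------------------------------------
# Anchored per-group transition flows.  Cells marked by the top-10 tables
# carry the published counts; remaining cells are calibrated fill (see
# module docstring and docs/methods.md).

_FLOWS: dict[str, dict[str, dict[str, int]]] = {
    "L1": {
        "Q:AccSE": {"Q:ModQ": 121, "Q:NewQ": 75},
        "Q:AccHW": {"Q:NewQ": 2},
        "Q:NewQ": {"E:ExamSR": 75, "E:DisSR": 7},
        "Q:ModQ": {"E:ExamSR": 158, "E:DisSR": 17},
        "A:SelHI": {"E:EvalI": 181, "A:SelHI": 44, "A:XplorF": 19,
                    "D:UnchkHI": 18, "E:FindQ": 14, "A:AccB": 1},
        "A:SelGI": {"E:EvalI": 70, "A:SelGI": 15, "D:UnchkGI": 7, "A:AccB": 7},
        "A:XplorF": {"E:EvalI": 91, "E:FindQ": 11, "A:XplorF": 8, "A:AccB": 5},
        "A:AccB": {"E:EvalI": 47, "A:SelHI": 27, "E:ExamSR": 11, "A:SelGI": 8},
        "E:ExamSR": {"A:SelHI": 188, "A:SelGI": 70, "Q:ModQ": 29, "E:DisSR": 23},
        "E:DisSR": {"Q:AccSE": 21, "Q:ModQ": 20, "Q:NewQ": 7},
        "E:EvalI": {"D:DisHI": 160, "U:UseHI": 120, "A:XplorF": 88,
                    "E:FindQ": 19, "D:DisGI": 18, "U:UseGI": 17,
                    "A:AccB": 8, "E:ExamSR": 1},
        "E:FindQ": {"E:EvalI": 41, "U:UseHI": 1, "D:DisHI": 1},
        "U:UseHI": {"Q:AccSE": 39, "A:AccB": 20, "E:ExamSR": 13, "Q:ModQ": 1},
        "U:UseGI": {"Q:AccSE": 1, "E:ExamSR": 1, "A:AccB": 1},
        "D:DisHI": {"Q:AccSE": 68, "E:ExamSR": 48, "A:AccB": 41, "Q:ModQ": 4},
        "D:DisGI": {"A:AccB": 10, "Q:AccSE": 7, "E:ExamSR": 1},
        "D:UnchkHI": {"A:SelHI": 17, "E:ExamSR": 1},
        "D:UnchkGI": {"A:SelGI": 6, "E:ExamSR": 1},
    },
    "L2": {
        "Q:AccSE": {"Q:NewQ": 63, "Q:ModQ": 52},
        "Q:AccHW": {"Q:NewQ": 2},
        "Q:NewQ": {"E:ExamSR": 64, "E:DisSR": 5},
        "Q:ModQ": {"E:ExamSR": 75, "E:DisSR": 9},
        "A:SelHI": {"E:EvalI": 101, "A:SelHI": 40, "A:XplorF": 9,
                    "E:FindQ": 8, "D:UnchkHI": 6},
        "A:SelGI": {"E:EvalI": 39, "A:SelGI": 6, "D:UnchkGI": 1, "A:AccB": 1},
        "A:XplorF": {"E:EvalI": 28, "A:AccB": 1, "E:FindQ": 1},
        "A:AccB": {"E:EvalI": 20, "E:ExamSR": 7, "A:SelHI": 6, "A:SelGI": 4},
        "E:ExamSR": {"A:SelHI": 113, "A:SelGI": 29, "Q:ModQ": 15, "E:DisSR": 12},
        "E:DisSR": {"Q:ModQ": 11, "Q:AccSE": 8, "Q:NewQ": 6},
        "E:EvalI": {"U:UseHI": 94, "D:DisHI": 36, "A:XplorF": 21,
                    "U:UseGI": 18, "E:FindQ": 16, "D:DisGI": 12,
                    "A:AccB": 10, "E:ExamSR": 4},
        "E:FindQ": {"E:EvalI": 23, "U:UseHI": 1, "D:DisHI": 1},
        "U:UseHI": {"Q:AccSE": 29, "E:ExamSR": 11, "A:AccB": 7, "Q:ModQ": 6},
        "U:UseGI": {"Q:AccSE": 5, "E:ExamSR": 1, "A:AccB": 1},
        "D:DisHI": {"Q:AccSE": 18, "A:AccB": 10, "E:ExamSR": 8},
        "D:DisGI": {"Q:AccSE": 6, "A:AccB": 4, "E:ExamSR": 1},
        "D:UnchkHI": {"A:SelHI": 5, "E:ExamSR": 1},
        "D:UnchkGI": {"A:SelGI": 5},
    },
    "L3": {
        "Q:AccSE": {"Q:NewQ": 48, "Q:ModQ": 35},
        "Q:AccHW": {"E:EvalI": 12, "E:FindQ": 6, "Q:NewQ": 4},
        "Q:NewQ": {"E:ExamSR": 56, "E:DisSR": 2},
        "Q:ModQ": {"E:ExamSR": 44, "E:DisSR": 5},
        "A:SelHI": {"E:EvalI": 101, "A:SelHI": 44, "D:UnchkHI": 3,
                    "A:XplorF": 3, "E:FindQ": 1},
        "A:SelGI": {"E:EvalI": 19, "A:SelGI": 2, "D:UnchkGI": 1},
        "A:XplorF": {"E:EvalI": 24, "A:AccB": 1, "E:FindQ": 1},
        "A:AccB": {"E:EvalI": 13, "E:ExamSR": 4},
        "E:ExamSR": {"A:SelHI": 102, "A:SelGI": 21, "E:DisSR": 9, "Q:ModQ": 6},
        "E:DisSR": {"Q:AccSE": 6, "Q:NewQ": 6, "Q:ModQ": 3},
        "E:EvalI": {"U:UseHI": 81, "D:DisHI": 51, "A:XplorF": 21,
                    "U:UseGI": 15, "E:FindQ": 6, "D:DisGI": 4,
                    "E:ExamSR": 3, "A:AccB": 1},
        "E:FindQ": {"E:EvalI": 12, "U:UseHI": 2},
        "U:UseHI": {"Q:AccSE": 14, "E:ExamSR": 12, "A:AccB": 6,
                    "Q:AccHW": 6, "Q:ModQ": 5},
        "U:UseGI": {"Q:AccSE": 3, "E:ExamSR": 1, "A:AccB": 1},
        "D:DisHI": {"Q:AccSE": 19, "E:ExamSR": 16, "A:AccB": 8, "Q:AccHW": 7},
        "D:DisGI": {"Q:AccSE": 2, "E:ExamSR": 1},
        "D:UnchkHI": {"A:SelHI": 4, "E:ExamSR": 1},
        "D:UnchkGI": {"E:ExamSR": 1},
    },
}

#: Start distributions over {Q:AccSE, Q:AccHW}.  The familiar group
#: sometimes starts at a known consumer health website; the others
#: essentially never do.
_START_PROBS: dict[str, dict[str, float]] = {
    "L1": {"Q:AccSE": 0.99, "Q:AccHW": 0.01},
    "L2": {"Q:AccSE": 0.97, "Q:AccHW": 0.03},
    "L3": {"Q:AccSE": 0.80, "Q:AccHW": 0.20},
}

#: Per-visit stop probability after an information-use activity,
#: calibrated numerically so simulated mean lengths hit the per-group
#: targets (see docs/methods.md).
_STOP_PROBS: dict[str, float] = {
    "L1": 0.399,
    "L2": 0.441,
    "L3": 0.505,
}


@dataclass
class GeneratorProfile:
    """Sampling recipe for one familiarity group's sessions.

    ``kernel`` is a row-stochastic matrix over ``states`` for a
    first-order generator (``kernel_order == 1``), or a mapping from
    length-``kernel_order`` history tuples to probability vectors for a
    higher-order generator (unlisted histories fall back to uniform).
    """

    label: str
    states: tuple[str, ...]
    kernel: np.ndarray | Mapping[tuple[str, ...], np.ndarray]
    start_probs: np.ndarray
    stop_prob: float
    kernel_order: int = 1
    mean_len: float = 28.7
    sd_len: float = 23.27
    min_len: int = _MIN_LEN
    max_len: int = _MAX_LEN
    stop_at_use_only: bool = True

    def __post_init__(self) -> None:
        self.start_probs = np.asarray(self.start_probs, dtype=float)
        if not np.isclose(self.start_probs.sum(), 1.0):
            raise ValueError("start distribution must sum to 1")
        if self.kernel_order == 1:
            self.kernel = np.asarray(self.kernel, dtype=float)
            if not np.allclose(self.kernel.sum(axis=1), 1.0):
                raise ValueError("kernel rows must sum to 1")
        if not self.min_len <= self.mean_len <= self.max_len:
            raise ValueError("need min_len <= mean_len <= max_len")

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(self.label.encode())
        h.update(repr(self.states).encode())
        if self.kernel_order == 1:
            h.update(np.ascontiguousarray(self.kernel).tobytes())
        else:
            for key in sorted(self.kernel):
                h.update(repr(key).encode())
                h.update(np.ascontiguousarray(self.kernel[key]).tobytes())
        h.update(self.start_probs.tobytes())
        h.update(f"{self.stop_prob}:{self.kernel_order}".encode())
        return h.hexdigest()[:16]


def _kernel_from_flows(flows: dict[str, dict[str, int]]) -> np.ndarray:
    k = len(ACTIVITY_CODES)
    pos = {c: i for i, c in enumerate(ACTIVITY_CODES)}
    counts = np.zeros((k, k), dtype=float)
    for a, row in flows.items():
        for b, n in row.items():
            counts[pos[a], pos[b]] = n
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        missing = [c for c, t in zip(ACTIVITY_CODES, totals) if t == 0]
        raise ValueError(f"states with no successors: {missing}")
    return counts / totals[:, None]


def default_profiles() -> dict[str, GeneratorProfile]:
    """The three calibrated group profiles (L1, L2, L3)."""
    profiles = {}
    for label in ("L1", "L2", "L3"):
        start = np.zeros(len(ACTIVITY_CODES))
        for code, p in _START_PROBS[label].items():
            start[ACTIVITY_CODES.index(code)] = p
        mean, sd = _LENGTH_TARGETS[label]
        profiles[label] = GeneratorProfile(
            label=label,
            states=ACTIVITY_CODES,
            kernel=_kernel_from_flows(_FLOWS[label]),
            start_probs=start,
            stop_prob=_STOP_PROBS[label],
            mean_len=mean,
            sd_len=sd,
        )
    return profiles


def lagged_profile(
    lag: int = 4,
    accuracy: float = 0.85,
    alphabet: Sequence[str] = ACTIVITY_CODES[:6],
    mean_len: float = 30.0,
    label: str = "LAG",
) -> GeneratorProfile:
    """A generator whose next symbol depends on the symbol ``lag`` steps back.

    The next activity equals a fixed permutation of the symbol ``lag``
    positions earlier with probability ``accuracy``, otherwise uniform.
    Capturing this structure requires n-gram histories of length >= lag,
    so held-out perplexity is minimized at order lag + 1.
    """
    states = tuple(alphabet)
    m = len(states)
    succ = {s: states[(i + 1) % m] for i, s in enumerate(states)}
    kernel: dict[tuple[str, ...], np.ndarray] = {}
    base = np.full(m, (1.0 - accuracy) / m)

    def row_for(oldest: str) -> np.ndarray:
        row = base.copy()
        row[states.index(succ[oldest])] += accuracy
        return row / row.sum()

    # Only the oldest history symbol matters; key rows by it to keep the
    # mapping small and exact.
    for s in states:
        kernel[(s,)] = row_for(s)
    return GeneratorProfile(
        label=label,
        states=states,
        kernel=kernel,
        start_probs=np.full(m, 1.0 / m),
        stop_prob=1.0 / mean_len,
        kernel_order=lag,
        mean_len=mean_len,
        sd_len=mean_len,
        min_len=lag + 1,
        max_len=_MAX_LEN,
        stop_at_use_only=False,
    )


def simulate_session(
    profile: GeneratorProfile,
    rng: np.random.Generator,
    participant_id: str = "SYN",
    topic_id: int = 1,
) -> SearchSession:
    """Draw one session from a profile.

    The walk starts from the start distribution and evolves under the
    kernel; after each information-use activity (any activity, for
    profiles with ``stop_at_use_only=False``) the session stops with
    probability ``stop_prob`` once the minimum length is reached.  At the
    maximum length the session is truncated back to the last use
    activity, so terminal states are use-stage activities (successful
    sessions), unless the walk never reached one.
    """
    states = profile.states
    m = len(states)
    idx_of = {s: i for i, s in enumerate(states)}
    use_idx = {idx_of[c] for c in USE_CODES if c in idx_of}

    if profile.kernel_order == 1:
        cum = np.cumsum(profile.kernel, axis=1)
    else:
        cum = None

    seq_idx = [int(np.searchsorted(np.cumsum(profile.start_probs), rng.random()))]
    while True:
        length = len(seq_idx)
        cur = seq_idx[-1]
        stop_eligible = (cur in use_idx) or not profile.stop_at_use_only
        if length >= profile.min_len and stop_eligible and rng.random() < profile.stop_prob:
            break
        if length >= profile.max_len:
            if profile.stop_at_use_only:
                last_use = max(
                    (i for i, s in enumerate(seq_idx)
                     if s in use_idx and i + 1 >= profile.min_len),
                    default=None,
                )
                if last_use is not None:
                    seq_idx = seq_idx[:last_use + 1]
            break
        if profile.kernel_order == 1:
            nxt = int(np.searchsorted(cum[cur], rng.random()))
        else:
            oldest = seq_idx[-profile.kernel_order] if length >= profile.kernel_order \
                else seq_idx[0]
            row = profile.kernel.get((states[oldest],))
            if row is None:
                row = np.full(m, 1.0 / m)
            nxt = int(np.searchsorted(np.cumsum(row), rng.random()))
        seq_idx.append(nxt)

    return SearchSession(
        participant_id=participant_id,
        topic_id=topic_id,
        activities=tuple(states[i] for i in seq_idx),
        familiarity_label=profile.label if profile.label in ("L1", "L2", "L3") else None,
    )


@dataclass
class SimulationConfig:
    """Reproducible recipe for a labeled synthetic corpus."""

    profiles: dict[str, GeneratorProfile] = field(default_factory=default_profiles)
    sessions_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SESSIONS_PER_GROUP)
    )
    seed: int = 0
    questionnaire_error_rate: float = 0.01

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "sessions_per_group": dict(self.sessions_per_group),
            "questionnaire_error_rate": self.questionnaire_error_rate,
            "profile_checksums": {
                label: p.checksum() for label, p in self.profiles.items()
            },
            "rng": "numpy.random.default_rng(PCG64)",
        }

    def manifest_json(self) -> str:
        return json.dumps(self.manifest(), indent=1, sort_keys=True)


def simulate_corpus(config: SimulationConfig) -> SessionCorpus:
    """Draw a labeled corpus: per-group session sets under a single seed."""
    rng = np.random.default_rng(config.seed)
    sessions: list[SearchSession] = []
    counter = 0
    for label in sorted(config.sessions_per_group):
        profile = config.profiles[label]
        for _ in range(config.sessions_per_group[label]):
            counter += 1
            sessions.append(
                simulate_session(
                    profile,
                    rng,
                    participant_id=f"SYN{counter:05d}",
                    topic_id=1 + (counter - 1) % 4,
                )
            )
    return SessionCorpus(sessions)


#: Per-label base answer patterns: status of the two items in each of
#: sections 1-3 for one topic.  L1 recognizes nothing; L2 handles
#: sections 1-2 (0.65 points, the inclusive L2 boundary); L3 answers all
#: six items (1.0).
_ANSWER_PATTERNS: dict[str, dict[int, bool]] = {
    "L1": {1: False, 2: False, 3: False},
    "L2": {1: True, 2: True, 3: False},
    "L3": {1: True, 2: True, 3: True},
}


def simulate_questionnaire(
    label: str,
    rng: np.random.Generator,
    participant_id: str = "SYN",
    error_rate: float = 0.01,
) -> list[QuestionnaireResponse]:
    """24 responses for a participant with the given label on every topic.

    Each item's status follows the label's base pattern and flips with
    probability ``error_rate``; at the default rate, scoring the output
    recovers the requested label for >= 95% of simulated participants.
    """
    if label not in _ANSWER_PATTERNS:
        raise ValueError(f"unknown label {label!r}")
    out = []
    for topic in range(1, 5):
        for section in (1, 2, 3):
            for item in (1, 2):
                correct = _ANSWER_PATTERNS[label][section]
                if rng.random() < error_rate:
                    correct = not correct
                out.append(
                    QuestionnaireResponse(
                        participant_id=participant_id,
                        section=section,
                        topic_id=topic,
                        item_index=item,
                        status="correct" if correct else "incorrect",
                    )
                )
    return out
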