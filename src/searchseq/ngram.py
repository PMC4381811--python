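"""n-gram language models of activity sequences with Witten-Bell smoothing.

A session is treated as a sentence over the closed 18-code activity
alphabet: n-1 start markers are prepended and one end marker appended
(start markers are never predicted; the end marker is predicted and
counted).  Conditional probabilities use *interpolated* Witten-Bell
discounting,

    p(w | h) = (c(h, w) + T(h) * p(w | h')) / (c(h) + T(h)),

where c(h) is the continuation total of history h, T(h) the number of
distinct codes observed after h, and h' drops the oldest symbol of h.
The order-0 base distribution is uniform over the predictable vocabulary
(the 18 codes plus the end marker).  Unseen histories fall through to
the next lower order.

Model quality on held-out sessions is measured by perplexity,

    PP = exp(- sum log p / t),

the geometric average branching factor over the t scored tokens (session
tokens plus end markers), and the model order is selected by minimizing
held-out perplexity across a sweep of orders (2-7 by default).
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .activities import ACTIVITY_CODES, SearchSession, SessionCorpus

__all__ = [
    "START",
    "END",
    "NGramModel",
    "PerplexityResult",
    "CorpusSplit",
    "split_corpus",
    "fit_ngram",
    "sequence_logprob",
    "perplexity",
    "select_order",
    "write_arpa",
    "read_arpa",
]

START = "<s>"
END = "</s>"

DEFAULT_ORDERS: tuple[int, ...] = (2, 3, 4, 5, 6, 7)


def _tokens_of(item) -> tuple[str, ...]:
    if isinstance(item, SearchSession):
        return item.activities
    return tuple(item)


@dataclass
class NGramModel:
    """Interpolated Witten-Bell n-gram model over a closed vocabulary."""

    order: int
    vocabulary: tuple[str, ...] = ACTIVITY_CODES
    pad: bool = True
    smoothing: str = "witten-bell-interpolated"
    #: history tuple (length <= order-1) -> Counter of continuation counts
    _followers: dict[tuple[str, ...], Counter] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        self.vocabulary = tuple(self.vocabulary)

    @property
    def predictable_vocabulary(self) -> tuple[str, ...]:
        """Symbols the model can predict: codes plus the end marker."""
        if self.pad:
            return self.vocabulary + (END,)
        return self.vocabulary

    # -- counting -----------------------------------------------------

    def _count_sequence(self, tokens: Sequence[str]) -> None:
        n = self.order
        padded = ((START,) * (n - 1) + tuple(tokens) + (END,)) if self.pad else tuple(tokens)
        first = n - 1 if self.pad else 0
        for pos in range(first, len(padded)):
            w = padded[pos]
            for k in range(n):  # history lengths 0 .. n-1
                if pos - k < 0:
                    break
                h = padded[pos - k:pos]
                self._followers.setdefault(h, Counter())[w] += 1

    # -- Witten-Bell probabilities ------------------------------------

    def context_count(self, h: tuple[str, ...]) -> int:
        c = self._followers.get(tuple(h))
        return sum(c.values()) if c else 0

    def continuation_count(self, h: tuple[str, ...], w: str) -> int:
        c = self._followers.get(tuple(h))
        return c.get(w, 0) if c else 0

    def distinct_followers(self, h: tuple[str, ...]) -> int:
        c = self._followers.get(tuple(h))
        return len(c) if c else 0

    def prob(self, w: str, history: Sequence[str] = ()) -> float:
        """Interpolated Witten-Bell p(w | history)."""
        if w not in self.predictable_vocabulary:
            raise ValueError(f"symbol {w!r} not in the model vocabulary")
        h = tuple(history)[-(self.order - 1):] if self.order > 1 else ()
        return self._prob(h, w)

    def _prob(self, h: tuple[str, ...], w: str) -> float:
        if not h:
            base = 1.0 / len(self.predictable_vocabulary)
            counter = self._followers.get((), None)
            if not counter:
                return base
            c = sum(counter.values())
            t = len(counter)
            return (counter.get(w, 0) + t * base) / (c + t)
        counter = self._followers.get(h)
        if not counter:
            return self._prob(h[1:], w)
        c = sum(counter.values())
        t = len(counter)
        return (counter.get(w, 0) + t * self._prob(h[1:], w)) / (c + t)

    # -- serialization ------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "order": self.order,
            "vocabulary": list(self.vocabulary),
            "pad": self.pad,
            "smoothing": self.smoothing,
            "counts": [
                {"history": list(h), "followers": dict(c)}
                for h, c in sorted(self._followers.items())
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NGramModel":
        payload = json.loads(text)
        model = cls(
            order=payload["order"],
            vocabulary=tuple(payload["vocabulary"]),
            pad=payload["pad"],
            smoothing=payload["smoothing"],
        )
        for entry in payload["counts"]:
            model._followers[tuple(entry["history"])] = Counter(entry["followers"])
        return model


@dataclass(frozen=True)
class PerplexityResult:
    order: int
    perplexity: float
    token_count: int
    log_prob_total: float
    dataset_id: str = ""


@dataclass
class CorpusSplit:
    train: SessionCorpus
    test: SessionCorpus
    fraction: float
    seed: int


def split_corpus(corpus: SessionCorpus, fraction: float = 0.8, seed: int = 0) -> CorpusSplit:
    """Seeded session-level random split into train and test sides.

    The train side gets ``round(fraction * n)`` sessions; the split is
    deterministic for a fixed seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    sessions = list(corpus)
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(sessions))
    n_train = int(round(fraction * len(sessions)))
    n_train = min(max(n_train, 1), len(sessions) - 1)
    train_idx = set(perm[:n_train].tolist())
    train = [s for i, s in enumerate(sessions) if i in train_idx]
    test = [s for i, s in enumerate(sessions) if i not in train_idx]
    return CorpusSplit(SessionCorpus(train), SessionCorpus(test), fraction, seed)


def fit_ngram(
    train: SessionCorpus | Iterable,
    order: int,
    vocabulary: Sequence[str] = ACTIVITY_CODES,
    pad: bool = True,
) -> NGramModel:
    """Train an interpolated Witten-Bell model of the given order.

    ``train`` may be a :class:`SessionCorpus` or any iterable of token
    sequences.  ``pad=False`` disables boundary markers (used for small
    hand-checked examples; the analysis default pads).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    model = NGramModel(order=order, vocabulary=tuple(vocabulary), pad=pad)
    n_seq = 0
    for item in train:
        tokens = _tokens_of(item)
        for t in tokens:
            if t not in model.vocabulary:
                raise ValueError(f"out-of-vocabulary code {t!r} in training data")
        model._count_sequence(tokens)
        n_seq += 1
    if n_seq == 0:
        raise ValueError("empty training corpus")
    return model


def sequence_logprob(model: NGramModel, session) -> tuple[float, int]:
    """Natural-log probability of one session under the model.

    Scores every session token plus the end marker (when padding is on);
    start markers are conditioned on but never scored.  Raises on
    out-of-vocabulary codes: the alphabet is closed.
    """
    tokens = _tokens_of(session)
    for t in tokens:
        if t not in model.vocabulary:
            raise ValueError(f"out-of-vocabulary code {t!r}")
    n = model.order
    padded = ((START,) * (n - 1) + tuple(tokens) + (END,)) if model.pad else tuple(tokens)
    first = n - 1 if model.pad else 0
    logp = 0.0
    count = 0
    for pos in range(first, len(padded)):
        h = padded[max(0, pos - (n - 1)):pos]
        logp += math.log(model._prob(h, padded[pos]))
        count += 1
    return logp, count


def perplexity(
    model: NGramModel, test: SessionCorpus | Iterable, dataset_id: str = ""
) -> PerplexityResult:
    """Pooled perplexity PP = exp(-sum(log p) / sum(tokens)) over a corpus."""
    total_logp = 0.0
    total_tokens = 0
    n_seq = 0
    for item in test:
        lp, t = sequence_logprob(model, item)
        total_logp += lp
        total_tokens += t
        n_seq += 1
    if n_seq == 0 or total_tokens == 0:
        raise ValueError("empty test corpus")
    return PerplexityResult(
        order=model.order,
        perplexity=math.exp(-total_logp / total_tokens),
        token_count=total_tokens,
        log_prob_total=total_logp,
        dataset_id=dataset_id,
    )


def select_order(
    corpus: SessionCorpus,
    orders: Sequence[int] = DEFAULT_ORDERS,
    fraction: float = 0.8,
    seed: int = 0,
    dataset_id: str = "",
) -> tuple[list[PerplexityResult], int]:
    """Sweep model orders on a shared split; best = lowest test perplexity.

    Ties resolve to the smaller order.
    """
    split = split_corpus(corpus, fraction=fraction, seed=seed)
    results: list[PerplexityResult] = []
    best_order = None
    best_pp = math.inf
    for order in orders:
        model = fit_ngram(split.train, order)
        result = perplexity(model, split.test, dataset_id=dataset_id)
        results.append(result)
        if result.perplexity < best_pp:
            best_pp = result.perplexity
            best_order = order
    return results, best_order


# -- ARPA export ------------------------------------------------------

def _log10(x: float) -> float:
    return math.log10(x) if x > 0 else -99.0


def write_arpa(model: NGramModel, path) -> None:
    """Write the model as an ARPA-style plain-text n-gram file.

    Interpolated Witten-Bell flattens exactly into backoff form: seen
    n-grams carry their interpolated probability and each history h
    carries backoff weight T(h) / (c(h) + T(h)).
    """
    levels: list[list[tuple[tuple[str, ...], float, float | None]]] = []
    for k in range(1, model.order + 1):
        entries = []
        if k == 1:
            grams = [(w,) for w in model.predictable_vocabulary]
            if model.pad:
                grams.append((START,))
            for g in sorted(grams):
                w = g[0]
                p = -99.0 if w == START else _log10(model._prob((), w))
                bow = None
                if model.order > 1:
                    c = model._followers.get(g)
                    if c is not None:
                        tot, t = sum(c.values()), len(c)
                        bow = _log10(t / (tot + t))
                entries.append((g, p, bow))
        else:
            grams = sorted(
                h + (w,)
                for h, counter in model._followers.items()
                if len(h) == k - 1
                for w in counter
            )
            for g in grams:
                p = _log10(model._prob(g[:-1], g[-1]))
                bow = None
                if k < model.order:
                    c = model._followers.get(g)
                    if c is not None:
                        tot, t = sum(c.values()), len(c)
                        bow = _log10(t / (tot + t))
                entries.append((g, p, bow))
        levels.append(entries)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\\data\\\n")
        for k, entries in enumerate(levels, start=1):
            fh.write(f"ngram {k}={len(entries)}\n")
        for k, entries in enumerate(levels, start=1):
            fh.write(f"\n\\{k}-grams:\n")
            for g, p, bow in entries:
                line = f"{p:.6f}\t{' '.join(g)}"
                if bow is not None:
                    line += f"\t{bow:.6f}"
                fh.write(line + "\n")
        fh.write("\n\\end\\\n")


def read_arpa(path) -> dict[int, dict[tuple[str, ...], float]]:
    """Read an ARPA file back as {order: {ngram tuple: log10 prob}}."""
    out: dict[int, dict[tuple[str, ...], float]] = {}
    current: int | None = None
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line == "\\data\\" or line.startswith("ngram "):
                continue
            if line == "\\end\\":
                break
            if line.endswith("-grams:") and line.startswith("\\"):
                current = int(line[1:line.index("-")])
                out[current] = {}
                continue
            if current is None:
                continue
            parts = line.split("\t")
            prob = float(parts[0])
            gram = tuple(parts[1].split(" "))
            out[current][gram] = prob
    return out
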