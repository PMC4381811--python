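"""Witten-Bell n-gram models, perplexity, splits, order selection, ARPA."""

import math

import numpy as np
import pytest

from searchseq.activities import ACTIVITY_CODES, SessionCorpus
from searchseq.ngram import (
    END,
    NGramModel,
    fit_ngram,
    perplexity,
    read_arpa,
    select_order,
    sequence_logprob,
    split_corpus,
    write_arpa,
)
from searchseq.simulate import default_profiles, simulate_session
from conftest import make_session


def small_corpus(n_sessions=40, seed=3, label="L1"):
    profile = default_profiles()[label]
    rng = np.random.default_rng(seed)
    return SessionCorpus([simulate_session(profile, rng) for _ in range(n_sessions)])


class TestWittenBellArithmetic:
    def test_unigram_hand_example(self):
        # stream A,A,B over closed vocab {A,B}, no boundary padding:
        # p(A) = (2 + 2*(1/2)) / (3 + 2) = 0.6
        model = fit_ngram([["A", "A", "B"]], 1, vocabulary=("A", "B"), pad=False)
        assert model.prob("A") == pytest.approx(0.6)
        assert model.prob("B") == pytest.approx(0.4)

    def test_discounting_strictly_reserves_mass(self):
        model = fit_ngram(
            [["Q:AccSE", "Q:NewQ"]] * 7, 2
        )
        p = model.prob("Q:NewQ", ["Q:AccSE"])
        assert p < 1.0
        assert p == pytest.approx((7 + 1 * model._prob((), "Q:NewQ")) / (7 + 1))

    def test_conditionals_normalize_over_predictable_vocabulary(self, rng):
        corpus = small_corpus()
        model = fit_ngram(corpus, 3)
        histories = [()]
        sessions = list(corpus)
        for _ in range(100):
            s = sessions[rng.integers(len(sessions))]
            i = rng.integers(len(s.activities))
            histories.append(tuple(s.activities[max(0, i - 2):i]))
        for h in histories:
            total = sum(model.prob(w, h) for w in model.predictable_vocabulary)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_unseen_history_falls_through_to_lower_order(self):
        model = fit_ngram([["Q:AccSE", "Q:NewQ", "E:ExamSR"]], 3)
        unseen = ("D:UnchkGI", "D:UnchkGI")
        assert model.prob("Q:NewQ", unseen) == pytest.approx(
            model.prob("Q:NewQ", unseen[1:])
        )

    def test_out_of_vocabulary_rejected(self):
        model = fit_ngram([["Q:AccSE", "Q:NewQ"]], 2)
        with pytest.raises(ValueError, match="vocabulary"):
            sequence_logprob(model, ["Q:AccSE", "NOT-A-CODE"])


class TestSequenceLogprob:
    def test_uniform_model_closed_form(self):
        model = NGramModel(order=2)  # no counts: uniform over 19 symbols
        logp, tokens = sequence_logprob(model, make_session(["Q:AccSE"] * 4))
        assert tokens == 5  # four activities plus the end marker
        assert logp == pytest.approx(5 * math.log(1.0 / 19.0))

    def test_self_trained_logprob_is_finite_negative(self):
        session = make_session(["Q:AccSE", "Q:NewQ", "E:ExamSR"])
        model = fit_ngram([session], 1)
        logp, _ = sequence_logprob(model, session)
        assert -math.inf < logp < 0.0

    def test_hand_built_unigram_with_end_marker(self):
        model = fit_ngram([["A", "A", "B"]], 1, vocabulary=("A", "B"))
        # padded stream A,A,B,</s>: N=4, T=3, base 1/3 over {A,B,</s>}
        p_a = (2 + 3 * (1 / 3)) / (4 + 3)
        p_b = (1 + 3 * (1 / 3)) / (4 + 3)
        p_end = (1 + 3 * (1 / 3)) / (4 + 3)
        logp, tokens = sequence_logprob(model, ["A", "A", "B"])
        assert tokens == 4
        assert logp == pytest.approx(2 * math.log(p_a) + math.log(p_b)
                                     + math.log(p_end))


class TestPerplexity:
    def test_uniform_model_perplexity_equals_vocabulary_size(self):
        model = NGramModel(order=3)
        corpus = [make_session(["E:EvalI"] * n) for n in (3, 7, 11)]
        result = perplexity(model, corpus)
        assert result.perplexity == pytest.approx(19.0)

    def test_training_reduces_branching(self):
        corpus = [make_session(["Q:AccSE", "Q:NewQ", "E:ExamSR", "A:SelHI"])] * 10
        model = fit_ngram(corpus, 2)
        assert perplexity(model, corpus).perplexity < 19.0

    def test_perplexity_matches_kernel_entropy_rate(self):
        """On first-order data, bigram perplexity approaches the generating
        kernel's exponentiated entropy rate (here: entropy of the session
        process estimated by Monte Carlo from the true kernel)."""
        profile = default_profiles()["L2"]
        rng = np.random.default_rng(10)
        train = [simulate_session(profile, rng) for _ in range(4000)]
        test = [simulate_session(profile, rng) for _ in range(800)]
        model = fit_ngram(SessionCorpus(train), 2)
        pp = perplexity(model, SessionCorpus(test)).perplexity

        # oracle: true per-token log-loss of the generating process on the
        # same test set (kernel transitions + stop rule as end marker)
        kernel = profile.kernel
        idx = {c: i for i, c in enumerate(ACTIVITY_CODES)}
        use = {"U:UseHI", "U:UseGI"}
        total, tokens = 0.0, 0
        for s in test:
            acts = s.activities
            total += math.log(profile.start_probs[idx[acts[0]]])
            tokens += 1
            for i, (a, b) in enumerate(zip(acts, acts[1:])):
                p = kernel[idx[a], idx[b]]
                if a in use and i + 1 >= profile.min_len:
                    p *= 1 - profile.stop_prob  # continued past a stop chance
                total += math.log(p)
                tokens += 1
            total += math.log(profile.stop_prob)  # end marker
            tokens += 1
        oracle_pp = math.exp(-total / tokens)
        assert pp == pytest.approx(oracle_pp, rel=0.15)


class TestSplitCorpus:
    def test_exact_division(self):
        corpus = SessionCorpus([make_session(["Q:AccSE", "Q:NewQ"], pid=f"p{i}")
                                for i in range(10)])
        split = split_corpus(corpus, 0.8, seed=1)
        assert len(split.train) == 8
        assert len(split.test) == 2

    def test_rounding_rule(self):
        corpus = SessionCorpus([make_session(["Q:AccSE", "Q:NewQ"], pid=f"p{i}")
                                for i in range(9)])
        split = split_corpus(corpus, 0.8, seed=1)
        assert len(split.train) == 7  # round(7.2)
        assert len(split.test) == 2

    def test_deterministic_and_exhaustive(self):
        corpus = small_corpus(25)
        a = split_corpus(corpus, 0.8, seed=42)
        b = split_corpus(corpus, 0.8, seed=42)
        assert [s.participant_id for s in a.train] == [s.participant_id for s in b.train]
        ids = {id(s) for s in corpus}
        assert {id(s) for s in list(a.train) + list(a.test)} == ids

    def test_fraction_validation(self):
        corpus = small_corpus(4)
        with pytest.raises(ValueError):
            split_corpus(corpus, 1.2, seed=0)


class TestSelectOrder:
    def test_first_order_data_prefers_low_order(self):
        corpus = small_corpus(500, seed=8)
        results, best = select_order(corpus, orders=(2, 3, 4, 5), seed=0)
        assert best <= 3
        assert len(results) == 4

    def test_degenerate_repetitive_corpus_resolves_ties_to_smallest(self):
        corpus = SessionCorpus(
            [make_session(["Q:AccSE", "Q:NewQ"] * 4, pid=f"p{i}") for i in range(10)]
        )
        results, best = select_order(corpus, orders=(2, 3, 4), seed=0)
        pps = [r.perplexity for r in results]
        assert best == results[int(np.argmin(np.round(pps, 12)))].order

    def test_determinism(self):
        corpus = small_corpus(60, seed=5)
        r1, b1 = select_order(corpus, orders=(2, 3), seed=9)
        r2, b2 = select_order(corpus, orders=(2, 3), seed=9)
        assert b1 == b2
        assert [r.perplexity for r in r1] == [r.perplexity for r in r2]

    def test_more_training_data_does_not_hurt(self):
        profile = default_profiles()["L3"]
        rng = np.random.default_rng(17)
        test = SessionCorpus([simulate_session(profile, rng) for _ in range(400)])
        pps = []
        for n in (300, 3000):
            train = SessionCorpus([simulate_session(profile, rng) for _ in range(n)])
            model = fit_ngram(train, 2)
            pps.append(perplexity(model, test).perplexity)
        assert pps[1] <= pps[0] * 1.02  # small slack for sampling noise


class TestSerialization:
    def test_json_round_trip_preserves_probabilities(self):
        corpus = small_corpus(15, seed=2)
        model = fit_ngram(corpus, 3)
        clone = NGramModel.from_json(model.to_json())
        h = ("E:ExamSR", "A:SelHI")
        for w in ("E:EvalI", "Q:AccSE", END):
            assert clone.prob(w, h) == pytest.approx(model.prob(w, h))

    def test_arpa_file_probabilities_match_model(self, tmp_path):
        corpus = small_corpus(10, seed=4)
        model = fit_ngram(corpus, 2)
        path = tmp_path / "model.arpa"
        write_arpa(model, path)
        table = read_arpa(path)
        assert set(table) == {1, 2}
        for gram, logp in list(table[2].items())[:20]:
            assert logp == pytest.approx(
                math.log10(model.prob(gram[-1], gram[:-1])), abs=1e-5
            )
        # backoff flattening is exact: unseen continuations under a seen
        # history equal backoff-weight * lower-order probability
        some_h = next(h for h, _ in model._followers.items() if len(h) == 1
                      and h[0] != "<s>")
        seen = set(model._followers[some_h])
        unseen = [w for w in model.predictable_vocabulary if w not in seen]
        if unseen:
            c = sum(model._followers[some_h].values())
            t = len(model._followers[some_h])
            lam = t / (c + t)
            w = unseen[0]
            assert model.prob(w, some_h) == pytest.approx(
                lam * model._prob((), w)
            )
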