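import numpy as np
import pytest

from searchseq.activities import SearchSession, SessionCorpus


def make_session(codes, pid="p1", topic=1, label=None):
    return SearchSession(
        participant_id=pid, topic_id=topic,
        activities=tuple(codes), familiarity_label=label,
    )


@pytest.fixture
def worked_example_session():
    """The narrative nine-activity example session: search engine, first
    query, examine results, select a health and a general item, evaluate
    and use the first, evaluate and discard the second."""
    return make_session(
        [
            "Q:AccSE", "Q:NewQ", "E:ExamSR", "A:SelHI", "A:SelGI",
            "E:EvalI", "U:UseHI", "E:EvalI", "D:DisGI",
        ]
    )


@pytest.fixture
def toy_labeled_corpus():
    """Small two-group corpus with hand-countable statistics."""
    return SessionCorpus(
        [
            make_session(["Q:AccSE", "Q:NewQ", "E:ExamSR", "A:SelHI", "E:EvalI",
                          "U:UseHI"], pid="a", label="L1"),
            make_session(["Q:AccSE", "Q:ModQ", "E:ExamSR", "A:SelGI", "E:EvalI",
                          "D:DisGI"], pid="b", label="L1"),
            make_session(["Q:AccHW", "Q:NewQ", "E:ExamSR", "A:SelHI", "E:EvalI",
                          "U:UseHI"], pid="c", label="L3"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
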