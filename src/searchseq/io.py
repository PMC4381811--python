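"""Readers, writers, and the end-to-end pipeline runner.

Session logs are CSV files with columns participant_id, topic_id, step,
activity_code (one row per activity, steps consecutive from 1) or a JSON
list of session objects with an "activities" array.  Questionnaire
tables are CSV with columns participant_id, section, topic_id,
item_index, status.  Sessions failing validation are excluded from all
statistics and reported, so analyses run only on qualified sessions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import comparison, ngram, patterns, transitions
from .activities import (
    SearchSession,
    SessionCorpus,
    activity_frequencies,
    search_efficiency,
    validate_session,
)
from .familiarity import QuestionnaireResponse, group_counts, label_participants

__all__ = [
    "read_sessions",
    "write_sessions",
    "read_questionnaire",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("searchseq")

_SESSION_COLUMNS = ["participant_id", "topic_id", "step", "activity_code"]


def _assemble(rows: pd.DataFrame, path) -> tuple[SessionCorpus, list[str]]:
    sessions: list[SearchSession] = []
    excluded: list[str] = []
    for (pid, topic), grp in rows.groupby(["participant_id", "topic_id"], sort=False):
        grp = grp.sort_values("step")
        steps = grp["step"].tolist()
        label = None
        if "familiarity_label" in grp.columns:
            labels = grp["familiarity_label"].dropna().unique()
            if len(labels) == 1:
                label = str(labels[0])
        session = SearchSession(
            participant_id=str(pid),
            topic_id=int(topic),
            activities=tuple(grp["activity_code"]),
            familiarity_label=label,
        )
        violations = validate_session(session)
        if steps != list(range(1, len(steps) + 1)):
            violations.append(f"step indices not consecutive from 1: {steps[:5]}...")
        if violations:
            msg = f"excluded session ({pid!r}, topic {topic}): " + "; ".join(violations)
            excluded.append(msg)
            log.warning("%s: %s", path, msg)
        else:
            sessions.append(session)
    return SessionCorpus(sessions), excluded


def read_sessions(path) -> SessionCorpus:
    """Read and validate a session log (CSV or JSON by extension).

    Invalid sessions are excluded and logged; the returned corpus holds
    only qualified sessions.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        records = []
        for obj in payload:
            for step, code in enumerate(obj["activities"], start=1):
                records.append(
                    {
                        "participant_id": obj["participant_id"],
                        "topic_id": obj["topic_id"],
                        "step": step,
                        "activity_code": code,
                        "familiarity_label": obj.get("familiarity_label"),
                    }
                )
        rows = pd.DataFrame(records)
    else:
        try:
            rows = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ValueError(f"malformed session log {path}: {exc}") from exc
        missing = [c for c in _SESSION_COLUMNS if c not in rows.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    corpus, _ = _assemble(rows, path)
    return corpus


def write_sessions(corpus: SessionCorpus, path) -> None:
    """Write a corpus as a session-log CSV (round-trips through read_sessions)."""
    path = Path(path)
    records = []
    for s in corpus:
        for step, code in enumerate(s.activities, start=1):
            records.append(
                {
                    "participant_id": s.participant_id,
                    "topic_id": s.topic_id,
                    "step": step,
                    "activity_code": code,
                    "familiarity_label": s.familiarity_label,
                }
            )
    pd.DataFrame(records).to_csv(path, index=False)


def read_questionnaire(path) -> list[QuestionnaireResponse]:
    """Read a questionnaire response table (CSV)."""
    rows = pd.read_csv(path)
    required = ["participant_id", "section", "topic_id", "item_index", "status"]
    missing = [c for c in required if c not in rows.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for i, row in rows.iterrows():
        try:
            out.append(
                QuestionnaireResponse(
                    participant_id=str(row["participant_id"]),
                    section=int(row["section"]),
                    topic_id=int(row["topic_id"]),
                    item_index=int(row["item_index"]),
                    status=str(row["status"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return out


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end analysis pipeline."""

    sessions_path: str
    questionnaire_path: str | None = None
    output_dir: str = "searchseq-output"
    alpha: float = comparison.DEFAULT_ALPHA
    orders: tuple[int, ...] = ngram.DEFAULT_ORDERS
    split_fraction: float = 0.8
    top_k: int = 20
    pattern_n: int | None = None  # None: use the selected order
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "orders" in payload:
            payload["orders"] = tuple(payload["orders"])
        return cls(**payload)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (not the output location)."""
        blob = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v
             for k, v in self.__dict__.items() if k != "output_dir"},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write one report bundle.

    Stages: familiarity labeling (when a questionnaire is given) ->
    activity frequencies -> per-group transition matrices and top-10
    reports -> pairwise chi-square comparisons -> n-gram order selection
    -> top-k pattern tables with categories -> search efficiency.  Every
    output lands in ``config.output_dir`` together with a manifest
    recording the config hash and seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read-sessions"
    try:
        corpus = read_sessions(config.sessions_path)
        log.info("read %d qualified sessions", len(corpus))

        if config.questionnaire_path:
            stage = "familiarity"
            responses = read_questionnaire(config.questionnaire_path)
            labels = label_participants(responses)
            labels.to_csv(out / "familiarity_labels.csv", index=False)
            group_counts(labels).to_csv(out / "familiarity_group_counts.csv")
            label_of = {
                (r.participant_id, r.topic_id): r.label
                for r in labels.itertuples()
            }
            corpus = SessionCorpus(
                [
                    s.with_label(label_of[(s.participant_id, s.topic_id)])
                    if (s.participant_id, s.topic_id) in label_of
                    else s
                    for s in corpus
                ]
            )

        stage = "frequencies"
        freq = activity_frequencies(corpus)
        freq.to_frame().to_csv(out / "activity_frequencies.csv")

        stage = "transitions"
        groups = corpus.groups()
        matrices = {}
        for label, group in groups.items():
            m = transitions.transition_counts(group)
            matrices[label] = m
            m.to_frame().to_csv(out / f"transitions_{label}.csv")
            report = transitions.top_transitions(m, 10)
            report.to_frame().to_csv(out / f"top_transitions_{label}.csv", index=False)

        stage = "compare"
        labels_present = list(groups)
        comparisons = []
        for i, a in enumerate(labels_present):
            for b in labels_present[i + 1:]:
                cmp_res = comparison.compare_matrices(
                    matrices[a], matrices[b], alpha=config.alpha,
                    name_a=a, name_b=b,
                )
                comparisons.append(cmp_res.to_dict())
        (out / "comparisons.json").write_text(json.dumps(comparisons, indent=1))

        stage = "select-order"
        results, best = ngram.select_order(
            corpus, orders=config.orders,
            fraction=config.split_fraction, seed=config.seed,
        )
        pd.DataFrame(
            [
                {"order": r.order, "perplexity": r.perplexity,
                 "token_count": r.token_count}
                for r in results
            ]
        ).to_csv(out / "perplexity_by_order.csv", index=False)

        stage = "patterns"
        n = config.pattern_n or best
        tables, categories = patterns.group_pattern_summary(corpus, n, config.top_k)
        for label, table in tables.items():
            table.to_frame().to_csv(out / f"patterns_{label}.csv", index=False)
        categories.to_csv(out / "pattern_categories.csv", index=False)

        stage = "efficiency"
        efficiency = {
            label: search_efficiency(group) for label, group in groups.items()
        }
        (out / "search_efficiency.json").write_text(json.dumps(efficiency, indent=1))

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "alpha": config.alpha,
            "orders": list(config.orders),
            "selected_order": best,
            "pattern_n": n,
            "config_hash": config.config_hash(),
            "qualified_sessions": len(corpus),
            "groups": {label: len(g) for label, g in groups.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
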