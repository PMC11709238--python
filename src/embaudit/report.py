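"""End-to-end audit orchestration, config handling and report assembly.

A single YAML config drives both audits, so a full study is one command:

.. code-block:: yaml

    embedding:
      path: vectors_glove.txt
      format: glove_text          # word2vec_binary | word2vec_text | glove_text
      oov_policy: mean_of_words
    analogy:                      # optional block
      k: 10
      exclude_inputs: true
      lexicon: [unemployable, unreliable, incompetent]
      battery:                    # omit to use the shipped default battery
        - [healthy, employable, depression]
        - [healthy, employable, psychosis, 10]
    axes:                         # optional block
      x_poles: [healthy, ill]
      y_poles: [employable, unemployable]
      terms:                      # omit to use the shipped default term lists
        psychiatric: [depression, psychosis]
        physical: [cancer]

Outputs are machine-readable first (TSV tables + JSON summary); the
plain-text report is assembled from them, and every number in it traces
to a table cell.  The embedding file's SHA-256 is recorded so reports are
attributable to an exact artefact.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Any, Sequence

import yaml

from .analogy import (
    AnalogyQuery,
    AnalogyResult,
    BiasLexicon,
    default_battery,
    run_battery,
)
from .axes import ProjectionTable, build_axis, default_terms, project_battery, render_scatter
from .formats import load_embeddings
from .store import TermSet, WordVectorStore

__all__ = [
    "AuditError",
    "AuditReport",
    "load_config",
    "run_full_audit",
    "summarize_bias",
    "analogy_results_frame",
]

logger = logging.getLogger(__name__)


class AuditError(RuntimeError):
    """Fatal audit failure (missing embedding, unusable config)."""


@dataclass
class AuditReport:
    """Everything one audit run produced, plus provenance metadata."""

    meta: dict[str, Any] = field(default_factory=dict)
    analogy_results: list[AnalogyResult] = field(default_factory=list)
    analogy_summary: dict[str, Any] = field(default_factory=dict)
    projection: ProjectionTable | None = None
    projection_extremes: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | PathLike) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise AuditError(f"config {path} is not a mapping")
    if "embedding" not in cfg:
        raise AuditError(f"config {path} has no 'embedding' block")
    if "analogy" not in cfg and "axes" not in cfg:
        raise AuditError(f"config {path} has neither an 'analogy' nor an 'axes' block")
    return cfg


def summarize_bias(results: Sequence[AnalogyResult]) -> dict[str, Any]:
    """Counts of queries whose first biased rank is 1, ≤5, ≤10 or absent,
    plus a per-attribute (B term) breakdown."""
    if not results:
        raise ValueError("no analogy results to summarise")
    counts = {"top1": 0, "top5": 0, "top10": 0, "none": 0, "errors": 0}
    per_attribute: dict[str, dict[str, int]] = {}
    for res in results:
        if not res.ok:
            counts["errors"] += 1
            continue
        rank = res.first_biased_rank
        attr = per_attribute.setdefault(
            res.query.b, {"queries": 0, "biased": 0, "best_rank": 0}
        )
        attr["queries"] += 1
        if rank is None:
            counts["none"] += 1
        else:
            attr["biased"] += 1
            if attr["best_rank"] == 0 or rank < attr["best_rank"]:
                attr["best_rank"] = rank
            if rank == 1:
                counts["top1"] += 1
            if rank <= 5:
                counts["top5"] += 1
            if rank <= 10:
                counts["top10"] += 1
    counts["per_attribute"] = per_attribute
    counts["n_queries"] = len(results)
    return counts


def analogy_results_frame(results: Sequence[AnalogyResult]):
    """Long-format table: one row per (query, rank, token, similarity,
    biased flag); error queries contribute a single error row."""
    import pandas as pd

    rows = []
    for res in results:
        qname = str(res.query)
        if not res.ok:
            rows.append(
                {"query": qname, "rank": 0, "token": "", "similarity": float("nan"),
                 "biased": False, "error": res.error}
            )
            continue
        for rank, (token, sim) in enumerate(res.ranked.items, start=1):
            rows.append(
                {"query": qname, "rank": rank, "token": token,
                 "similarity": sim, "biased": rank in res.biased_positions,
                 "error": ""}
            )
    return pd.DataFrame(
        rows, columns=["query", "rank", "token", "similarity", "biased", "error"]
    )


def _parse_battery(block: dict[str, Any]) -> list[AnalogyQuery]:
    k = int(block.get("k", 10))
    exclude = bool(block.get("exclude_inputs", True))
    raw = block.get("battery")
    if raw is None:
        return [
            AnalogyQuery(q.a, q.b, q.c, k=k, exclude_inputs=exclude)
            for q in default_battery(k=k)
        ]
    queries = []
    for row in raw:
        if not isinstance(row, (list, tuple)) or len(row) not in (3, 4):
            raise AuditError(f"battery row {row!r} is not [a, b, c] or [a, b, c, k]")
        a, b, c = (str(x) for x in row[:3])
        row_k = int(row[3]) if len(row) == 4 else k
        queries.append(AnalogyQuery(a, b, c, k=row_k, exclude_inputs=exclude))
    return queries


def run_full_audit(
    config: str | PathLike | dict[str, Any],
    out_dir: str | PathLike | None = None,
    *,
    store: WordVectorStore | None = None,
) -> AuditReport:
    """Execute the configured analogy and/or axes audits.

    ``config`` may be a path or an already-parsed mapping; ``store`` may
    be injected to skip file loading (used by tests and the simulator).
    Individual OOV terms become warnings; a missing embedding file or an
    empty config is fatal (:class:`AuditError`).
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    if "embedding" not in cfg:
        raise AuditError("config has no 'embedding' block")
    emb = cfg["embedding"]
    oov_policy = emb.get("oov_policy", "mean_of_words")

    report = AuditReport()
    if store is None:
        path = Path(emb.get("path", ""))
        if not path.is_file():
            raise AuditError(f"embedding file not found: {path}")
        store = load_embeddings(path, emb.get("format", "glove_text"))
        report.meta["embedding_sha256"] = _sha256(path)
        report.meta["embedding_path"] = str(path)
    else:
        report.meta["embedding_path"] = store.meta.source
    report.meta["embedding_format"] = store.meta.format
    report.meta["vocab_size"] = len(store)
    report.meta["dim"] = store.dim
    report.meta["oov_policy"] = oov_policy
    report.meta["config_sha256"] = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    report.meta["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()

    if "analogy" in cfg:
        block = cfg["analogy"] or {}
        queries = _parse_battery(block)
        lexicon = BiasLexicon(block["lexicon"]) if "lexicon" in block else BiasLexicon()
        report.analogy_results = run_battery(
            store, queries, lexicon, oov_policy=oov_policy
        )
        report.analogy_summary = summarize_bias(report.analogy_results)
        for res in report.analogy_results:
            if not res.ok:
                report.warnings.append(f"analogy {res.query}: {res.error}")
            for tok, sim in res.suppressed_inputs:
                report.warnings.append(
                    f"analogy {res.query}: excluded input {tok!r} would have "
                    f"out-ranked the top-1 (cosine {sim:.4f})"
                )

    if "axes" in cfg:
        block = cfg["axes"] or {}
        x_pos, x_neg = block.get("x_poles", ["healthy", "ill"])
        y_pos, y_neg = block.get("y_poles", ["employable", "unemployable"])
        terms = (
            TermSet.from_mapping(block["terms"])
            if "terms" in block
            else default_terms()
        )
        x_axis = build_axis(store, x_pos, x_neg, oov_policy=oov_policy)
        y_axis = build_axis(store, y_pos, y_neg, oov_policy=oov_policy)
        report.projection = project_battery(
            store, terms, x_axis, y_axis, oov_policy=oov_policy
        )
        if len(report.projection):
            report.projection_extremes = report.projection.extremes()
        for term, msg in report.projection.unresolved:
            report.warnings.append(f"projection term {term!r}: {msg}")

    if out_dir is not None:
        write_outputs(report, out_dir)
    return report


def write_outputs(report: AuditReport, out_dir: str | PathLike) -> None:
    """Emit TSV tables, JSON summary, scatter image and text report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"meta": report.meta, "warnings": report.warnings}

    if report.analogy_results:
        frame = analogy_results_frame(report.analogy_results)
        frame.to_csv(out / "analogy_results.tsv", sep="\t", index=False,
                     float_format="%.6f")
        summary["analogy"] = {
            "summary": report.analogy_summary,
            "first_biased_rank": {
                str(res.query): res.first_biased_rank
                for res in report.analogy_results
                if res.ok
            },
        }
    if report.projection is not None:
        report.projection.to_tsv(out / "projections.tsv")
        summary["axes"] = {
            "x_axis": report.projection.x_axis.label,
            "y_axis": report.projection.y_axis.label,
            "extremes": report.projection_extremes,
            "unresolved": report.projection.unresolved,
        }
        if len(report.projection):
            render_scatter(report.projection, out / "scatter.png")
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n"
    )
    (out / "report.txt").write_text(format_report(report))


def format_report(report: AuditReport) -> str:
    """Human-readable plain-text rendering of the report."""
    lines = ["Embedding bias audit", "=" * 20, ""]
    for key in ("embedding_path", "embedding_format", "embedding_sha256",
                "vocab_size", "dim", "oov_policy", "timestamp"):
        if key in report.meta:
            lines.append(f"{key:18s} {report.meta[key]}")
    if report.analogy_results:
        s = report.analogy_summary
        lines += ["", "Analogy battery", "-" * 15,
                  f"queries: {s['n_queries']}  biased@1: {s['top1']}  "
                  f"biased@5: {s['top5']}  biased@10: {s['top10']}  "
                  f"unbiased: {s['none']}  errors: {s['errors']}"]
        for res in report.analogy_results:
            if res.ok:
                rank = res.first_biased_rank
                lines.append(
                    f"  {str(res.query):50s} first biased rank: "
                    f"{rank if rank is not None else '-'}"
                )
            else:
                lines.append(f"  {str(res.query):50s} ERROR: {res.error}")
    if report.projection is not None:
        lines += ["", "Axis projection", "-" * 15,
                  f"x: {report.projection.x_axis.label}",
                  f"y: {report.projection.y_axis.label}",
                  f"terms resolved: {len(report.projection)}  "
                  f"unresolved: {len(report.projection.unresolved)}"]
        for _, row in report.projection.rows.iterrows():
            lines.append(
                f"  {row['term']:28s} {row['category']:22s} "
                f"x={row['x_score']:+.6f}  y={row['y_score']:+.6f}"
            )
    if report.warnings:
        lines += ["", "Warnings", "-" * 8]
        lines += [f"  {w}" for w in report.warnings]
    return "\n".join(lines) + "\n"
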