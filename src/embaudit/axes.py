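"""Semantic-axis projection: place probe terms on pole-pair axes.

A semantic axis is the raw difference vector between a positive and a
negative pole word, e.g. ``v(healthy) - v(ill)``.  A term's axis score is
the cosine similarity between its vector and that difference vector, a
number in ``[-1, 1]``: positive means the term sits toward the positive
pole.  Two axes (x and y) give every term a 2-D coordinate; the scatter
of diagnoses and control terms over the healthy-ill × employable-
unemployable plane (and the normal-abnormal × reliable-unreliable
robustness repeat) is the audit's graphical output.

The coordinates table is the unit-tested surface; the rendered image is
a thin matplotlib layer over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import cosine_similarity
from .store import OOVError, OovPolicy, TermSet, WordVectorStore, lookup

__all__ = [
    "SemanticAxis",
    "ProjectionTable",
    "build_axis",
    "project",
    "project_battery",
    "render_scatter",
    "CATEGORY_COLORS",
    "default_terms",
]

#: fixed category → colour mapping for the scatter plot
CATEGORY_COLORS = {
    "psychiatric": "green",
    "physical": "blue",
    "favourable_attribute": "red",
    "very_healthy_control": "yellow",
}

#: shipped probe-term lists (editable via config): psychiatric and
#: physical diagnoses plus favourable-attribute and very-healthy controls.
_DEFAULT_TERMS = {
    "psychiatric": [
        "depression",
        "bipolar",
        "psychosis",
        "schizophrenia",
        "eating disorder",
        "OCD",
        "anxiety disorder",
        "ADHD",
        "PTSD",
        "mania",
        "borderline",
    ],
    "physical": [
        "back pain",
        "obesity",
        "paralysed",
        "heart disease",
        "cancer",
    ],
    "favourable_attribute": [
        "handsome",
        "good looking",
        "tall",
    ],
    "very_healthy_control": [
        "olympic gold medallist",
        "professional footballer",
        "professional tennis player",
        "airline pilot",
        "marathon runner",
        "member of parliament",
        "landscape gardener",
    ],
}


def default_terms() -> TermSet:
    """The shipped diagnosis/control battery as a :class:`TermSet`."""
    return TermSet.from_mapping(_DEFAULT_TERMS)


@dataclass
class SemanticAxis:
    """Difference vector between two pole words."""

    positive_pole: str
    negative_pole: str
    axis_vector: np.ndarray

    def __post_init__(self) -> None:
        self.axis_vector = np.asarray(self.axis_vector, dtype=np.float64)
        if self.positive_pole == self.negative_pole:
            raise ValueError("axis poles must be distinct words")
        if not np.any(self.axis_vector):
            raise ValueError(
                f"degenerate axis: {self.positive_pole!r} and "
                f"{self.negative_pole!r} have identical vectors"
            )

    @property
    def label(self) -> str:
        return f"{self.negative_pole} ← → {self.positive_pole}"


@dataclass
class ProjectionTable:
    """Per-term (category, x, y) cosine scores against two axes."""

    rows: pd.DataFrame  # columns: term, category, x_score, y_score
    x_axis: SemanticAxis
    y_axis: SemanticAxis
    unresolved: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def extremes(self) -> dict:
        """Per-category extreme terms on each axis (audit-report summary)."""
        out: dict = {}
        for category, grp in self.rows.groupby("category", sort=True):
            entry = {}
            for axis in ("x_score", "y_score"):
                hi = grp.loc[grp[axis].idxmax()]
                lo = grp.loc[grp[axis].idxmin()]
                entry[axis] = {
                    "max": {"term": hi["term"], "score": float(hi[axis])},
                    "min": {"term": lo["term"], "score": float(lo[axis])},
                }
            out[str(category)] = entry
        return out

    def to_tsv(self, path: str | PathLike) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.6f")


def build_axis(
    store: WordVectorStore,
    positive_pole: str,
    negative_pole: str,
    *,
    oov_policy: OovPolicy = "case_fallback",
) -> SemanticAxis:
    """Axis vector ``v(positive) - v(negative)`` from raw (unnormalised)
    pole vectors; identical pole vectors are a degenerate-axis error."""
    vp = lookup(store, positive_pole, oov_policy)
    vn = lookup(store, negative_pole, oov_policy)
    return SemanticAxis(positive_pole, negative_pole, vp - vn)


def project(
    store: WordVectorStore,
    term: str,
    axis: SemanticAxis,
    oov_policy: OovPolicy = "mean_of_words",
) -> float:
    """Cosine similarity of ``term``'s vector to the axis vector."""
    return cosine_similarity(lookup(store, term, oov_policy), axis.axis_vector)


def project_battery(
    store: WordVectorStore,
    terms: TermSet | Sequence[tuple[str, str]],
    x_axis: SemanticAxis,
    y_axis: SemanticAxis,
    *,
    oov_policy: OovPolicy = "mean_of_words",
) -> ProjectionTable:
    """Project every term onto both axes.

    One row per term that resolves; OOV terms are recorded in
    ``unresolved`` with the error message, never raised at batch level.
    """
    records = []
    unresolved: list[tuple[str, str]] = []
    for term, category in terms:
        try:
            vec = lookup(store, term, oov_policy)
            records.append(
                {
                    "term": term,
                    "category": category,
                    "x_score": cosine_similarity(vec, x_axis.axis_vector),
                    "y_score": cosine_similarity(vec, y_axis.axis_vector),
                }
            )
        except (OOVError, ValueError) as exc:
            unresolved.append((term, str(exc)))
    rows = pd.DataFrame(
        records, columns=["term", "category", "x_score", "y_score"]
    )
    return ProjectionTable(rows, x_axis, y_axis, unresolved)


def _make_figure(table: ProjectionTable):
    """Build the scatter figure (separated from saving for testability)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if len(table) == 0:
        raise ValueError("cannot render an empty projection table")
    fig, ax = plt.subplots(figsize=(9, 7))
    for category, grp in table.rows.groupby("category", sort=True):
        ax.scatter(
            grp["x_score"],
            grp["y_score"],
            c=CATEGORY_COLORS.get(str(category), "gray"),
            edgecolors="black",
            linewidths=0.5,
            s=60,
            label=str(category),
            zorder=3,
        )
        for _, row in grp.iterrows():
            ax.annotate(
                row["term"],
                (row["x_score"], row["y_score"]),
                textcoords="offset points",
                xytext=(4, 4),
                fontsize=8,
            )
    ax.axhline(0.0, color="lightgray", lw=0.8, zorder=1)
    ax.axvline(0.0, color="lightgray", lw=0.8, zorder=1)
    ax.set_xlabel(table.x_axis.label)
    ax.set_ylabel(table.y_axis.label)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    return fig


def render_scatter(table: ProjectionTable, out_path: str | PathLike) -> None:
    """Scatter the projection table with the fixed category colours and
    one labelled point per row (coincident points both rendered)."""
    import matplotlib.pyplot as plt

    fig = _make_figure(table)
    fig.savefig(out_path)
    plt.close(fig)
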