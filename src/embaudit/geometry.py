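"""Core embedding geometry: cosine similarity, exact nearest neighbours,
and the 3CosAdd analogy target.

The analogy rule completes ``A : B :: C : ?`` by ranking every vocabulary
token by cosine similarity to the composite vector ``v(B) - v(A) + v(C)``.
Input vectors are unit-normalised before the arithmetic by default, which
is the convention of the standard ``most_similar`` implementations whose
published numbers this package is designed to reproduce.  Reported
similarities are cosines against the composite vector itself.

Search is exact (full scan over the vocabulary): audit vocabularies are
desk-scale and bit-reproducibility matters more than speed here.  Ties are
broken by ascending vocabulary index, i.e. file order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .store import OovPolicy, WordVectorStore, lookup

__all__ = [
    "RankedNeighbors",
    "cosine_similarity",
    "top_k",
    "analogy_target",
]

logger = logging.getLogger(__name__)


@dataclass
class RankedNeighbors:
    """Tokens ranked by descending cosine similarity to a query vector."""

    items: list[tuple[str, float]] = field(default_factory=list)
    query_meta: str = ""

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def tokens(self) -> list[str]:
        return [tok for tok, _ in self.items]

    @property
    def similarities(self) -> list[float]:
        return [sim for _, sim in self.items]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors, in ``[-1, 1]``.

    1 means identical direction, 0 orthogonal, -1 opposite.  The raw
    quotient is clamped against floating-point overshoot.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def top_k(
    store: WordVectorStore,
    query: np.ndarray,
    k: int,
    exclude: Iterable[str] = (),
) -> RankedNeighbors:
    """The ``k`` vocabulary tokens most cosine-similar to ``query``.

    Exhaustive exact search over the whole vocabulary.  All-zero rows and
    tokens in ``exclude`` (exact match) are ineligible.  If fewer than
    ``k`` tokens are eligible, all of them are returned and a notice is
    logged.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    query = np.asarray(query, dtype=np.float64)
    qnorm = np.linalg.norm(query)
    if qnorm == 0.0:
        raise ValueError("top_k query vector is zero")
    if len(store) == 0:
        return RankedNeighbors([], query_meta="empty store")

    sims = store.unit_matrix @ (query / qnorm)
    np.clip(sims, -1.0, 1.0, out=sims)
    eligible = ~store.zero_rows
    excluded = set(exclude)
    if excluded:
        for tok in excluded:
            if tok in store:
                eligible[store.index_of(tok)] = False
    n_eligible = int(eligible.sum())
    if k > n_eligible:
        logger.info(
            "top_k: requested k=%d but only %d eligible tokens", k, n_eligible
        )
    sims = np.where(eligible, sims, -np.inf)
    # stable argsort on -sims: descending similarity, ties by vocab index
    order = np.argsort(-sims, kind="stable")[: min(k, n_eligible)]
    items = [(store.tokens[i], float(sims[i])) for i in order]
    return RankedNeighbors(items)


def analogy_target(
    store: WordVectorStore,
    a: str,
    b: str,
    c: str,
    *,
    normalize_inputs: bool = True,
    oov_policy: OovPolicy = "case_fallback",
) -> np.ndarray:
    """The 3CosAdd composite vector ``v(b) - v(a) + v(c)``.

    With ``normalize_inputs`` (the default) each looked-up vector is scaled
    to unit norm before the arithmetic.  OOV errors from :func:`lookup`
    propagate, naming the offending term.
    """
    vecs = [lookup(store, t, oov_policy) for t in (a, b, c)]
    if normalize_inputs:
        normed = []
        for term, v in zip((a, b, c), vecs):
            n = np.linalg.norm(v)
            if n == 0.0:
                raise ValueError(f"term {term!r} has a zero vector")
            normed.append(v / n)
        vecs = normed
    va, vb, vc = vecs
    return vb - va + vc
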