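"""Shared fixtures and independent oracles.

The oracle implementations here are deliberately pure Python (``math``
module, explicit loops, no numpy linear algebra) so that agreement with
the package's vectorised code paths is a genuine cross-check, not a
tautology.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from embaudit import WordVectorStore
from embaudit.store import StoreMeta


# ---------------------------------------------------------------- oracles
def oracle_cosine(a, b) -> float:
    """Cosine similarity by explicit summation."""
    dot = sum(float(x) * float(y) for x, y in zip(a, b))
    na = math.sqrt(sum(float(x) ** 2 for x in a))
    nb = math.sqrt(sum(float(y) ** 2 for y in b))
    return max(-1.0, min(1.0, dot / (na * nb)))


def oracle_top_k(tokens, matrix, query, k, exclude=()):
    """Brute-force full sort: descending cosine, ties by vocabulary index."""
    scored = []
    for i, tok in enumerate(tokens):
        row = [float(x) for x in matrix[i]]
        if tok in exclude or not any(row):
            continue
        scored.append((tok, oracle_cosine(row, query), i))
    scored.sort(key=lambda item: (-item[1], item[2]))
    return [(tok, sim) for tok, sim, _ in scored[:k]]


@pytest.fixture
def top_k_oracle():
    return oracle_top_k


# ---------------------------------------------------------------- stores
def make_store(tokens, matrix, fmt="memory") -> WordVectorStore:
    return WordVectorStore(tokens, np.asarray(matrix, dtype=float),
                           StoreMeta(format=fmt))


@pytest.fixture
def tiny_store() -> WordVectorStore:
    """Five 3-d vectors with hand-checkable geometry."""
    return make_store(
        ["a", "b", "anxiety", "disorder", "zero"],
        [
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [2.0, 4.0, 6.0],
            [4.0, 2.0, 0.0],
            [0.0, 0.0, 0.0],
        ],
    )


@pytest.fixture
def random_store_factory():
    """Seeded factory for randomised stores of bounded size."""

    def factory(seed: int, n: int = 50, d: int = 8) -> WordVectorStore:
        rng = np.random.default_rng(seed)
        tokens = [f"w{i:04d}" for i in range(n)]
        return make_store(tokens, rng.normal(size=(n, d)))

    return factory
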