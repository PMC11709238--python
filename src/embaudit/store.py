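"""In-memory container for a static word embedding.

A :class:`WordVectorStore` pairs an ordered vocabulary with a ``|V| x d``
real matrix, row *i* holding the vector of token *i*.  Tokens are compared
case-sensitively: pretrained news-corpus embeddings deliberately keep
``Lawyer`` and ``lawyer`` as distinct entries, and collapsing them would
change audit results.  Case handling is therefore a *query-time* policy
(see :func:`lookup`), never a property of the store.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "WordVectorStore",
    "TermSet",
    "OOVError",
    "lookup",
    "CATEGORIES",
]

OovPolicy = Literal["error", "case_fallback", "mean_of_words"]

#: term categories used by the projection batteries (fixed plotting contract)
CATEGORIES = (
    "psychiatric",
    "physical",
    "favourable_attribute",
    "very_healthy_control",
)

_WORD_SPLIT = re.compile(r"[\s_]+")


class OOVError(KeyError):
    """A term could not be resolved to any stored vector.

    Carries the list of keys that were attempted, in order, so audit
    reports can say exactly what was tried.
    """

    def __init__(self, term: str, attempted: Sequence[str]):
        self.term = term
        self.attempted = list(attempted)
        super().__init__(
            f"out-of-vocabulary term {term!r}; attempted keys: "
            + ", ".join(repr(a) for a in self.attempted)
        )


@dataclass
class StoreMeta:
    source: str = ""
    format: str = ""
    case_sensitive: bool = True


class WordVectorStore:
    """Ordered vocabulary plus a dense ``|V| x d`` vector matrix.

    Parameters
    ----------
    tokens
        Unique token strings; order defines row order and tie-breaking
        in nearest-neighbour search.
    matrix
        Array of shape ``(len(tokens), dim)``; all entries must be finite.
    meta
        Provenance (source path, file dialect, case flag).
    """

    def __init__(
        self,
        tokens: Sequence[str],
        matrix: np.ndarray,
        meta: StoreMeta | None = None,
        *,
        dim: int | None = None,
    ):
        tokens = list(tokens)
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2:
            matrix = matrix.reshape(len(tokens), -1 if tokens else (dim or 0))
        if matrix.shape[0] != len(tokens):
            raise ValueError(
                f"matrix has {matrix.shape[0]} rows for {len(tokens)} tokens"
            )
        if dim is not None and matrix.shape[1] != dim:
            raise ValueError(f"matrix dim {matrix.shape[1]} != declared {dim}")
        if matrix.size and not np.all(np.isfinite(matrix)):
            raise ValueError("matrix contains non-finite entries")
        index: dict[str, int] = {}
        for i, tok in enumerate(tokens):
            if tok in index:
                raise ValueError(f"duplicate token {tok!r} at rows {index[tok]} and {i}")
            index[tok] = i
        self.tokens: list[str] = tokens
        self.matrix: np.ndarray = matrix
        self.meta = meta or StoreMeta()
        self._index = index
        self._unit: np.ndarray | None = None
        self._zero_rows: np.ndarray | None = None

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])

    def index_of(self, token: str) -> int:
        return self._index[token]

    def row(self, token: str) -> np.ndarray:
        return self.matrix[self._index[token]]

    # -- derived geometry ----------------------------------------------
    @property
    def zero_rows(self) -> np.ndarray:
        """Boolean mask of all-zero rows (cosine undefined; kept but
        excluded from nearest-neighbour candidacy)."""
        if self._zero_rows is None:
            if len(self) == 0:
                self._zero_rows = np.zeros(0, dtype=bool)
            else:
                self._zero_rows = ~np.any(self.matrix != 0.0, axis=1)
        return self._zero_rows

    @property
    def unit_matrix(self) -> np.ndarray:
        """Row-normalised copy of the matrix, computed lazily.

        Nonzero rows have Euclidean norm 1 (to 1e-9); all-zero rows are
        left as zeros and flagged in :attr:`zero_rows`.
        """
        if self._unit is None:
            norms = np.linalg.norm(self.matrix, axis=1, keepdims=True)
            safe = np.where(norms == 0.0, 1.0, norms)
            self._unit = self.matrix / safe
        return self._unit

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<WordVectorStore |V|={len(self)} d={self.dim} "
            f"format={self.meta.format or '?'}>"
        )


def _case_variants(term: str) -> list[str]:
    out = [term]
    for cand in (term.lower(), term.capitalize()):
        if cand not in out:
            out.append(cand)
    return out


def lookup(
    store: WordVectorStore,
    term: str,
    oov_policy: OovPolicy = "case_fallback",
) -> np.ndarray:
    """Resolve ``term`` to a vector of length ``store.dim``.

    Policies:

    ``error``
        Exact case-sensitive match only.
    ``case_fallback``
        Exact, then lowercased, then capitalised.
    ``mean_of_words``
        For multiword terms (``"anxiety disorder"``): try the
        underscore-joined form first (``anxiety_disorder``, with case
        fallback), then fall back to the arithmetic mean of the
        in-vocabulary constituent word vectors, each resolved with case
        fallback.  Single words behave like ``case_fallback``.

    Raises
    ------
    OOVError
        When no key resolves; lists every attempted key.
    """
    if not term:
        raise ValueError("empty term")
    attempted: list[str] = []

    def try_keys(keys: Iterable[str]) -> np.ndarray | None:
        for key in keys:
            attempted.append(key)
            if key in store:
                return store.row(key)
        return None

    if oov_policy == "error":
        vec = try_keys([term])
        if vec is not None:
            return vec
        raise OOVError(term, attempted)

    if oov_policy == "case_fallback":
        vec = try_keys(_case_variants(term))
        if vec is not None:
            return vec
        raise OOVError(term, attempted)

    if oov_policy == "mean_of_words":
        joined = "_".join(_WORD_SPLIT.split(term.strip()))
        vec = try_keys(_case_variants(joined))
        if vec is not None:
            return vec
        if joined != term:
            vec = try_keys(v for v in _case_variants(term) if v not in attempted)
            if vec is not None:
                return vec
        words = [w for w in _WORD_SPLIT.split(term.strip()) if w]
        if len(words) > 1:
            parts = []
            for word in words:
                part = try_keys(
                    v for v in _case_variants(word) if v not in attempted
                )
                if part is not None:
                    parts.append(part)
            if parts:
                return np.mean(parts, axis=0)
        raise OOVError(term, attempted)

    raise ValueError(f"unknown oov_policy {oov_policy!r}")


@dataclass
class TermSet:
    """Probe terms annotated with their plotting category."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for term, category in self.entries:
            if not term:
                raise ValueError("empty term in TermSet")
            if category not in CATEGORIES:
                raise ValueError(
                    f"unknown category {category!r} for {term!r}; "
                    f"expected one of {CATEGORIES}"
                )

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_mapping(cls, mapping: dict[str, Sequence[str]]) -> "TermSet":
        """Build from ``{category: [terms...]}`` (config-file layout)."""
        entries = [
            (term, category)
            for category, terms in mapping.items()
            for term in terms
        ]
        return cls(entries)
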