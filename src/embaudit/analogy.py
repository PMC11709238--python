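"""Analogy batteries and the biased-item position statistic.

An occupational-stigma probe asks the embedding ``healthy : employable ::
depression : ?`` and inspects the ranked completions.  A completion is
counted as *biased* when it appears in a curated lexicon of undesirable
attributes (``unemployable``, ``unreliable``, ``incompetent``, ...); the
per-query statistic is the first (smallest) 1-based rank at which such a
token appears, or none.

Input exclusion: by convention the three probe words (and their case and
underscore variants) are removed from the candidate list.  Because a
return identical to B can be exactly the *unbiased* answer, exclusion is
a flag, and each result records any excluded input that would have
out-ranked the reported top-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .geometry import RankedNeighbors, analogy_target, cosine_similarity, top_k
from .store import OOVError, OovPolicy, WordVectorStore

__all__ = [
    "AnalogyQuery",
    "BiasLexicon",
    "AnalogyResult",
    "run_analogy",
    "run_battery",
    "reverse_query",
    "DEFAULT_LEXICON",
    "default_battery",
]

#: attributes × diagnoses probes anchored at "healthy", plus prestige
#: professions anchored at healthy × psychosis; editable via config.
_ATTRIBUTES = ("employable", "reliable", "competent", "resilient")
_DIAGNOSES = ("psychosis", "depression", "anxiety_disorder")
_PROFESSIONS = ("lawyer", "doctor", "surgeon", "engineer", "banker", "CEO")

#: undesirable-completion lexicon; matching is case-insensitive with
#: underscore→space folding, so "Unemployable" and "un_employable" hit.
DEFAULT_LEXICON = (
    "unemployable",
    "unreliable",
    "unreliability",
    "incompetent",
    "incompetence",
    "unresilient",
)


@dataclass(frozen=True)
class AnalogyQuery:
    """``a is to b as c is to ?`` with report depth ``k``."""

    a: str
    b: str
    c: str
    k: int = 10
    exclude_inputs: bool = True

    def __post_init__(self) -> None:
        if not (self.a and self.b and self.c):
            raise ValueError("analogy terms must be non-empty")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")

    def __str__(self) -> str:
        return f"{self.a} : {self.b} :: {self.c} : ?"


def _fold(token: str) -> str:
    return token.replace("_", " ").casefold()


@dataclass(frozen=True)
class BiasLexicon:
    """Set of completion tokens counted as biased returns."""

    entries: frozenset[str] = frozenset(DEFAULT_LEXICON)

    def __init__(self, entries: Iterable[str] = DEFAULT_LEXICON):
        object.__setattr__(self, "entries", frozenset(_fold(e) for e in entries))

    def matches(self, token: str) -> bool:
        return _fold(token) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class AnalogyResult:
    """Ranked completions of one analogy plus bias-rank bookkeeping.

    ``suppressed_inputs`` lists (token, similarity) pairs for excluded
    input words that would have out-ranked the reported top-1 — the
    annotation that flags possible all-terms-different artefacts.
    """

    query: AnalogyQuery
    ranked: RankedNeighbors | None = None
    biased_positions: list[int] = field(default_factory=list)
    first_biased_rank: int | None = None
    suppressed_inputs: list[tuple[str, float]] = field(default_factory=list)
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def _exclusion_keys(terms: Iterable[str]) -> set[str]:
    keys: set[str] = set()
    for term in terms:
        for base in {term, term.replace(" ", "_"), term.replace("_", " ")}:
            keys.update({base, base.lower(), base.capitalize(), base.upper()})
    return keys


def run_analogy(
    store: WordVectorStore,
    query: AnalogyQuery,
    lexicon: BiasLexicon | None = None,
    *,
    oov_policy: OovPolicy = "mean_of_words",
) -> AnalogyResult:
    """Answer one 3CosAdd analogy and locate biased completions.

    The ranked list is the ``query.k`` nearest tokens to the composite
    vector ``v(b) - v(a) + v(c)``; the probe words and their case and
    underscore variants are removed when ``query.exclude_inputs``.  An
    empty (or absent) lexicon yields no biased positions, not an error.
    """
    try:
        target = analogy_target(
            store, query.a, query.b, query.c, oov_policy=oov_policy
        )
    except (OOVError, ValueError) as exc:
        return AnalogyResult(query=query, error=str(exc))

    exclude = (
        _exclusion_keys((query.a, query.b, query.c))
        if query.exclude_inputs
        else set()
    )
    ranked = top_k(store, target, query.k, exclude=exclude)
    ranked.query_meta = str(query)

    biased = [
        pos
        for pos, (tok, _) in enumerate(ranked.items, start=1)
        if lexicon is not None and lexicon.matches(tok)
    ]

    suppressed: list[tuple[str, float]] = []
    if query.exclude_inputs and ranked.items:
        top1_sim = ranked.items[0][1]
        for tok in sorted(exclude):
            if tok in store and not store.zero_rows[store.index_of(tok)]:
                sim = cosine_similarity(store.row(tok), target)
                if sim > top1_sim:
                    suppressed.append((tok, sim))

    return AnalogyResult(
        query=query,
        ranked=ranked,
        biased_positions=biased,
        first_biased_rank=biased[0] if biased else None,
        suppressed_inputs=suppressed,
    )


def run_battery(
    store: WordVectorStore,
    queries: Sequence[AnalogyQuery],
    lexicon: BiasLexicon | None = None,
    *,
    oov_policy: OovPolicy = "mean_of_words",
) -> list[AnalogyResult]:
    """Run a battery of analogies; per-query failures become error records,
    never batch aborts."""
    if not queries:
        raise ValueError("empty analogy battery")
    return [
        run_analogy(store, q, lexicon, oov_policy=oov_policy) for q in queries
    ]


def reverse_query(query: AnalogyQuery) -> AnalogyQuery:
    """Swap the A and C roles, keeping B: ``a:b::c:?`` → ``c:b::a:?``.

    Mirrors the woman:doctor::man:? vs man:doctor::woman:? control pair;
    an involution (``reverse(reverse(q)) == q``).
    """
    return replace(query, a=query.c, c=query.a)


def default_battery(k: int = 10) -> list[AnalogyQuery]:
    """The shipped probe battery: employability attributes crossed with
    diagnoses, anchored at ``healthy``, plus prestige professions probed
    for psychosis."""
    queries = [
        AnalogyQuery("healthy", attr, diag, k=k)
        for attr in _ATTRIBUTES
        for diag in _DIAGNOSES
    ]
    queries += [
        AnalogyQuery("healthy", prof, "psychosis", k=k) for prof in _PROFESSIONS
    ]
    return queries
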