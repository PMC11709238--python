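"""Readers and writers for the standard static-embedding file dialects.

Three dialects are supported:

``word2vec_binary``
    ASCII header ``"<|V|> <d>\\n"``, then for each word a space-terminated
    token followed by ``d`` little-endian float32 values (optionally
    newline-separated records, as written by the original C tool).
``word2vec_text``
    Same header, ASCII float components.
``glove_text``
    Headerless; each line is ``<token> v1 ... vd`` and ``d`` is inferred
    from the first line.

Tokens in the binary dialect are decoded as UTF-8 with surrogate-escape
byte fallback: the GoogleNews vocabulary contains tokens that are not
valid UTF-8, and the fallback keeps them round-trippable.
"""

from __future__ import annotations

import logging
from os import PathLike
from pathlib import Path
from typing import Literal

import numpy as np

from .store import StoreMeta, WordVectorStore

__all__ = [
    "EmbeddingFormatError",
    "load_word2vec_binary",
    "load_word2vec_text",
    "load_glove_text",
    "load_embeddings",
    "write_store",
    "FORMATS",
]

logger = logging.getLogger(__name__)

EmbeddingFormat = Literal["word2vec_binary", "word2vec_text", "glove_text"]
FORMATS: tuple[str, ...] = ("word2vec_binary", "word2vec_text", "glove_text")

_ENC = ("utf-8", "surrogateescape")


class EmbeddingFormatError(ValueError):
    """Malformed embedding file (bad header, truncated block, bad value)."""


def _dedupe(tokens: list[str], matrix: np.ndarray, path: str):
    """Keep the first occurrence of any duplicated token, with a warning."""
    seen: dict[str, int] = {}
    keep: list[int] = []
    for i, tok in enumerate(tokens):
        if tok in seen:
            logger.warning(
                "duplicate token %r in %s (rows %d and %d); keeping first",
                tok, path, seen[tok], i,
            )
        else:
            seen[tok] = i
            keep.append(i)
    if len(keep) == len(tokens):
        return tokens, matrix
    return [tokens[i] for i in keep], matrix[keep]


def _parse_header(line: bytes | str, path: str) -> tuple[int, int]:
    if isinstance(line, bytes):
        line = line.decode("ascii", "replace")
    parts = line.split()
    if len(parts) != 2:
        raise EmbeddingFormatError(
            f"{path}: malformed header {line.strip()!r}; expected '<|V|> <d>'"
        )
    try:
        vocab_size, dim = int(parts[0]), int(parts[1])
    except ValueError:
        raise EmbeddingFormatError(
            f"{path}: non-integer header fields {line.strip()!r}"
        ) from None
    if vocab_size < 0 or dim <= 0:
        raise EmbeddingFormatError(
            f"{path}: header declares |V|={vocab_size}, d={dim}"
        )
    return vocab_size, dim


def load_word2vec_binary(path: str | PathLike) -> WordVectorStore:
    """Load a word2vec binary file (e.g. ``GoogleNews-vectors-negative300.bin``)."""
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.readline(128)
        vocab_size, dim = _parse_header(header, str(path))
        vec_bytes = 4 * dim
        tokens: list[str] = []
        rows = np.empty((vocab_size, dim), dtype=np.float32)
        for i in range(vocab_size):
            chunks = []
            while True:
                ch = fh.read(1)
                if not ch:
                    raise EmbeddingFormatError(
                        f"{path}: truncated at byte offset {fh.tell()} "
                        f"while reading token {i + 1}/{vocab_size}"
                    )
                if ch == b" ":
                    break
                if ch == b"\n" and not chunks:
                    continue  # record separator written by some tools
                chunks.append(ch)
            token = b"".join(chunks).decode(*_ENC)
            block = fh.read(vec_bytes)
            if len(block) != vec_bytes:
                raise EmbeddingFormatError(
                    f"{path}: truncated vector block for token {token!r} at "
                    f"byte offset {fh.tell()} (got {len(block)}/{vec_bytes} bytes)"
                )
            rows[i] = np.frombuffer(block, dtype="<f4")
            tokens.append(token)
    tokens, rows = _dedupe(tokens, rows, str(path))
    return WordVectorStore(
        tokens, rows, StoreMeta(source=str(path), format="word2vec_binary")
    )


def load_word2vec_text(path: str | PathLike) -> WordVectorStore:
    """Load a word2vec text file (header line, then one token per line)."""
    path = Path(path)
    with open(path, "r", encoding=_ENC[0], errors=_ENC[1]) as fh:
        header = fh.readline()
        vocab_size, dim = _parse_header(header, str(path))
        tokens, vectors = _read_text_body(fh, str(path), dim, first_lineno=2)
    if len(tokens) != vocab_size:
        raise EmbeddingFormatError(
            f"{path}: header declares {vocab_size} tokens, file has {len(tokens)}"
        )
    matrix = (
        np.array(vectors, dtype=np.float64)
        if tokens
        else np.empty((0, dim), dtype=np.float64)
    )
    tokens, matrix = _dedupe(tokens, matrix, str(path))
    return WordVectorStore(
        tokens, matrix, StoreMeta(source=str(path), format="word2vec_text"), dim=dim
    )


def load_glove_text(path: str | PathLike) -> WordVectorStore:
    """Load a GloVe text file (headerless; ``d`` inferred from line 1)."""
    path = Path(path)
    with open(path, "r", encoding=_ENC[0], errors=_ENC[1]) as fh:
        tokens, vectors = _read_text_body(fh, str(path), dim=None, first_lineno=1)
    if not tokens:
        raise EmbeddingFormatError(f"{path}: empty GloVe file, cannot infer d")
    matrix = np.array(vectors, dtype=np.float64)
    tokens, matrix = _dedupe(tokens, matrix, str(path))
    return WordVectorStore(
        tokens, matrix, StoreMeta(source=str(path), format="glove_text")
    )


def _read_text_body(fh, path: str, dim: int | None, first_lineno: int):
    tokens: list[str] = []
    vectors: list[list[float]] = []
    for lineno, line in enumerate(fh, start=first_lineno):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split(" ")
        token, comps = fields[0], fields[1:]
        if dim is None:
            dim = len(comps)
            if dim == 0:
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: no vector components on first line"
                )
        if len(comps) != dim:
            raise EmbeddingFormatError(
                f"{path}:{lineno}: expected {dim} components, found {len(comps)}"
            )
        try:
            vectors.append([float(x) for x in comps])
        except ValueError as exc:
            raise EmbeddingFormatError(f"{path}:{lineno}: {exc}") from None
        tokens.append(token)
    return tokens, vectors


_LOADERS = {
    "word2vec_binary": load_word2vec_binary,
    "word2vec_text": load_word2vec_text,
    "glove_text": load_glove_text,
}


def load_embeddings(path: str | PathLike, format: EmbeddingFormat) -> WordVectorStore:
    """Dispatch to the loader for ``format``."""
    try:
        loader = _LOADERS[format]
    except KeyError:
        raise ValueError(
            f"unknown embedding format {format!r}; expected one of {FORMATS}"
        ) from None
    return loader(path)


def write_store(
    store: WordVectorStore, path: str | PathLike, format: EmbeddingFormat
) -> None:
    """Write ``store`` so the matching loader round-trips it.

    Tokens containing whitespace are unrepresentable in every dialect
    (space is the field separator) and raise ``ValueError``.
    """
    if format not in FORMATS:
        raise ValueError(
            f"unknown embedding format {format!r}; expected one of {FORMATS}"
        )
    for tok in store.tokens:
        if any(c.isspace() for c in tok):
            raise ValueError(
                f"token {tok!r} contains whitespace and cannot be written "
                f"to the {format} dialect"
            )
    path = Path(path)
    if format == "word2vec_binary":
        with open(path, "wb") as fh:
            fh.write(f"{len(store)} {store.dim}\n".encode("ascii"))
            mat32 = store.matrix.astype("<f4")
            for tok, row in zip(store.tokens, mat32):
                fh.write(tok.encode(*_ENC) + b" " + row.tobytes() + b"\n")
        return
    with open(path, "w", encoding=_ENC[0], errors=_ENC[1], newline="\n") as fh:
        if format == "word2vec_text":
            fh.write(f"{len(store)} {store.dim}\n")
        for tok, row in zip(store.tokens, store.matrix):
            fh.write(tok + " " + " ".join(f"{x:.6f}" for x in row) + "\n")
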