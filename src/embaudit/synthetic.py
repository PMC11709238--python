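"""Synthetic embedding stores with known ground-truth geometry.

Real pretrained embeddings are gigabytes of opaque numbers; testing an
audit pipeline against them proves nothing about correctness.  This
generator builds small vocabularies whose geometry is known exactly:

* two orthonormal axis directions ``u_x``, ``u_y``, with the four pole
  words planted at ``±u_x`` / ``±u_y`` so that the pole-difference axis
  vector is exactly ``2 u``;
* planted probe terms ``v = x u_x + y u_y + r u_res + ε`` with chosen
  loadings ``(x, y)`` (``x² + y² ≤ 1``; the residual ``r = √(1-x²-y²)``
  goes to a term-specific direction orthogonal to both axes), so that at
  noise σ = 0 the projection scores equal the loadings exactly;
* planted analogy parallelograms ``v_d = v_b − v_a + v_c + η`` whose
  completion ``d`` beats every other token's cosine against the 3CosAdd
  composite by at least a margin δ (verified at generation time);
* isotropic unit-norm background noise words.

Noise vectors ε have independent N(0, σ²/d) components, so ‖ε‖ ≈ σ is
the expected perturbation relative to the unit-norm planted vectors.
All randomness derives from the spec's seed; regenerating with the same
spec is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import numpy as np

from .formats import write_store
from .store import StoreMeta, WordVectorStore

__all__ = ["SyntheticSpec", "GroundTruth", "GenerationError", "generate", "emit_fixture"]


class GenerationError(RuntimeError):
    """A requested margin or configuration could not be realised."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth recipe for one synthetic embedding store.

    ``planted_terms`` are ``(term, x_loading, y_loading)`` triples with
    ``x² + y² ≤ 1``; ``analogy_quads`` are ``(a, b, c, d, margin)``
    tuples.  Defaults: 50 dimensions, 500 background words, noise
    σ = 0.02, seed 20250108.
    """

    dim: int = 50
    n_background: int = 500
    planted_terms: tuple[tuple[str, float, float], ...] = ()
    pole_pairs: tuple[tuple[str, str], tuple[str, str]] = (
        ("healthy", "ill"),
        ("employable", "unemployable"),
    )
    analogy_quads: tuple[tuple[str, str, str, str, float], ...] = ()
    noise_sd: float = 0.02
    seed: int = 20250108

    def __post_init__(self) -> None:
        if self.dim < 4:
            raise ValueError("dim must be >= 4 (two axes plus residual room)")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        names = [p for pair in self.pole_pairs for p in pair]
        names += [t for t, _, _ in self.planted_terms]
        if len(set(names)) != len(names):
            raise ValueError("planted terms and pole words must be distinct")
        for term, x, y in self.planted_terms:
            if x * x + y * y > 1.0 + 1e-12:
                raise ValueError(
                    f"loadings for {term!r} violate x² + y² <= 1: ({x}, {y})"
                )
        for a, b, c, d, delta in self.analogy_quads:
            if delta < 0:
                raise ValueError(f"negative margin for quad {(a, b, c, d)}")
            if len({a, b, c, d}) != 4:
                raise ValueError(f"quad terms must be pairwise distinct: {(a, b, c, d)}")


@dataclass
class GroundTruth:
    """What the pipeline should recover from the generated store."""

    loadings: dict[str, tuple[float, float]] = field(default_factory=dict)
    quad_top1: dict[tuple[str, str, str], str] = field(default_factory=dict)
    pole_pairs: tuple[tuple[str, str], tuple[str, str]] = (
        ("healthy", "ill"),
        ("employable", "unemployable"),
    )


def _orthonormal_pair(rng: np.random.Generator, dim: int) -> tuple[np.ndarray, np.ndarray]:
    q, _ = np.linalg.qr(rng.standard_normal((dim, 2)))
    return q[:, 0].copy(), q[:, 1].copy()


def _unit_complement(rng: np.random.Generator, basis: list[np.ndarray], dim: int) -> np.ndarray:
    """Random unit vector orthogonal to every vector in ``basis``."""
    for _ in range(64):
        v = rng.standard_normal(dim)
        for b in basis:
            v -= (v @ b) * b
        n = np.linalg.norm(v)
        if n > 1e-9:
            return v / n
    raise GenerationError("could not draw a vector in the orthogonal complement")


def generate(spec: SyntheticSpec) -> tuple[WordVectorStore, GroundTruth]:
    """Build the store and its ground truth deterministically from the seed.

    Raises :class:`GenerationError` if a quad's margin cannot be honoured
    after a bounded number of background resampling rounds.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.dim
    u_x, u_y = _orthonormal_pair(rng, d)

    tokens: list[str] = []
    rows: list[np.ndarray] = []

    def add(token: str, vec: np.ndarray) -> None:
        tokens.append(token)
        rows.append(vec)

    def noise() -> np.ndarray:
        if spec.noise_sd == 0.0:
            return np.zeros(d)
        return rng.normal(0.0, spec.noise_sd / np.sqrt(d), d)

    (posx, negx), (posy, negy) = spec.pole_pairs
    add(posx, u_x.copy())
    add(negx, -u_x)
    add(posy, u_y.copy())
    add(negy, -u_y)

    truth = GroundTruth(pole_pairs=spec.pole_pairs)
    for term, x, y in spec.planted_terms:
        r = float(np.sqrt(max(0.0, 1.0 - x * x - y * y)))
        u_res = _unit_complement(rng, [u_x, u_y], d)
        add(term, x * u_x + y * u_y + r * u_res + noise())
        truth.loadings[term] = (x, y)

    quad_vectors: dict[str, np.ndarray] = {}
    for a, b, c, dd, _delta in spec.analogy_quads:
        for t in (a, b, c):
            if t not in quad_vectors and t not in tokens:
                quad_vectors[t] = _unit_complement(rng, [u_x, u_y], d)
                add(t, quad_vectors[t])
        va, vb, vc = (rows[tokens.index(t)] for t in (a, b, c))
        add(dd, vb / np.linalg.norm(vb) - va / np.linalg.norm(va)
            + vc / np.linalg.norm(vc) + noise())
        truth.quad_top1[(a, b, c)] = dd

    n_named = len(tokens)
    width = max(4, len(str(max(spec.n_background, 1))))
    bg = rng.standard_normal((spec.n_background, d))
    bg /= np.linalg.norm(bg, axis=1, keepdims=True)
    for i in range(spec.n_background):
        add(f"bg{i:0{width}d}", bg[i])

    matrix = np.vstack(rows) if rows else np.empty((0, d))
    # enforce each quad's cosine margin by resampling offending background
    for a, b, c, dd, delta in spec.analogy_quads:
        ia, ib, ic, idd = (tokens.index(t) for t in (a, b, c, dd))
        va, vb, vc = matrix[ia], matrix[ib], matrix[ic]
        target = (vb / np.linalg.norm(vb) - va / np.linalg.norm(va)
                  + vc / np.linalg.norm(vc))
        t_unit = target / np.linalg.norm(target)
        unit = matrix / np.linalg.norm(matrix, axis=1, keepdims=True)
        sims = unit @ t_unit
        ceiling = sims[idd] - delta
        for _ in range(200):
            bad = np.flatnonzero(sims > ceiling)
            bad = bad[bad != idd]
            fixed_bad = bad[bad < n_named]
            if fixed_bad.size:
                raise GenerationError(
                    f"margin {delta} for quad {(a, b, c, dd)} violated by "
                    f"non-background tokens {[tokens[j] for j in fixed_bad]}"
                )
            if bad.size == 0:
                break
            fresh = rng.standard_normal((bad.size, d))
            fresh /= np.linalg.norm(fresh, axis=1, keepdims=True)
            matrix[bad] = fresh
            sims[bad] = fresh @ t_unit
        else:
            raise GenerationError(
                f"could not realise margin {delta} for quad {(a, b, c, dd)} "
                f"after bounded retries (n_background={spec.n_background})"
            )

    store = WordVectorStore(
        tokens, matrix, StoreMeta(source=f"synthetic(seed={spec.seed})",
                                  format="synthetic")
    )
    return store, truth


def emit_fixture(spec: SyntheticSpec, out_dir: str | PathLike) -> Path:
    """Write the store in all three file dialects plus ``ground_truth.json``.

    Returns the fixture directory.  Intended for loader round-trip and
    end-to-end CLI tests; text dialects are byte-deterministic per seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    store, truth = generate(spec)
    write_store(store, out / "vectors_word2vec.bin", "word2vec_binary")
    write_store(store, out / "vectors_word2vec.txt", "word2vec_text")
    write_store(store, out / "vectors_glove.txt", "glove_text")
    payload = {
        "spec": {
            "dim": spec.dim,
            "n_background": spec.n_background,
            "planted_terms": [list(t) for t in spec.planted_terms],
            "pole_pairs": [list(p) for p in spec.pole_pairs],
            "analogy_quads": [list(q) for q in spec.analogy_quads],
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        },
        "loadings": {t: list(xy) for t, xy in truth.loadings.items()},
        "quad_top1": [
            {"a": a, "b": b, "c": c, "d": dd}
            for (a, b, c), dd in truth.quad_top1.items()
        ],
    }
    (out / "ground_truth.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    return out
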