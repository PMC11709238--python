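# Methods

## The audit model

A static word embedding is a map from a vocabulary V to vectors in R^d
(d = 300 for the standard pretrained releases). All scoring is by cosine
similarity, `cos(a, b) = a·b / (|a||b|)`, clamped to [−1, 1] against
floating-point overshoot; it is undefined (an error) for zero vectors,
and all-zero rows in a store are retained but excluded from
nearest-neighbour candidacy.

**Analogy probes.** `A : B :: C : ?` is answered by the 3CosAdd rule:
rank every token by cosine similarity to the composite vector
`v(B) − v(A) + v(C)` computed on unit-normalised input vectors. Reported
similarities are cosines against the composite vector itself, not against
`v(C)`: this matches the behaviour of the `most_similar`-style library
implementations whose published numbers an auditor will want to
reproduce. Both conventions are exposed (`normalize_inputs` flag).
Search is exhaustive and exact — vocabularies at audit scale do not
justify approximate indexes, and bit-reproducibility matters. Ties are
broken by ascending vocabulary (file) index, which makes results stable
across runs and platforms.

By the *all-terms-different* convention the three probe words and their
case/underscore variants are excluded from the candidates. Because a
completion identical to B can be precisely the unbiased answer, exclusion
is a per-query flag, and every result records any excluded input that
would have out-ranked the reported top-1, so the analyst can see when the
convention manufactured the headline.

**Bias statistic.** A completion is *biased* iff it belongs to a curated
lexicon of undesirable attributes; matching is case-insensitive with
underscore→space folding (semantic hits, not surface forms). The
per-query statistic is the first (smallest) 1-based biased rank within
the top-k window (k = 10 by default), or none. Battery-level summaries
count queries biased at rank 1, within 5, within 10, or not at all. The
statistic is deliberately judgement-free: bias is lexicon membership,
and the lexicon is a config input.

**Axis projection.** A pole pair (p, n) defines the axis vector
`v(p) − v(n)` on the *raw* (unnormalised) stored vectors; a term's
coordinate is its cosine similarity to that vector, so coordinates live
in [−1, 1] and are invariant to positive rescaling of the term vector.
Swapping the poles negates every score exactly. Two axes give each term
a 2-D coordinate; no dimensionality reduction is applied on top — the
coordinates are the similarity scores themselves, which is the definition
that reproduces published per-term values, and the scatter plot is a thin
rendering layer over the unit-tested coordinates table. Scores are
reported at six decimals. The fixed plotting contract colours psychiatric
diagnoses green, physical diagnoses blue, favourable-attribute controls
red and very-healthy controls yellow.

**Out-of-vocabulary policy.** Stores are case-sensitive (news-corpus
embeddings keep `Lawyer` and `lawyer` distinct by design); case handling
is query-time only. Policies: `error` (exact match), `case_fallback`
(exact → lower → capitalised), `mean_of_words` (underscore-joined form
first — GoogleNews stores phrases as `anxiety_disorder` — then the mean
of the constituent in-vocabulary word vectors). `mean_of_words` is the
default for probe terms because single-word GloVe vocabularies cannot
contain multiword controls like `olympic gold medallist`; it is a
reasonable stand-in, not a claim about how any particular library
resolves phrases, and unresolved terms are always reported, never
silently dropped.

## The synthetic generator

The generator emulates exactly the geometric structure the audits
measure, and nothing else:

* Two orthonormal axis directions u_x, u_y are drawn (QR of a seeded
  Gaussian matrix); the four pole words are planted at ±u_x, ±u_y so the
  pole-difference axis is exactly 2u and ground-truth scores are closed
  form.
* A planted term with loadings (x, y), x² + y² ≤ 1, gets
  `v = x·u_x + y·u_y + r·u_res + ε` with `r = √(1−x²−y²)` on a
  term-specific unit direction orthogonal to both axes. At noise σ = 0
  the projection of v on either axis equals the loading exactly.
* An analogy quad (a, b, c, d, δ) plants `v_d = v_b − v_a + v_c + η` and
  *verifies* at generation time that every other token's cosine against
  the 3CosAdd composite sits at least δ below d's, resampling offending
  background words a bounded number of times and failing loudly
  (`GenerationError`) if the margin is infeasible — e.g. when a planted,
  non-resampleable token violates it.
* Background words are isotropic unit-norm Gaussian vectors. Noise ε has
  i.i.d. N(0, σ²/d) components, so ‖ε‖ ≈ σ measures the perturbation
  relative to the unit-norm planted vectors.
* Planted vectors are stored raw (not re-normalised after noise): cosine
  scoring is scale-invariant and raw storage exercises the normalisation
  code path.
* All randomness flows from one integer seed; text-dialect fixture files
  are byte-identical across runs. Defaults: d = 50, 500 background
  words, σ = 0.02, seed 20250108.

What the generator does **not** emulate: corpus co-occurrence statistics,
word-frequency effects (e.g. common diagnoses having better-estimated
vectors than rare ones), anisotropy of real embedding spaces, or phrase
vocabularies. Passing the synthetic suite therefore demonstrates that the
pipeline measures planted geometry correctly — it does not by itself say
anything about what any real embedding contains. Conclusions about real
models come from running the audits on the pretrained files.

## Numerical choices

* Similarities are computed in float64 on row-normalised matrices; the
  word2vec binary dialect stores float32, so binary round trips are exact
  to ≈5·10⁻⁷ on order-1 values. Text dialects print six decimals
  (round-trip error ≤ 5·10⁻⁷ absolute; the GloVe tolerance used in tests
  is 1e-3).
* Degenerate inputs fail loudly: zero query vectors, identical pole
  vectors, empty batteries and malformed files (bad header, truncated
  vector block with the byte offset named, inconsistent GloVe row width
  with the line number named) all raise typed errors. Duplicate file
  tokens keep the first occurrence with a warning, mirroring common
  loader behaviour.
* Requesting more neighbours than there are eligible tokens returns all
  eligible tokens and logs a notice.

## Verification study (problem sizes)

The acceptance script and suite run the study at desk scale, chosen so
the whole cycle completes in seconds while keeping each measurement
well-powered: 200 randomised stores (|V| ≤ 200, d ≤ 20, k ≤ 10) for
oracle equivalence of the search; 20 seeded stores × 30 planted terms at
σ = 0.01 for parameter recovery (Pearson r ≥ 0.99 per axis; exact to
1e-6 at σ = 0); 50 seeded replicates of a δ = 0.05 quad for planted-bias
recovery; 15 randomised stores × 3 dialects for round trips; and an
eleven-probe battery with exactly one planted biased completion for the
summary statistics. The oracles are pure-Python full-sort/summation
implementations kept independent of the package's vectorised paths.

## Known limitations

* The biased-rank statistic has no significance test attached; rank
  differences between probes are descriptive. Effect-size methods (WEAT,
  MAC, SAME) are out of scope.
* Contextual embeddings (BERT/ELMo-class) are out of scope; the package
  audits static vector files only.
* The `mean_of_words` phrase resolution is a documented approximation;
  audits of multiword terms on single-word vocabularies inherit it.
* Published six-decimal per-term values for GloVe depend on the exact
  distributed release; when raw values cannot be matched, the documented
  fallback is to check the published rank ordering instead.
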