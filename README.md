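# embaudit

Audit static word embeddings for occupational bias against psychiatric
diagnoses.

AI-assisted recruiting (resume parsing, job recommenders) is built on
pretrained word embeddings such as Word2Vec/GoogleNews and GloVe. If those
embeddings place *depression* closer to *unemployable* than to
*employable*, downstream systems can silently discriminate against job
seekers with mental health conditions. `embaudit` implements the two
standard probes used to measure this, for anyone (clinical informaticians,
fairness auditors, NLP practitioners) who needs to run them reproducibly:

1. **3CosAdd word analogies with a biased-rank statistic.** An analogy
   `A : B :: C : ?` is solved by ranking every vocabulary token *w* by

   ```
   score(w) = cos(v(w),  v(B) − v(A) + v(C))
   ```

   with the input vectors unit-normalised and (by convention) the three
   probe words excluded from the candidates. A probe like
   `healthy : employable :: depression : ?` is scored by the **first biased
   rank**: the smallest position in the top-*k* list occupied by a token
   from a curated bias lexicon (*unemployable*, *unreliable*,
   *incompetent*, ...), or none.

2. **Semantic-axis projection.** A pole pair defines an axis vector
   `v(healthy) − v(ill)`; a term's coordinate is its cosine similarity to
   that vector. Two axes (healthy–ill × employable–unemployable, with a
   normal–abnormal × reliable–unreliable robustness repeat) chart
   psychiatric diagnoses against physical diagnoses and healthy control
   terms on a 2-D plane.

Because pretrained embeddings are multi-gigabyte downloads, the package
ships a seeded **synthetic embedding generator** that plants known axis
loadings, analogy parallelograms (`v_D = v_B − v_A + v_C` with a
controlled cosine margin) and isotropic background words, so the whole
pipeline is testable offline with exact ground truth.

## Worked example

Generate a synthetic store with three planted terms and one planted
analogy, then audit it:

```python
import embaudit as ea

spec = ea.SyntheticSpec(
    planted_terms=(("depressed", -0.10, -0.08), ("fit", 0.30, 0.25)),
    analogy_quads=(("well", "productive", "psychotic", "workshy", 0.05),),
    n_background=200, noise_sd=0.0, seed=7,
)
store, truth = ea.generate(spec)

res = ea.run_analogy(store,
                     ea.AnalogyQuery("well", "productive", "psychotic"),
                     ea.BiasLexicon(["workshy"]))
print(res.ranked.items[0], res.first_biased_rank)

x = ea.build_axis(store, "healthy", "ill")
print(round(ea.project(store, "depressed", x), 6))
```

prints

```
('workshy', 1.0) 1
-0.1
```

i.e. the planted biased completion *workshy* is returned at rank 1 with
cosine similarity 1.0 (the parallelogram is exact at noise σ=0), so the
first biased rank is 1; and *depressed* projects onto the healthy–ill
axis at exactly its planted loading −0.10.

The same study from the shell:

```bash
embaudit simulate --out fixture/            # writes all 3 file dialects + ground truth
embaudit audit-axes --embeddings fixture/vectors_glove.txt --format glove-txt \
    --x-poles healthy,ill --y-poles employable,unemployable --out axes_out/
embaudit audit-analogy --embeddings fixture/vectors_word2vec.bin \
    --format word2vec-bin --out analogy_out/
embaudit audit-all --config study.yaml --out full_out/
```

Each audit writes `analogy_results.tsv` / `projections.tsv`,
`summary.json`, `scatter.png` and a plain-text `report.txt`; the report
records the embedding file's SHA-256 so results are attributable to an
exact artefact.

## Auditing real pretrained embeddings

Point the CLI at a standard embedding file — the GoogleNews Word2Vec
binary (`word2vec-bin`) or any GloVe text release (`glove-txt`). Multiword
probes like `anxiety disorder` resolve via the underscore-joined vocabulary
entry when present, else the mean of the constituent word vectors. The
optional published-value tests in `tests/test_acceptance.py` run
automatically when the files are placed at
`repro/GoogleNews-vectors-negative300.bin` and `repro/glove.6B.300d.txt`.

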