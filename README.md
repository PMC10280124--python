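# fdmine

Text-mining pipeline for the **"future directions" sections** of scientific
corpora — the closing paragraphs where authors state the follow-up work they
consider worthwhile.  Aggregated over a large corpus (the package emulates
the structure of the open COVID-19 literature releases: a metadata table plus
one full-text JSON per paper), these passages reveal which research topics a
field expects to grow, and how those expectations shift over time.

The pipeline:

1. **Ingest & clean** — load the metadata CSV and full-text JSONs; keep
   English, 2020-or-later, full-text, non-duplicate records; audit every
   dropped row with a reason code.
2. **Extract** — rule-based extraction of future-directions text: the final
   body paragraph (position rule) plus terminal-section paragraphs that
   contain a trigger phrase such as *"future work"* or *"prospective"*
   (keyword rule), scored by precision/recall/F1 against labeled samples.
3. **Vectorize** — normalize (lowercase, strip punctuation, standard +
   corpus-specific stop words, pluggable lemmatizer) and weight with TF-IDF,
   `idf(t) = ln((1+N)/(1+df_t)) + 1`, vocabulary capped at the 5,000 terms of
   highest document frequency, rows L2-normalized.
4. **Embed** — a symmetric autoencoder (four relu hidden layers per side,
   linear bottleneck) trained with Adam (lr 1e-4, batch 7, betas 0.9/0.999)
   to minimize `Loss(y, y') = Σᵢ (yᵢ − y'ᵢ)² / n`; the bottleneck
   activations are the document embeddings.
5. **Cluster & evaluate** — Lloyd-style k-means with a pluggable assignment
   distance (cosine, correlation, Jaccard, Bray-Curtis); cluster number
   chosen by the elbow of the distortion curve over k ∈ [2, 20]; clusterings
   scored with normalized mutual information,
   `NMI(X;Y) = 2 I(X;Y) / (H(X) + H(Y))`.
6. **Topic dynamics** — per-month topic proportions; the window split into
   prophase/metaphase/telophase; each topic's transition between adjacent
   stages classified as **birth, inheritance, division, merger, or
   extinction** (5% proportion threshold, overlap-mass rules).

A first-class synthetic-corpus generator plants topic vocabularies, monthly
topic trends, trigger keywords, and every kind of noise record the cleaning
rules target, so the whole pipeline is testable offline with exact ground
truth.

## Worked example

```python
from fdmine import (SyntheticConfig, generate_corpus, extract_corpus,
                    tokenize_units, build_tfidf, AutoencoderConfig,
                    train_autoencoder, encode, cluster_embeddings, nmi)

corpus = generate_corpus(SyntheticConfig(n_topics=3, docs_per_month=50,
                                         months=[f"2020-{m:02d}" for m in range(1, 7)],
                                         topic_vocab_size=60,
                                         background_vocab_size=120, seed=100))
units = extract_corpus(corpus.records)
matrix = build_tfidf(tokenize_units(units), max_features=500)
cfg = AutoencoderConfig(input_dim=len(matrix.vocabulary),
                        hidden_dims=(128, 96, 64, 32), bottleneck_dim=16,
                        epochs=15, steps_per_epoch=150, seed=42)
model, history = train_autoencoder(matrix, cfg)
emb = encode(model, matrix)
assignment = cluster_embeddings(emb, 3, metric="cosine", seed=0)
truth = [corpus.truth_topic[d] for d in assignment.doc_ids]
print(f"extracted units: {len(units)}")
print(f"final training loss: {history.per_epoch[-1]:.4f}")
print(f"NMI vs planted topics: {nmi(assignment.labels.tolist(), truth):.3f}")
```

prints

```
extracted units: 300
final training loss: 0.7073
NMI vs planted topics: 1.000
```

All 300 generated documents yield an extraction unit (no keyword omission was
configured), the autoencoder's mean squared reconstruction error settles
near 0.7 per (unit-norm) document, and cosine k-means on the embeddings
reproduces the three planted topics exactly (NMI = 1).

The same analysis is available from the shell:

```bash
fdmine generate --outdir corpus --n-topics 3 --docs-per-month 50 --seed 100
fdmine run-all --config pipeline.yaml        # or stage by stage:
fdmine clean --config pipeline.yaml
fdmine extract --config pipeline.yaml
...
```

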