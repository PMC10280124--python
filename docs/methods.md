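# Methods

## Corpus model and cleaning

A corpus is a metadata table (one row per paper: id, title, abstract,
publication date, language, journal, authors, full-text flag) plus one JSON
document per full-text paper holding ordered body paragraphs with section
names.  Cleaning keeps records that are English, dated on/after 2020-01,
have full text, and are not duplicates; each dropped row receives exactly one
reason code with precedence duplicate → non_english → pre_2020 →
no_full_text.  Duplicates are keyed by doc_id first and by the exact
(title, abstract) pair second, first occurrence winning.  Records whose date
fails to parse are flagged at load time and fall outside the observation
window (dropped as pre_2020) rather than being silently removed.  The loader
itself deduplicates by doc_id by default; the pipeline loads with
deduplication off so the cleaning audit counts duplicate rows — the audit is
the single source of drop statistics.

## Future-directions extraction

Authors conventionally put follow-up plans in the closing paragraph(s).  The
extractor combines a position rule — the final body paragraph — with a
keyword rule — any paragraph of the terminal section (the last named section)
containing a trigger phrase.  The default trigger list is "future
directions", "future work", "future research", "future studies", "future
step", "prospective", "we plan"; matching is case-insensitive substring
search after whitespace normalization, before any stemming or lemmatization
(extraction precedes normalization in the pipeline order).  A unit is
emitted only when some candidate paragraph actually contains a trigger
phrase; the matched rule ("both" when the final paragraph matched,
"keyword" otherwise) and the matched phrases are recorded.  "Last
paragraph" means the final entry of the structured body; prose is never
re-segmented.  Extraction quality is scored as precision/recall/F1 over
document ids against a gold labeling, with the degenerate conventions
precision = 1 when nothing is predicted and recall = 1 when the gold set is
empty.

## Normalization and TF-IDF

Normalization lowercases, deletes punctuation (underscore is kept as a word
character), removes a standard English stop-word list (scikit-learn's) plus
corpus-specific custom stop words — by default the future-directions
boilerplate terms *paper, study, research, future, plan* — and applies an
optional lemmatizer hook (identity by default, so tests run hermetically; a
biomedical lemmatizer can be plugged in for real corpora).

The vocabulary is capped at the `max_features` (default 5,000) terms with
the highest **document** frequency, ties broken lexicographically; document
frequency is preferred over collection frequency because it is stable under
document-length variation.  Weights are raw term frequency times smoothed
inverse document frequency, `idf(t) = ln((1+N)/(1+df_t)) + 1`, and rows are
L2-normalized (all-zero rows are left as zeros).  This is the standard
smoothed TF-IDF variant; the weighting itself is delegated to
scikit-learn's `TfidfTransformer`, which implements exactly this form.

## Distance measures

Four vector distances parameterize clustering:

* cosine: `1 − x·y/(‖x‖‖y‖)`
* correlation: `1 − Pearson(x, y)`
* Jaccard (binary): mismatching positions / union support, on binarized
  vectors (entry ≠ 0)
* Bray-Curtis: `Σ|xₖ−yₖ| / (Σxₖ + Σyₖ)`, for non-negative input

All four are implemented as distances (cosine and correlation as one minus
the similarity) so they are interchangeable in the clustering stage.  The
formulas are dimension-agnostic and are applied to document rows; they work
equally on term columns.  Degenerate inputs (zero vector for cosine,
constant vector for correlation, empty union support for Jaccard, zero mass
for Bray-Curtis) raise a typed error rather than producing NaN; the pairwise
driver excludes degenerate rows and reports their indices so downstream
policy can treat them explicitly.  Numerical results are clipped to the
metric's mathematical range to suppress rounding noise at the boundaries.

## Autoencoder

A symmetric feed-forward autoencoder embeds documents: encoder
input → h₁ → h₂ → h₃ → h₄ → bottleneck, decoder mirrored.  The count of
four hidden layers per side is fixed; the layer widths are free parameters
defaulting to a geometric taper 1024/512/128/64 with bottleneck 32.  Hidden layers use relu (sigmoid/tanh available); the bottleneck and
output layers are linear.  Weights are initialized with seeded Glorot
uniform draws.

Training minimizes the mean squared reconstruction error
`Loss(y, y′) = Σᵢ (yᵢ − y′ᵢ)²/n`, read with `i` indexing **samples**: each
term is the squared Euclidean norm of one row's residual and `n` is the
sample count.  The optimizer is Adam with learning rate 1e-4, β₁ = 0.9,
β₂ = 0.999, ε = 1e-8.  "Batch size 7" and "300 steps per epoch" are taken
literally: every epoch performs exactly 300 Adam steps over mini-batches of
7 rows drawn from a per-epoch reshuffled cyclic stream, independent of
corpus size.  The default is 100 epochs; optional early stopping (patience
10, min-delta 1e-6) is off by default so runs are exactly reproducible.
Everything runs on plain numpy with a seeded generator, so training is
deterministic to the bit on a fixed platform.  A non-finite epoch loss
raises a divergence error naming the epoch.

## Clustering

The clustering algorithm is generalized Lloyd iteration — k-means with a
pluggable assignment distance.  Centers are seeded k-means++-style (first
center uniform, subsequent centers with probability proportional to squared
distance under the chosen metric), points are assigned to the nearest center
(ties to the lowest index), centers are recomputed as coordinate means
(re-normalized for cosine), empty clusters are reseeded from the farthest
point, and iteration stops at a label fixpoint or `max_iter`.  The best of
`restarts` (default 5) seeded restarts by total within-cluster distance is
returned.  Lloyd iteration is used because the distortion objective and the
elbow analysis presuppose a k-means-style procedure.

**Distortion** is the total squared Euclidean distance of each sample to its
cluster's coordinate-mean centroid, *regardless of the assignment metric* —
the squared-error form is stated unconditionally, and the coordinate mean is
its minimizer.  The **elbow scan** computes distortion for k ∈ [2, 20]
(configurable) under a shared seed and selects the knee as the interior k
maximizing the discrete second difference of the curve.  Because
imperfectly converged runs put small upward bumps on the plateau that
masquerade as curvature, knee detection operates on the monotone
running-minimum envelope of the curve (the raw curve is reported).  The
knee's *strength* — its curvature as a fraction of the curve's total drop —
gates a reliability flag (default threshold 0.3): structureless data decays
smoothly and spreads its curvature, while planted structure concentrates it
at the true k.  A manual override replaces the knee when the analyst has
made the visual judgment themselves.

## Clustering evaluation

Entropy, mutual information and NMI are plug-in estimates from empirical
label distributions, in natural log (NMI is base-invariant):
`H(X) = −Σ p log p`, `I(X;Y) = Σ p(x,y) ln[p(x,y)/(p(x)p(y))]`,
`NMI = 2I/(H(X)+H(Y))`, with `0·log 0 ≡ 0` and the convention that two
identical single-class labelings have NMI 1.  On synthetic corpora the NMI
reference is the planted topic labels.  Real corpora carry no reference
labeling; there the comparison harness reports NMI across seeds/metrics as a
stability measure instead, and no accuracy claim is made.

The metric-comparison harness trains the autoencoder once per shared seed
(the MSE objective does not depend on the clustering metric), clusters the
same embeddings under each of the four metrics, and reports NMI per metric
plus the shared loss trajectory and an optional metric-specific evaluation
loss (mean reconstruction distance under that metric).

## Topic timeline and evolution

Cluster keywords are ranked by contrast — mean in-cluster TF-IDF weight
minus mean out-of-cluster weight — a documented substitute for an unstated
derivation; human-readable topic names are display labels supplied by
configuration, never inferred.

The timeline counts documents per month per cluster; proportions are counts
over the month total, and months with zero documents are flagged rather than
fabricated.  The observation window is split into three contiguous,
as-equal-as-possible stages (remainder months to the earlier blocks):
prophase, metaphase, telophase.  Stage-level proportions are
document-weighted means (total stage counts normalized within the stage),
which is robust to the strong monthly volume skew real corpora show.

Stage overlap is measured as **document flow**: `overlap[i, j]` is the
fraction of cluster i's stage-t documents whose nearest stage-(t+1)
stage-restricted centroid is cluster j (row-normalized).  A stable topic
yields a near-identity row; drifting content spreads row mass.  (An earlier
centroid-similarity variant proved uninformative: shared background
vocabulary makes all centroids similar, flattening every row.)

Evolution classification compares stage-mean proportions against a strict
threshold (default 5%: exactly 5% is *not* above) and assigns every
above-threshold topic exactly one event per adjacent stage pair:

* **birth** — rises above the threshold, unless a splitting/merging survivor
  feeds it at least `branch_min` of its row mass (then it is a
  division/merger target, mirroring topics that emerge by splitting off an
  existing one);
* **extinction** — falls below the threshold;
* survivors (above in both stages) are classified by their overlap row:
  ≥ 2 branches of at least `branch_min` (default 0.25) → **division**; a
  single dominant link holding at least `inherit_min` (default 0.6) of both
  its row and its column mass → **inheritance**; dominant links sharing one
  successor → **merger** (a lone merger candidate falls back to
  inheritance).

The precedence division > inheritance > merger-candidate makes the event
assignment a deterministic function of (timeline, overlaps, thresholds).

## Synthetic corpus generator

The generator defines the study conditions.  Documents are bags of synthetic
tokens from K pairwise-disjoint topic vocabularies (`topic3_word017`) plus a
shared background vocabulary (`bg_word0042`), assembled into
Introduction/Methods/Discussion pseudo-sections and a final
future-directions paragraph (about a quarter of the document's tokens) that
carries a verbatim trigger phrase with probability 1 − `keyword_omission_rate`.
Token draws come from the document's topic vocabulary with probability
`topic_word_fraction` (default 0.9).  Document length is Poisson with mean
`doc_length_tokens` (default 80, floor 20).  Per-month topic mixtures follow
a row-stochastic trend table (uniform by default), so timeline and evolution
analyses have planted ground truth.  Noise records are injected per-record
at Bernoulli rates and counted exactly: exact duplicate rows under the same
id, non-English records (non-"en" language field *and* a separate
vocabulary, so both metadata- and content-based filters are testable),
pre-2020 records, and abstract-only records.

Defaults are the benchmark regime: 7 topics, 100 documents/month over
January–September 2020, topic vocabulary 250/topic, background 600.  What
the generator does **not** emulate: real English prose and grammar, real
vocabulary burstiness and Zipfian overlap between topics, citation
structure, OCR noise, or ambiguous section segmentation.  Passing tests
therefore demonstrate that the pipeline's machinery is correct and that it
recovers structure of the planted kind; they do not certify extraction or
clustering accuracy on real text.

## Problem sizes and numerical choices

Test and acceptance runs use reduced scales chosen to exercise the same
code paths at desk scale: the topic-recovery benchmark uses 900 documents,
2,000 TF-IDF features, hidden widths 256/128/64/32 with bottleneck 16, and
30 epochs; elbow-recovery runs use 300 documents, 500 features, widths
128/96/64/32 with bottleneck 16, 15 epochs, and k ∈ [2, 12].  Tolerances:
oracle equivalences at 1e-12; probability conservation at 1e-9; binomial
checks at 3 standard deviations.  Ties everywhere break toward the lowest
index or lexicographically smallest term so that reruns are identical.

## Known limitations

* The extraction rules assume the structured body of full-text JSON; PDFs
  and unstructured text are out of scope, as is language identification from
  text (the metadata language field is authoritative).
* Lloyd iteration finds local optima; restarts mitigate but do not remove
  this, and elbow selection inherits that noise.
* The evolution rules are explicit substitutes for a taxonomy that is
  usually presented only pictorially; `branch_min`/`inherit_min` are
  interpretable but heuristic.
* Word-cloud rendering is replaced by an exact term-frequency table;
  GPU training is out of scope — the numpy implementation targets
  desk-scale corpora.
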