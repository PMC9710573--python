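# Methods

This note documents the models and procedures implemented in `litmarker`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Dictionary matching

Entity recognition is exact dictionary matching over curated term lists,
not statistical NER. Synonyms are normalized (unicode NFC, internal
whitespace collapsed, flanking punctuation stripped — an idempotent
transform) and inserted into a trie keyed on token sequences, so "most
extended term" means *longest token span*. Matching is greedy
left-to-right maximal munch: at each token position the deepest trie hit
is emitted and scanning resumes after it, bounding work per sentence by
(token count × longest synonym length) — linear for a fixed lexicon.
Emitted spans never overlap; when two terms tie on the same longest span
(a synonym shared across entity types), all payloads are emitted and the
downstream filters or type-pair selection decide.

Case policy was an open choice: the source lists for genes are dominated
by short all-uppercase symbols whose lowercase forms are common words or
other abbreviations (the classic EMT-the-gene vs. EMT-the-process trap).
The default is therefore case-insensitive matching *except* for
all-uppercase synonyms of ≤ 6 characters, which must match the surface
exactly. Both the global folding and the uppercase exception length are
configurable (`MatchPolicy`).

Sentence splitting and tokenization are deliberately simple and fully
specified: split after `.!?` followed by whitespace and an
uppercase/digit/opening character (so "s. pneumonia" never splits), and
tokenize as alphanumeric runs plus single punctuation marks. The contract
— offsets reconstruct the text, every alphanumeric run is exactly one
token — is what the rest of the pipeline relies on, and is property-tested.

### Mention filters

Two rules, both scoped as published behavior of the pipeline:

* dot-prefix: a surface matching `^[A-Za-z]\.\s` is dropped (species-style
  abbreviations are too ambiguous to trust from a dictionary hit);
* short-term: surfaces under 4 characters are dropped unless the document
  previously contained the definition pattern `long form (ABBR)`.
  Definitions are harvested per document in reading order; the defining
  occurrence itself conforms to the pattern and is kept
  (definition position ≤ mention position). Length is measured in
  characters of the matched surface, since the rule targets
  abbreviation-style tokens.

## Unsupervised training-data generation

The labeler assumes association strength correlates with sentence-level
co-occurrence frequency, but uses that correlation only to *label
training data* — the trained classifier then judges any sentence
regardless of its pair's frequency, which is what lets rare pairs be
found at prediction time.

Parameters (defaults chosen to the pipeline's published operating point):

| parameter | default | meaning |
|---|---|---|
| t₁ | 10 | minimum sentence co-occurrences for a pair to donate positives |
| t₂ | 50 | per-pair cap on donated sentences (guards against frequency bias) |
| ratio | 6:4 | positive:negative balance of the assembled dataset |
| split | 8:2 | stratified train:validation division |

The negative rule admits frequency-one pairs but excludes sentences whose
entity census is exactly one disease and one biomarker (two mentions
total): such minimal sentences usually assert a real association. The
published phrasing of this exclusion is ambiguous between "exactly these
two mentions" and "one mention of each pair type, ignoring others"; we
implement the first reading, which matches the stated rationale, and
isolate it in a single predicate (`weak_labeling._is_excluded_negative`)
so the alternative is a one-line change.

Sampling beyond t₂ and ratio downsampling draw from one seeded random
stream; instances are canonically sorted before any shuffle, so a fixed
seed reproduces the dataset byte-for-byte. A sentence may legitimately
appear as positive via one pair and negative via another: the unit of
labeling is the pair-in-sentence.

## Relation model

Preprocessing replaces each entity span with one type-specific marker
token (`DISEASE1`, `MICROBIOME2`; slot by span order) and shapes the
sequence to exactly 100 tokens, tail-padded with `[PAD]`. Truncation
prefers the sentence prefix but shifts the window right when the second
marker would fall off; spans farther apart than the window are an error
rather than a silent marker loss.

The default backend is a linear classifier over sparse unigram counts of
the masked sequence, trained with minibatch SGD on the logistic loss.
Validation macro-F1 is recorded every epoch and the best epoch's weights
are kept. This choice is deliberate: the pipeline is model-agnostic at
the `fit`/`predict_proba` interface, the cue-style signals the weak
labeler produces are linearly separable, and a CPU-second model makes the
whole system testable end to end. `ModelConfig` also carries the
transformer-backend contract (768-dim encoder features, AdamW, lr 1e-5 or
3e-5, batch 16 or 32, 50 or 10 epochs for the binary and five-way tasks
respectively); the sparse baseline consumes only epochs, batch size,
label set and seed, using scikit-learn's optimal SGD schedule instead of
the stated transformer optimizer.

`litmarker.tree_composition` realizes the heavyweight architecture's *forward
contract* in numpy: a hash-seeded random-feature encoder emits 768-dim
per-token vectors with a light bidirectional neighbor mix (contextual in
the sense that the same token embeds differently in different
neighborhoods); a latent binary tree composes the sequence — adjacent
pairs are tentatively merged by a GRU-style combiner, merge candidates
scored, the winner selected by straight-through Gumbel argmax (plain
argmax at inference) — and the concatenation [sentence vector, entity-1
feature, entity-2 feature] feeds a fully connected softmax layer. The
composer internals are a simplified GRU-style gate (no trained
parameters are shipped); the composer is swappable and zeroed classifier
weights provably give the uniform distribution. Entity features are taken
at the *marker positions* (the alternative — span-pooling the original
entity tokens — is not implemented).

## Granular relations

Screening is label-agnostic: a sentence passes if it contains any cue
token (token-level, case-insensitive — "risk" never fires inside
"risky"), and the five-way classifier decides the label. Cue lists may be
expanded with nearest neighbors from any `Mapping[str, ndarray]` word-vector
provider (cosine threshold 0.8, top-5 by default). Distant supervision
joins screened pairs against knowledge-base triples; a pair under several
KB labels yields one flagged instance per label rather than a silent
choice. Because the published label set has exactly five members but real
predictions should be allowed to abstain, `classify_granular` returns
"NA" when the best probability falls below a threshold (default 0.5,
disable with `na_threshold=None`).

## Synthetic corpora

The generator emulates the statistical shape the pipeline was built for —
a skewed co-occurrence profile with one dominant pair (the 400-count
regime), a frequency-one tail, three-entity negative sentences,
two-entity excluded sentences, filler sentences, and both table patterns
— with exact realized counts and full ground truth. Entities are
two-token invented names so multi-token longest match is always
exercised; cue phrases are single tokens so planted labels are
unambiguous. What it does *not* emulate: natural language variability,
entity ambiguity across types, negation and hedging, co-reference, or
noisy labels (real automatic labeling carries roughly 15–20% positive
noise; the planted cues are noise-free). Passing tests therefore
demonstrate the machinery — thresholds, invariants, learnability — not
real-corpus accuracy.

Default problem sizes in the tests and the acceptance script (20–40
documents, co-occurrence counts 1–400, 500–6,000 training instances,
1,000 randomized matcher cases) were chosen as the smallest sizes at
which every behavior under test is exercised with margin; all complete in
seconds to a few minutes on one CPU.

## Pipeline and reporting

Query resolution uses normalized edit-distance similarity
(`difflib.SequenceMatcher`) with cutoff 0.85; exact synonym matches rank
first, and a below-cutoff query returns the top-3 closest terms as
suggestions. The report is a pure function of (corpus, term lists, model,
config) and is cached under a SHA-256 content key; cache on/off yields
identical output, which is tested. Ranking counts distinct evidence items
(sentences and table units weighted equally — the relative weighting is
genuinely open and left configurable by filtering evidence kinds),
descending, ties broken alphabetically.

## Known limitations

* Dictionary NER cannot find entities absent from the term lists, and
  inherits list ambiguities; the case policy only mitigates the
  short-symbol problem.
* The shipped tree-composition backend is a forward contract with random
  initialization, not a trained model; training it requires a pretrained
  encoder and is out of scope.
* Cross-sentence relations, negation ("no association was found") and
  experimental context are not modeled; a sentence asserting absence of
  association still counts as a candidate.
* The negative rule depends on mention censuses after filtering, so
  aggressive filtering can change which sentences are eligible negatives.

## Control metrics

The permutation control retrains the classifier on randomly shuffled
labels and reports F1 against the shuffled validation labels, which is
chance-level for any classifier. (Held-out F1 against *true* labels is
not a valid control here: a ~50% shuffle leaves a few percent residual
label-feature correlation, enough for a separable cue to be partially
recovered.)
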