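# Methods

## The paper-scoring model

The triage classifier is deliberately minimal: a bag-of-words enrichment
lexicon and a correlation score, with no smoothing, stemming, n-grams or
TF-IDF weighting.

**Text and tokens.**  The scoring text of a paper is its title concatenated
with its abstract.  Tokens are maximal runs of ASCII letters and digits,
case-folded; hyphens and all other punctuation split tokens.  This is the
simplest reproducible rule, and because the classifier only compares
relative word frequencies, the precise tokenisation convention matters far
less than its determinism.  A stop-word list (packaged default: ~130 common
English function words, overridable per call or via `--stoplist`) removes
words with no discriminatory value between the classes.

**Document size.**  The denominator of enrichment — the "size" of an
article — is the token count *after* stop-word removal.  Taking the
pre-removal count instead would rescale each document's enrichment vector
by a constant, and the Pearson score is invariant under positive scaling of
either argument, so this choice affects the stored lexicon values but not
training–scoring consistency or any ranking.  The same scale-invariance
argument shows that scoring a paper with raw counts and with enrichments
yields the identical correlation; the suite asserts this to 1e-12, which is
why the counts-vs-enrichments question needs no further resolution (it
*would* matter if Pearson were replaced by a similarity that is not
scale-invariant).

**Lexicon.**  The term vector *W* is every distinct non-stop word occurring
in P ∪ N, in sorted lexicographic order — any fixed order works, since the
paper vector *v* is aligned to *W*; a fixed order makes retraining
bit-reproducible.  Scores are plain mean-enrichment differences; each lies
in [−1, 1] by construction, with ±1 attained only by a word filling every
document of one class and absent from the other.

**Degenerate cases.**  Ranking must be total, so scoring never raises on
unusual input: an empty document, a document sharing no word with *W*, or a
zero-variance vector each yield score 0 with an explicit `degenerate` flag,
placing such papers mid-ranking.  Training, by contrast, rejects empty
classes, PMID overlap between P and N, and zero-length documents outright —
a silently weakened lexicon would be worse than an error.

**Ranking.**  Descending by score; ties break by ascending PMID (numeric
when the PMID is numeric) so output is reproducible; at most 1,000 rows are
returned by default, mirroring the display cap of the original paper
browser.

## Evaluation machinery

The ROC sweep processes tied scores as a block, producing a diagonal
segment, and integrates by the trapezoid rule.  This makes the AUC exactly
the Mann–Whitney statistic (probability a random positive outscores a
random negative, ties counted 1/2); the suite checks that identity on 1,000
random instances and cross-checks against scikit-learn's reference
implementation.

`performance` is the Pearson correlation between the real-valued paper
scores and the 0/1 labels of a test set — the single summary the iteration
study records.  `mie` is 100 × (positives / total) over a fully labeled
set and refuses unknown labels rather than guessing.

The iteration study draws each training subset without replacement, seeded
per (replicate, cell) through a seed-sequence hierarchy, so every cell is
independently reproducible and the whole table is deterministic given the
seed.  The original study reports one value per cell; a `replicates`
parameter (default 1 for fidelity) averages several draws per cell, which
is recommended because single draws at small negative-set sizes are noisy.
Rows are emitted positive-size-major with the negative size varying
fastest, matching the printed table layout.

## The synthetic corpus generator

Real training corpora for this problem are hand-labeled and unpublished, so
the test bed is generative.  Documents are multinomial bags over a shared
vocabulary; positive documents multiply the probability mass of a set of
positive-marker words by `effect` (renormalised), negative documents do the
same for a disjoint negative-marker set, and unknown documents draw from a
50/50 mixture.  Document lengths are Poisson around `doc_length_mean` with
a floor of 5 tokens.  Bags are rendered to text (title = first three
sampled tokens) and written as MEDLINE records, so the reader, tokenizer
and stop-word filter are exercised end-to-end, not bypassed.

Defaults, chosen once as abstract-scale values: `vocab_size=500` informative
words, `doc_length_mean=120` tokens (a typical abstract after stop-word
removal), 20 marker words per class, `effect=2.0`, 200/200/100
positive/negative/unknown documents.  With equal marker-set sizes the two
class normalisers are equal, so the expected positive/negative enrichment
ratio of a marker word is exactly `effect`; the suite verifies empirical
convergence to within 10% at 2,000 documents.  This model is the minimal
one under which the enrichment-difference lexicon is a consistent marker
detector, which is precisely what makes it a useful ground truth: with
`effect=5` and 200 training documents per class the trained lexicon signs
every marker word correctly in ≥95% of replicates and ranks held-out
papers at AUC ≈ 1; with `effect=1` the classes are exchangeable and AUC
averages 0.5.

What the generator does **not** emulate: English syntax and word burstiness,
Zipfian vocabulary, topic drift, MeSH structure, correlated markers, or
label noise.  Passing tests therefore demonstrate correctness of the
algorithms and qualitative recovery of controlled signal — not the absolute
performance numbers one would obtain on a real hand-labeled corpus, which
depend on corpus composition and are out of reach without the original
(unpublished) training sets.  For the same reason the acceptance checks
assert trends and bounds (AUC near 1 under strong signal, near 0.5 under
null, performance rank-correlated with training-set size) rather than any
specific published value.

## Annotation data model

Records are immutable dataclasses under the structured minimotif syntax.
Positions are 1-based indices of the first motif residue; consensus-only
entries may omit the position.  Controlled-vocabulary terms are stored as
opaque accession+label pairs validated for prefix format only (`GO:`,
`MOD:`) — resolving against live ontologies is out of scope.  The clone
operation copies everything except the motif sequence and position, the two
fields that vary across the motif families produced by high-throughput
experiments.

Persistence is flat-file: records as RFC-4180 CSV (list-valued fields
';'-joined within one cell, with ';' forbidden inside items so the round
trip is lossless) plus a JSON-lines store; review histories as JSON-lines
with ISO-8601 timestamps.  Review histories are append-only — operations
return extended copies and reject out-of-order timestamps per paper — and
the status vocabulary is closed at exactly seven names; the suite fails if
an eighth appears.  A relational backend could replace these files behind
the same operations.

## Sequence validation

Consensus notation: upper-case amino-acid letters are literals, `[..]` is a
residue class, lower-case `x` is the wildcard.  Negated classes and
variable-length gaps are not part of the notation and are rejected.  In
sequences, upper-case `X` denotes an unknown residue and matches only the
wildcard.  Occurrence search compiles the pattern to a lookahead regular
expression so overlapping matches are all reported; the suite checks
equivalence with a naive per-position scanner on 1,000 random pairs, and
validation of a claimed position is definitionally membership in the
occurrence list (a consensus with several occurrences validates at any of
them).  Public coordinates are 1-based with inclusive ends, the biological
convention; 0-based half-open spans are internal, with the conversion
tested as a bijection.

## Markup

Highlighting matches catalog terms case-insensitively as whole words
(boundaries = no adjacent letter/digit), which keeps "motifs" inside longer
words unhighlighted.  Overlaps are resolved by a fixed category priority
(minimotif > putative minimotif > activity > target > affinity > protein
domain > bolding of the word "motif"), preferring the longer match within a
category; the priority order is a design choice of this package — the
original viewer never documents overlap behaviour — and is centralised in
one tuple.  Rendering escapes all text, so stripping the emitted tags
recovers the escaped abstract byte-for-byte (a property test).

## Problem sizes and determinism

The acceptance checks use 100 random small corpora for the bound suite,
100 instances for oracle equivalence, 1,000 instances for the AUC identity,
20 replicates of 500-document corpora for parameter recovery, a 16-cell
size grid with 5 replicates for the trend study, and one 10,000-abstract
corpus for the end-to-end run — sizes at which every qualitative effect is
stable across seeds while the whole suite stays fast.  All randomness flows
through explicit integer seeds (numpy `default_rng` / seed sequences);
identical seeds yield byte-identical corpora, lexicons and rankings.

## Known limitations

* The classifier inherits the biases of its training set (type biasing);
  like the original, the package mitigates this only by exposing all word
  scores for inspection rather than reweighting automatically.
* Single-occurrence words receive scores like any other; no frequency
  cutoff beyond stop-word removal is applied.
* The MEDLINE writer normalises internal whitespace in long fields when
  wrapping continuation lines; round-trips are exact for single-spaced
  text, which is what the generator emits.
* Live PubMed retrieval, full-text parsing, MeSH handling and multi-user
  persistence are out of scope.
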