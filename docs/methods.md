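# Methods

This note documents the models and procedures implemented in `textmarkers`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not establish.

## Input model

The canonical input is CoNLL-U. The pipeline deliberately does not invoke
a parser: dependency analyses are consumed, not produced, which keeps every
stage deterministic and testable. Heads are stored 0-based
sentence-internal with an explicit ROOT sentinel (CoNLL-U's 1-based HEAD,
0 = root, is converted at the boundary). Multiword-token ranges are skipped
in favour of their syntactic words; empty nodes are ignored; an
out-of-range head is reassigned to ROOT with a warning rather than
rejecting the document. All surfaces and lemmas are lowercased at
ingestion so dictionary and norm lookups are case-insensitive.

## Lexicon scoring

Documents are reconstructed as their ordered lemmas; tokens tagged
PUNCT/SYM/NUM are removed, keyed on the UPOS tag rather than character
classes since the input is already parsed. The surfaces `?` and `!` are
retained as literal tokens (punctuation lemmas are unreliable, so retention
keys on the surface) because they can themselves be dictionary entries.
Compound rules (an explicit input file, `lemma lemma<TAB>joined_entry`) are
applied greedily left-to-right after removal, longest rule first at each
position; joining is idempotent. The match ratio's denominator is the
post-joining processed token count, including retained marks — they
participate in matching, so they belong in the denominator; a switch
(`marks_in_denominator=False`) exposes the alternative. An empty processed
document yields a missing ratio, never a division error.

## Sophistication and megalalia

Lexical sophistication maps a norm table (lemma → rating on a declared
scale, age-of-acquisition-like) onto the document's non-PUNCT/SYM/NUM
lemmas and takes the token-pooled arithmetic mean; unmapped lemmas are
skipped and coverage (mapped / eligible tokens) is always reported so
low-coverage documents can be screened (threshold configurable, default
none). Megalalia is the Gini coefficient of the same mapped values, in its
mean-absolute-difference form G = ΣᵢΣⱼ|xᵢ−xⱼ|/(2n²x̄), computed with the
equivalent O(n log n) sorted formula and verified against the O(n²)
definition in tests. This form is scale-invariant and bounded by 1 − 1/n;
it requires at least two mapped values, none negative, not all zero — the
norm loader enforces a non-negative declared scale. Fewer than two mapped
values yield a missing megalalia score.

## Syntactic composite

Three per-document metrics: mean tokens per sentence; mean VERB+AUX tokens
per sentence (clause proxies — "verbs including auxiliaries" maps to the
two UD tags); and the per-sentence maximum of |i − head(i)| averaged over
sentences, with ROOT tokens contributing distance 0 (a switch excludes them
instead). The composite is the first principal component of the three
z-scored metrics (correlation-matrix PCA — the metrics have different
units). Eigenvectors are sign-ambiguous, so PC1 is oriented so the loading
on sentence length is positive: higher pc1 always means more complex
syntax. The fitted model (means, SDs, loadings, explained variance) is
serialized to a plain-text key-value file so a composite fitted on one
corpus can score another.

## Cohesion

Sentence embeddings are the mean of the word vectors of tokens that are
not stopwords (surface lookup against a replaceable list), not PUNCT/SYM,
and in vocabulary; out-of-vocabulary tokens are skipped — no subword
fallback, keeping the core dependency-free behind a simple table contract.
Lookup keys on the lowercased surface (a lemma switch exists). Cohesion is
the mean cosine over adjacent sentence pairs where both sides have a
vector; pairs with a missing side are dropped rather than the whole
document, and documents with fewer than two embedded sentences score
missing. The scramble test draws a uniform non-identity permutation of
sentences per document (word order within sentences untouched), filters to
documents with at least 20 sentences by default, and compares arms with an
unpaired Welch t-test plus pooled-SD Cohen's d (a paired variant is
available by flag).

## Trait scales and statistics

Likert responses rescale affinely to [0, 1]; reverse-keyed items map to
1 − z; the composite is the available-item mean by default (strict mode
rejects missingness), making instruments with different ranges directly
poolable. Subscale scoring is exposed as named item subsets supplied by
the user.

Pearson correlations report Fisher-z 95% CIs and t-distribution p-values
(n − 2 df) under pairwise-complete deletion, so each matrix cell carries
its own n. Welch's t uses Satterthwaite df; Cohen's d uses the pooled SD
even alongside Welch's t, the conventional pairing in psychology
reporting. Significance stars at .05/.01/.001; no multiple-testing
correction by default (exploratory convention), with a Holm option.
Moderated regressions z-standardize outcome, predictor and moderator,
form the product after standardization, and fit OLS listwise, reporting
standardized betas with SE/t/p/CI.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
not natural language; lemmas are arbitrary strings. Defaults represent the
emulated study conditions: 385 participants, one document each (285 on an
11-item 1–7 instrument, 100 on a 15-item 1–5 instrument, items loading
0.8 on the latent trait), a planted trait–lexicon correlation of .19, and
documents of 5–15 sentences of 6–14 tokens.

The trait→lexicon link is logistic: p(trait) = expit(logit(base) +
b·trait), base rate 0.10. The slope b is found by a deterministic 1-D root
search (Brent) on an analytic prediction of the realized correlation
computed from the already-drawn traits, measured composites and document
skeleton token counts — the prediction accounts for binomial thinning
noise and for measurement attenuation in the composite, so the realized
corpus correlation is an unbiased draw around the target. Document
structure (sentence lengths, slot categories, dependency heads) is decided
before lexical content precisely so these counts exist at calibration
time.

Sophisticated-word insertion probability rises linearly with the 0–1
trait (base .05, slope .10), driving megalalia. Sentences share a topic in
blocks of 2–5; topic words are drawn near a topic centroid in embedding
space (dimension 50 — cohesion depends on cosine geometry, not on
dimension, and 50 keeps generated corpora small; noise SD 0.3 per
coordinate), so adjacent same-block sentences are similar and scrambling
reliably lowers cohesion. Heads attach to an adjacent neighbour or to the
sentence root (the first verb) with a configurable long-head probability;
the complexity-contrast generator sets long sentences / many verbs / long
heads against the opposite for a labeled high-vs-low corpus. All draws
flow from one seeded numpy generator; written output is byte-identical
across runs of the same configuration.

Because the planted topic structure is clean and strong, validation effect
sizes on synthetic corpora (scramble d ≈ 7 at the default noise level,
contrast d > 20) are far larger than anything expected of real essays;
the tests therefore assert only directional thresholds (d > 0.5, d > 1),
and passing them shows the metrics respond to the planted structure — not
that real text carries effects of that size. Real data differ in ways the
generator does not emulate: natural lexical frequency distributions,
morphology (no subword handling), parser errors, topic drift within
sentences, and non-logistic trait–usage links.

## Problem sizes and numerical choices

Validation runs use the sizes stated with each check: 100 documents of
20–40 sentences for the scramble test, 50 documents per arm for the
complexity contrast, n = 500/1000 corpora for parameter recovery, 200
replicates at n = 1000 for moderation power, 2000 null datasets for CI
coverage. Gini agreement with the pairwise oracle is asserted at 1e-12,
statistics against textbook-formula oracles at 1e-10. Degenerate inputs
are contracts, not crashes: empty processed documents, unmapped
vocabularies, constant matrix variables and sub-minimum group sizes all
produce missing values or errors naming the condition. Identical constant
groups in the Welch test return t = 0, d = 0 rather than 0/0.

## Known limitations

* No live parser adapter: text must arrive parsed (CoNLL-U).
* No subword embeddings; out-of-vocabulary content words are simply
  skipped, which can bias cohesion for morphology-rich text.
* The dictionary, norm table and embeddings are consumed as inputs; their
  construction and validation are out of scope.
* Moderation models assume linear, homoscedastic effects of standardized
  predictors; no robust-SE option is exposed.
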