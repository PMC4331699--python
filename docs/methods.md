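# Methods

## Problem and overall design

`chemner` recognizes chemical (and, generically, biomedical) entity
mentions in title+abstract documents. The approach is semi-supervised in
the feature space: a supervised second-order linear-chain CRF over BIO
labels consumes two families of features — a *baseline* set of
morpho-orthographic templates computable from the labeled text alone, and
*word-representation* features (Brown-cluster bit-string prefixes and
word-vector-class ids) induced once from a large unlabeled corpus. No
lexicon or dictionary is used anywhere; any domain knowledge enters
exclusively through the unlabeled text.

Two exact-match evaluation views are supported: mention-level
(doc, section, start, end) offsets, and document-level indexing by unique
(doc, string) pairs, with precision `p = TP/(TP+FP)`, recall
`r = TP/(TP+FN)` and `F1 = 2pr/(p+r)` (empty denominators score 0).

## Preprocessing

Two tokenizers are provided. The *whitespace* tokenizer splits on blanks;
the *simple* tokenizer emits maximal `[A-Za-z0-9]+` runs or single
punctuation characters. Both record exact character offsets. The
supervised path uses the simple tokenizer on raw text so gold offsets are
never disturbed; representation induction uses the whitespace tokenizer on
*cleansed* text (control characters removed; a small fixed table maps
Greek letters to their English names and typographic dashes/quotes and
the multiplication sign to ASCII). Cleansing changes string lengths and is
therefore never applied to text carrying offset annotations; no offset
mapping is attempted.

Sentence splitting is rule-based: a split occurs after `[.?!]` followed by
whitespace and an uppercase/digit sentence start, except after a fixed
abbreviation list (`e.g.`, `Fig.`, `et al.`, single initials, ...) and
never inside open parentheses. The default lemmatizer is deliberately
trivial — lowercase, then strip a plural `es` after a consonant, else a
plural `s` after a non-`s` consonant — and any stronger lemmatizer or POS
tagger can be plugged in through the batch provider interface
(word list in, lemma/POS list out, order preserving). A provider failure
falls back to the lowercased token with a logged warning. POS features
exist behind a flag and default to off.

## Baseline features

Per token: word identity, lemma, orthographic shape patterns applied with
**full-match** semantics (Roman numerals `[ivxdlcm]+|[IVXDLCM]+`,
punctuation `[,\.;:?!]`, dash-start, nucleotide alphabet `[atgcu]+`,
numbers `[0-9]+`, capitalized `[A-Z][a-z]*`, quotes), 2/3/4-character
prefixes and suffixes (omitted when longer than the token), and 2/3
character n-grams over the token flanked by `^`/`$` sentinels. 2/3-word
n-grams covering the current position are anchored at the position with
their alignment. All token-level templates are replicated over a ±2
sliding window with `@offset` tags; out-of-sentence positions contribute a
single `PAD@offset` sentinel. The Roman-numeral pattern intentionally
fires on ordinary words like "mild" whose letters all lie in the
character class: the printed pattern is reproduced without a stop list.
Feature keys are plain strings (no hashing) so feature dumps diff cleanly.

Lemma features are windowed exactly like word features, and word n-grams
use raw (not lowercased) text.

## Brown clustering

Words are clustered to maximize the average mutual information of
adjacent-cluster bigrams,

    I(C) = sum over c, c' of  P(c,c') * log2( P(c,c') / (P(c) P(c')) ),

with maximum-likelihood bigram probabilities, zero-count terms
contributing zero, and logs in base 2 (the base only scales the
objective). Bigrams are counted within lines; words under `min_count`
(default 2) fold into a reserved rare symbol.

Induction uses the active-set strategy: the `K` most frequent words seed
singleton clusters; each further word (by descending frequency, ties
lexicographic) enters as a temporary (K+1)-th cluster and the merge
losing the least quality is applied, so the cost is `O(V · K²)` quality
deltas rather than the cubic all-pairs agglomeration. After the last
insertion the K-cluster partition defines `model.quality`; K−1 further
merges close the tree. Bit strings read root-to-leaf, 0 denoting the
higher-frequency branch (ties: lexicographically smaller minimum word),
which makes path tables byte-stable across runs. Feature lookup takes
bit-string prefixes of lengths 4/6/10/20; unknown words fall back to
their lowercased form, then to the rare symbol, then to `UNK`. Cluster
files use the conventional `bitpath<TAB>word<TAB>frequency` text layout.

## Word vectors and word-vector classes

Word vectors are trained by plain SGD on the negative-sampling objective
(k = 5 noise draws from the unigram^0.75 distribution) in either CBOW
(averaged context predicts the center) or skip-gram (center predicts each
context word) form — a log-linear model with no hidden layer. The context
window is 5 by default and per-position widths are sampled uniformly in
[1, window], the standard trick that downweights distant context. The
learning rate decays linearly from 0.025. Training is single-threaded and
deterministic under the config seed; input-side vectors are returned. The
reference dimension is 250; desk-scale runs and tests use 25, which is
sufficient for the latent-class structure of the synthetic corpora.

The WVC model discretizes the vector space: vectors are L2-normalized
(cosine geometry) and clustered by Lloyd's K-means with k-means++ seeding,
run to an assignment fixpoint or 100 iterations; an emptied cluster is
re-seeded with the point farthest from its centroid. The within-cluster
sum of squares is recorded per iteration and is non-increasing. Class ids
are relabeled densely in order of first appearance so assignment files
are byte-stable. Reference class counts are 300/500/1000; desk scale uses
~12. Both CBOW and skip-gram are available; skip-gram is the desk-scale
default because it learns more from small corpora.

## Second-order CRF

The label at position *t* is conditioned on the two previous labels. The
model is realized on a pair-state lattice (states are (y_{t-1}, y_t));
observation features tie to the current label, transition parameters are
(y_{t-2}, y_{t-1}, y_t) triples, and two BOS sentinels pad the left
context. All charts are in log space. Training maximizes the conditional
log-likelihood with a Gaussian prior (σ = 1 by default; no authoritative
setting exists, so the default is declared rather than inferred) by
L-BFGS on the exact gradient — empirical minus expected counts from
forward-backward. The analytic gradient is verified against central
finite differences in the tests. Stopping: relative objective change
below `tolerance` or `max_iter` iterations.

Decoding is Viterbi with ties broken toward the earlier label in the
alphabet. BIO-illegal transitions (I-X not after B-X/I-X) are removed
structurally with −inf potentials at decode time (on by default);
marginals default to the unconstrained distribution, which is what the
enumeration oracle checks and what calibrated confidences require. A
mention's confidence is the minimum posterior of the decoded label over
its tokens.

## Postprocessing

BIO runs merge into mentions; an orphan I-X is promoted to B-X (keeps
recall; configurable by relabeling upstream if dropping is preferred).
Two corpus-independent rules follow: (1) mentions whose text has
stack-mismatched `()`/`[]`/`{}` or an odd number of `"` characters are
dropped (double quotes are undirected, hence parity); (2) abbreviation
definitions `long form (SF)` are detected by the
letters-in-order/short-form-in-parentheses heuristic (SF ≤ 10 characters
with at least one letter; its first character must match at a word
boundary in the long form; the leftward search is bounded by
min(|SF|+5, 2|SF|) words). If the long form overlaps a tagged mention and
the short form is untagged, the short form is added with the same type
and confidence, and symmetrically. The operation only ever adds mentions
and is idempotent. No specific published abbreviation algorithm is
claimed; the rule above is fixed and tested.

## Synthetic data

The labeled-corpus generator emulates title+abstract records: carrier
sentence templates contain chemical-context slots ("treated with …",
"addition of …") and plain noun slots. Chemical slots are filled with
grammar-generated names — optional stereo modifier `(R)-`/`(S)-`, digit
locants, a stem from a closed list, an optional infix, and a nomenclature
suffix from {-ol, -ane, -ene, -ate, -ide, -ine}, sometimes as two-token
salt/acid forms — or, when not an entity, with distractors. Distractors
come in two fixed vocabularies: *pseudo-chemicals* built from disjoint
stems but the same suffixes (never entities), drawn with a long-tailed
Zipf-like law, and plain nouns. Pseudo-chemicals appear in both slot
kinds but predominantly in noun slots, so entity-hood correlates with a
word's corpus-wide context distribution, not its surface shape — the
structure Brown clustering and WVC induction can recover and surface
features alone cannot. The per-slot entity probability is solved from the
requested entity-token density (default 0.15, a typical mention density
for chemistry abstracts) given the shipped template set. Gold offsets are
recorded exactly during rendering; both generators are deterministic
under their seed.

The class-LM generator samples tokens from a latent-class bigram chain
with a near-permutation class-transition matrix (`switch_noise`
off-diagonal mass; 0 gives deterministic class cycling) and uniform
within-class emission, returning the word→class map for recovery tests.

What the generators do **not** emulate: real nomenclature (IUPAC),
MEDLINE register and vocabulary growth, annotation noise, nested or
discontinuous mentions, and document-length/burstiness effects. Passing
tests therefore demonstrate correctness of the machinery and the
*direction* of the representation-feature effect under recoverable
structure — not the absolute accuracy to expect on real corpora.

## Study sizes and numerical choices

The shipped end-to-end comparison trains on 300 documents, evaluates on
100 held-out documents, and induces representations from 2,000 unlabeled
documents with Brown K = 24, one WVC model with C = 12, and 25-dimensional
skip-gram vectors (3 epochs) — sizes chosen so the full comparison runs
on a single CPU in minutes while leaving the baseline measurably short of
ceiling. CRF training uses σ = 1.0, tolerance 1e-4, max 100 L-BFGS
iterations. Charts use log-space arithmetic throughout; `logsumexp`
guards underflow; posteriors are exponentiated only after normalization.
Ties in ranking prediction rows are broken by ascending (start, text) for
deterministic files.

## Known limitations

* The CRF trains in memory on dense per-sentence charts; it is a
  desk-scale reference, not a 1M-document system.
* Brown induction materializes a dense cluster-count matrix per merge
  evaluation; vocabularies beyond ~10^4 words call for the usual
  windowed implementations.
* The abbreviation heuristic handles the common `long form (SF)` pattern
  only; coordination/ellipsis ("2- and 3-hydroxy…") and nested mentions
  are out of scope.
* Offsets assume plain text; XML unescaping and full-text section
  structure are out of scope.
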