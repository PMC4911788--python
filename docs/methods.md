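# Methods

This note documents the models, the tunable parameters, the synthetic data
the package is validated on, and the numerical and design choices made where
the design was genuinely open.

## Data model and formats

A corpus is a list of two-section documents (title, abstract). Mention
offsets are 0-based half-open character offsets over `title + " " +
abstract`; the separator occupies one offset position, matching the PubTator
convention, so real BC5CDR-style files need no re-indexing. Composite or
alternative concept IDs (e.g. pipe-joined IDs) are treated as opaque atomic
strings. Duplicate mention lines are kept as distinct objects; deduplication
happens only in evaluation's set semantics. Overlapping gold mentions are
permitted by the data model; label projection resolves them (longer mention
wins, with a warning) only at training time. Encoding is UTF-8 throughout.

## Preprocessing

The tokenizer is rule-based: whitespace split, then word tokens are maximal
alphanumeric runs glued by internal hyphens, apostrophes or periods; every
other character is its own token. This keeps multi-part chemical names
(`5-fluorouracil`) whole while exposing parenthesized abbreviations
(`(CAD)` → `(`, `CAD`, `)`). Slashes and commas always split. The sentence
splitter looks for `.!?` followed by whitespace and an upper-case letter or
digit, suppressed inside brackets and after a stop-list of abbreviations
("e.g.", "i.v.", "Fig." …); the title is always segmented separately so no
sentence crosses the section boundary. The POS tagger is a deterministic
closed-class lexicon plus suffix rules with `NN` as fallback; it is
deliberately self-contained so tests never depend on a model download, and
the backend is pluggable through `preprocess_document(backend=...)`.
Mentions that cross token boundaries (possible on real data, never on
synthetic data) are snapped outward to full tokens for label projection,
with a warning.

## Mention recognition

Both sequence labelers consume the same feature extractor instance, so their
feature spaces are identical by construction. Families: token uni/bi/trigram
windows (±2), POS uni/bi/trigrams, a fixed list of token×POS index
combinations, sentence-length bucket (≤10, 11–25, 26–40, >40 tokens — raw
lengths as categorical keys would explode the space), unmatched-bracket
flag, prefixes/suffixes of length 1–5, character n-grams (n ≤ 4), positional
and run-collapsed word shapes, title/abstract section, gazetteer
longest-match begin/inside flags per entity type, and a corpus frequency
flag (term frequency > 4 and normalized IDF < 0.1; IDF is
`log(N/df)/log(N)` so the 0.1 threshold is meaningful at any corpus size).
The orthographic predicate set is closed: all-caps, initial-cap,
internal-cap, contains-digit, all-digits, hyphen, slash, punctuation-only,
Greek letter. Word-representation features (Brown-style path prefixes of
length 4/6/10 and embedding cluster ids) are supported but off by default:
at package scale they would have to be trained on the corpus being
processed, and they are not needed to reach the recovery targets below.

Labels are BIO over two entity types (five labels). Scoring is the classic
linear chain — per-token emission weights over the feature map plus
label-pair transition weights only (no feature-conjoined transitions), which
keeps exhaustive enumeration over all `5^L` labelings a valid decoding
oracle and is tested against one.

* **CRF** — minimizes the L2-regularized negative log-likelihood with
  L-BFGS; gradients by forward–backward. Defaults: `l2 = 0.1`, at most 100
  iterations. Training is deterministic.
* **Margin-based structured tagger** — cost-augmented averaged structured
  perceptron: training decodes with a unit Hamming cost added to every
  non-gold label and applies averaged updates, a large-margin objective
  distinct from the CRF's. Defaults: 10 epochs, cost 1.0, seeded shuffling.

Both models serialize to JSON (float `repr` round-trips IEEE doubles
exactly), and a reloaded model reproduces predictions bit-for-bit.

The stacked meta-classifier is a linear SVM over merged proposals. For every
candidate it aggregates, over all candidates at the same or adjacent
position (span overlap or at most one token between — our reading of
"adjacent"), eight pairwise span-agreement booleans as any-true flags, plus
the number of proposing taggers and per-tagger indicators. Meta-training
uses 5-fold document-level cross-validated proposals, the standard stacking
protocol; a candidate is positive iff it exactly matches a gold span and
type. If both taggers are perfect the stacking corpus is single-class; the
classifier then degenerates to keep-everything, which is the correct limit.
Overlaps among kept mentions are resolved toward the higher decision score,
ties toward the longer span. By construction the ensemble never invents a
span outside the union of tagger proposals.

## Normalization

Abbreviation completion re-implements the Schwartz–Hearst character
alignment: a parenthesized short form (2–10 characters, at least one letter,
at most two words) is matched right-to-left against the preceding window of
at most `min(|SF|+5, 2·|SF|)` words; every short-form character must appear
in order and the first must start a word. Definitions are resolved
document-wide; when a short form is defined twice, the nearest preceding
definition wins.

Lookup keys are canonicalized: case-folded, punctuation to spaces,
whitespace collapsed; plural stripping is off by default. Dictionary lookup
is exact-match, first-loaded entry wins on duplicate keys. The candidate-list
strategies replace live MeSH WebSearch / Wikipedia APIs with offline TSV
lists keyed by canonicalized mention text; an absent list behaves as an
empty API response (the live APIs were reported to time out in exactly this
way, so the offline contract is faithful as well as hermetic). The re-ranker
is a pairwise-preference linear SVM (the SVM-rank training signal): per
query, the candidate resolving to the gold ID is preferred over every other,
each preference contributing the feature difference in both orientations.
Candidate features: mention bag-of-words, Dice similarity (on canonical
token sets) between candidate and mention and between candidate and context
mentions, source indicators, and rank positions in each list. The default
strategy is direct mapping, which dominates the list-based strategies
whenever the dictionary covers the corpus vocabulary.

## CID relation extraction

Candidates are (chemical ID, disease ID) pairs, both mapped (ID ≠ −1).
The filter: (1) keep mention pairs spanning at most `window` sentences
(window 3 ⇒ index difference ≤ 2, so window 1 means "same sentence";
title and abstract share one sentence numbering, title first); (2) per ID
pair keep the single pair with the fewest tokens strictly between the
mentions (ties: earliest document position); (3) drop candidates whose gap
exceeds a threshold fitted as the floor of the mean gap over positive
step-2 training candidates. Unmapped mentions cannot form candidates but do
count in the mentions-between statistic — they cannot carry a gradable
relation, yet surrounding mention density is informative. Classifier
features are exactly three families: bags-of-words of the two mention
texts, a bucketed mentions-between count (0, 1, 2, 3–5, 6+), and a binary
known-pair flag against a TSV knowledge list (a stand-in for a curated
chemical–disease database). Class imbalance is handled by an exposed
positive-class weight (default in the shipped configs: 2.0). A candidate is
positive at training time iff its ID pair is annotated for its document.

## Synthetic data: what it emulates, and what it does not

The generator builds a world (chemical and disease lexicons with
MeSH-shaped IDs, a knowledge-pair list, unmappable "orphan" names) and
emits 300 documents by default, split 2:1 into train/test before any model
sees data. Names come from prefix/stem/suffix pools (chemical suffixes
-ine/-ol/-ate/-mide/…, disease suffixes -itis/-emia/-pathy/-oma/…), so
affix, shape and character-n-gram features are informative the way they are
on real biomedical text. Default rates: 40 chemicals, 40 diseases, 25
knowledge pairs, abbreviation rate 0.25, relation trigger rate 0.5,
distractor rate 0.5, corruption noise 0.1.

Every document holds 1–3 chemical–disease events. Trigger events place the
pair in one sentence joined by a three-token inductive connector and are
always relational; knowledge events co-mention a known pair in one sentence
with one orphan mention between them and are always relational; distractor
events are trigger-free co-mentions, either in the same sentence with an
orphan between (the same surface shape as a knowledge event) or across
adjacent sentences. Trigger tokens sit strictly between the paired
mentions, never inside mention text: since the relation classifier's
feature set deliberately excludes context words, learnability is carried by
the knowledge flag and the mentions-between statistic, and the trigger only
controls the gold labels. Two layout invariants make the filter's behaviour
analyzable: all same-sentence event pairs have exactly three tokens between
the mentions (so the fitted threshold equals 3 and no positive is lost to
step 3), and every template keeps at least three tokens before its first
mention and two after its last (so cross-sentence pairs always have gaps
above the threshold). Knowledge pairs are rejected when sampling unrelated
concept combinations for a document, keeping the planted-relation rule
exact.

What the generator does **not** emulate: discourse structure, coordination
and nested mentions, real MeSH vocabulary and its synonymy, composite
concept IDs, boundary ambiguity in gold annotation, and long-range
relational language. Perfect or near-perfect scores on synthetic data
therefore demonstrate that each stage implements its contract and that the
planted signal is recovered — not that comparable scores would be reached
on a real challenge corpus, where state-of-the-art systems reach
mention-level F1 in the high eighties to low nineties and relation-level F1
well below that. Running the
pipeline on a real BC5CDR download needs no code changes (same PubTator
format and offset convention), but the official scorer's special cases
(alternative-ID credit, hypernym handling) are not reproduced.

## Numerical and procedural choices

* Viterbi breaks exact ties toward the lower label index; training uses
  continuous weights where ties have measure zero.
* The degenerate single-class stacking corpus yields a constant-decision
  meta-classifier rather than an error.
* `fit_gap_threshold` refuses a training set without positives;
  `generate_candidates` refuses to run with an unfitted (`AUTO`) threshold.
* Evaluation uses the 0/0 → 0 convention for precision, recall and F1, and
  set semantics at every level; report percentages are rounded half-up to
  two decimals.
* The pipeline fans one global seed out to per-stage seeds by fixed
  offsets; two runs with identical config and seed produce byte-identical
  model files and predictions (tested).
* Linear SVMs (meta-classifier, re-ranker, relation classifier) use the
  liblinear-family solver from scikit-learn with a fixed random state;
  learned coefficients are copied into plain arrays so bundles serialize to
  JSON without pickle.
* Problem sizes in the shipped experiments (300-document corpus, 90-document
  stacking subset, 5 cross-validation folds, 200 decoder-oracle sentences)
  were chosen so the full suite and the reproduction script each run in a
  few minutes on one CPU while keeping every estimate's sampling error well
  inside the asserted margins.

## Known limitations

* The lexicon POS tagger is crude; its tags are features, not outputs, and
  the taggers' recovery is insensitive to tag quality on synthetic data —
  on real text a stronger backend may help.
* The re-ranker pools candidates across both lists by canonical name; ties
  among equally ranked first names in the original APIs are unknowable, so
  offline lists are strictly ordered by construction.
* The mention recognizer emits a single best sequence (no n-best), and the
  meta-classifier cannot output a span proposed by neither tagger.
* Document-wide abbreviation resolution can mis-expand a short form that is
  redefined with a different meaning mid-document (nearest preceding
  definition wins, which handles the common case).
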