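# Methods

## Problem and model

`vonorm` links free-text vaccine names ("mentions") from clinical-trial
intervention records to concepts of an ontology-derived reference
vocabulary. The pipeline is a cascade: dictionary-style extraction,
bi-encoder candidate retrieval, weighted rank fusion across several
encoders, a string-matching override, top-n evaluation, and an
ontology-aware error taxonomy. Each stage is usable on its own; the
`pipeline` module wires them together.

## Vocabulary and hierarchy

A concept carries an opaque id, a preferred label, synonyms and is-a
parents. Label normalization is lowercase + whitespace collapse only —
deliberately no stemming, since stemming mismatches are a distinct error
category downstream and must not be hidden by the index. A normalized
label shared by several concepts maps to all of them; ambiguity is never
collapsed silently.

The is-a graph must be acyclic (checked at load). The relation between a
gold and a predicted concept is classified by a fixed cascade: identical;
parent_child at directed distance 1; ancestor_descendant at directed
distance exactly 2; sibling when neither is an ancestor of the other but
they share an immediate parent; distant when connected in the undirected
graph at distance > 2; disconnected otherwise. "One level" is read as one
is-a edge, and "spanning more than two levels" as undirected distance
greater than 2 — a choice, made so the three hierarchy error subclasses
are mutually exclusive and exhaustive below the semantic class. Direction
is reported separately (`gold_is_ancestor`) rather than doubling the label
set. Note one literal consequence: two concepts whose only connection is a
shared *child* sit at undirected distance 2 and therefore classify as
`disconnected`, not `distant`; such co-parent pairs are rare in
vaccine-style taxonomies.

## Extraction

The two screening queries replicate WHERE-clause semantics over an
exported CSV/TSV rather than a live database: (1) `intervention_type =
'Biological'` (case-sensitive equality on the stored value) and the
lowercased name contains a lowercased vocabulary label as a plain
substring; (2) same type filter and the name contains `vaccine`. Their
union is de-duplicated by normalized name, keeping which query (or both)
matched. The TF-IDF disambiguator fits on the corpus {mention} ∪
candidates with lowercase word-unigram tokens (single-character tokens
kept), smoothed idf `ln((1+N)/(1+df)) + 1` and L2 normalization
(scikit-learn's default TF-IDF scheme); ties break by longest label, then
lexicographically, making the result independent of candidate order.

## Retrieval

Encoders are pluggable behind a two-method contract: deterministic
embedding, L2-normalized output (zero vector for empty text). The
shipped `MockEncoder` hashes boundary-padded character trigrams of the
lowercased text into a fixed number of term-frequency buckets with a
seed-keyed BLAKE2 hash. It is not a language model and does not capture
synonymy or abbreviations — by design: it gives the pipeline a fast,
fully deterministic encoder whose failure modes (initialisms, heavy
typos) are themselves useful for exercising the error taxonomy.
Transformer bi-encoders plug in through `CallableBackend`;
`TrainingConfig` records the fine-tuning recipe for such models
(1 epoch, batch 256, lr 2e-5, max sequence length 25 — short pair texts
overfit beyond one epoch), and `build_pair_corpus` emits the
`concept_id||surface` pair file such self-alignment fine-tuning consumes.
Training itself is out of scope of this package.

A concept is scored by the max cosine over all of its labels (not the
mean), matching dictionary-linking practice: an exact synonym hit scores
1. Ties break by concept id ascending, so output is bit-reproducible.

## Ensemble and SM-Rule

Fusion weights default to validation-Acc@1-proportional weights over the
top-m (default 3) models; explicit weights can be configured. Per
candidate c, the fused score is Σᵢ wᵢ·fᵢ(c) with fᵢ the raw cosine
(`score`), the min-max scaled cosine within model i's own list, constant
lists scaling to 1 (`scale`), or rank points (k − r + 1)/k (`rank`); a
candidate absent from a model's list contributes 0 under every metric —
the simplest defensible convention. The rank-point formula and min-max
scaling are fixed, documented choices.

The SM-Rule promotes to rank 1, with score 1.0, the concept of a
vocabulary label occurring verbatim in the mention (case-insensitive,
word boundaries enforced where the label starts/ends with a word
character, so "flu" cannot fire inside "influenza"). When several labels
hit, labels whose concept is a strict is-a ancestor of another hit's
concept are discarded first, then the longest label wins (ties: token
count, then lexicographic; an ambiguous label promotes the smallest
concept id). The ancestor filter is what implements the annotation
convention that a product name ("FluMist") beats the general class
("influenza vaccine") even though the general label is longer. The rule
is applied after fusion, replaces only the top slot (remaining candidates
keep their relative order, truncated back to k), and is idempotent.

## Evaluation

Acc@n is the percentage of evaluated mentions with a gold concept among
the top n candidates, rounded half-up to one decimal. Multi-gold
mentions count correct on any hit (each listed mapping is a valid
answer); an all-gold policy is available behind `require_all_golds`.
Mentions without gold annotation are excluded with a warning. The 8:1:1
split takes ⌊0.8N⌋/⌊0.1N⌋/remainder after a seeded shuffle.

## Error taxonomy

One category per top-1 miss, first match wins: correct; oov (no gold in
the vocabulary); multi-concept mention; the three hierarchy subclasses
via the is-a cascade above; abbreviation (a mention token equals the
initialism of a ≥2-word gold label); spelling (edit distance 1–2 between
normalized mention and a gold label — distance 0 is an exact match and is
deliberately left to the disambiguation rule, which would otherwise be
unreachable for exactly-matching ambiguous labels); stemming (equal after
per-token suffix stripping over a small fixed suffix list); disambiguation
(a gold label is shared with ≥1 other concept); noisy mention (dosage
/unit/schedule regex documented in `error_analysis.NOISE_PATTERN`);
semantic fall-through (covers pairs spanning more than two levels).
Shares are integer percentages (half-up) over the non-correct records, as
is the share of misses recovered within the top 10.

## Synthetic data

`generate_vocabulary` builds a templated taxonomy: disease-level roots
("measles vaccine"), platform children ("inactivated measles vaccine"),
branded leaf products with the descriptive form as synonym. Labels are
globally unique by construction; each concept carries 0–2 synonyms.
`generate_mentions` derives surface strings from labels with
per-perturbation probabilities: case changes, adjacent-character typos,
parenthetical manufacturer suffixes, initialisms, placebo suffixes
(gold stays the vaccine's own concept), dosage tokens, and multi-vaccine
joins (both concepts recorded as gold) — the same noise sources the error
taxonomy distinguishes. `generate_interventions` wraps mentions in
Biological rows and mixes in distractors (non-Biological rows and
Biological products avoiding every label and the word "vaccine"). All
randomness flows through one seeded `random.Random`; no global state.

What the generator does not emulate: real ontology label distributions,
real trial-registry text statistics, cross-lingual or misspelled beyond
the modeled perturbations, and real transformer encoders. Passing tests
therefore demonstrate the pipeline's correctness and its behavior under
controlled noise, not field performance on registry data.

## Problem sizes and defaults

The test suite and `scripts/acceptance.py` use taxonomies of 7–52
concepts and corpora of 40–550 mentions; 550 with an 8:1:1 split
(440/55/55) mirrors the scale of a realistic expert-annotated corpus for
this task. The acceptance run uses a moderate-noise profile (typos 0.3,
abbreviations 0.2, case noise 0.3, dosage tokens 0.15, multi-vaccine
joins 0.1) chosen so the error taxonomy is exercised without saturating
it, and a zero-noise 200-mention control corpus on which the pipeline is
expected to be exact. Encoder banks are three to five trigram encoders
with distinct hash seeds and dimensions (192–448), standing in for a
collection of pre-trained models. Degradation checks average Acc@1 over
10 seeds at typo probabilities {0, 0.2, 0.5}.

## Known limitations

- The trigram mock encoder cannot resolve abbreviations or semantic
  synonymy; with it, accuracy on noisy corpora is driven largely by the
  SM-Rule and surface overlap.
- The SM-Rule assumes vocabulary labels are trustworthy substrings;
  a label that is a common English word would over-fire (mitigated by
  word-boundary matching, not eliminated).
- OWL ingestion handles labels, exact synonyms and named-class
  subsumption only; anonymous class expressions are ignored, and
  vaccine-branch membership is computed from the named hierarchy.
- Suffix stripping for the stemming category is a small fixed list, not a
  full stemmer; borderline inflections may fall through to `semantic`.
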