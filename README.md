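# vonorm

Normalize free-text vaccine names from clinical-trial intervention tables
to concepts of the Vaccine Ontology (VO).

Trial registries record interventions as free text — `"MenACWY-CRM
conjugate vaccine (Menveo, Novartis)"`, `"2012–2013 trivalent seasonal
live attenuated influenza vaccine (FluMist ®)"`, `"AIDSVAX B/E Placebo"` —
with no standard coding. Linking each such mention to an ontology concept
(medical concept normalization) is what makes vaccine trials queryable,
comparable and auditable. `vonorm` implements a cascaded normalization
pipeline for this task, for informaticians working with registry exports
(e.g. the AACT `interventions` table) and an ontology-derived reference
vocabulary.

## Method

1. **Extraction.** Two screening queries over the interventions table:
   rows with `intervention_type = 'Biological'` whose name contains a
   vocabulary label as a case-insensitive substring, and Biological rows
   containing the keyword `vaccine`. Results are combined and
   de-duplicated by normalized name. When one row matches several labels,
   a TF-IDF word-unigram cosine (smoothed idf `ln((1+N)/(1+df)) + 1`,
   L2-normalized) picks the closest label.
2. **Candidate retrieval.** Mention and every concept label (preferred
   label and synonyms) are embedded by a pluggable text encoder; a
   concept's score is the max cosine over its labels and the top-k
   concepts form the candidate list. A deterministic hashed
   character-trigram encoder ships for fully offline use; transformer
   bi-encoders plug in through the same contract, and
   `build_pair_corpus` emits the `concept_id||surface` pair file used to
   fine-tune them.
3. **Ensemble.** Per-model candidate lists are fused by a weighted sum
   under one of three metrics — raw cosine (`score`), per-list min-max
   scaled cosine (`scale`), or Borda-style rank points `(k − r + 1)/k`
   (`rank`) — with weights proportional to each model's validation Acc@1
   over the top-m models.
4. **SM-Rule.** If a vocabulary label occurs verbatim (word-boundary,
   case-insensitive) inside the mention, its concept is promoted to rank 1
   with score 1.0; labels of concepts that are is-a ancestors of another
   hit are discarded first, so a product name beats the general class
   it appears alongside.
5. **Evaluation.** Acc@n = 100 · #{mentions with a gold concept in the
   top n} / #mentions, for n = 1..10, under a seeded 8:1:1
   train/validation/test split. A mention annotated with several gold
   concepts counts correct on any hit.
6. **Error analysis.** Each top-1 miss is assigned one category by a
   fixed cascade — out-of-vocabulary, multi-concept mention,
   parent/child, ancestor/descendant or sibling in the is-a DAG,
   abbreviation, spelling, stemming, disambiguation (shared surface
   label), noisy mention, or the semantic fall-through — plus the share
   of misses whose gold concept is still inside the top 10.

A seeded synthetic generator (`vonorm.synthetic`) builds templated vaccine
taxonomies, noisy annotated mentions and interventions tables, so the
whole pipeline runs and is tested without any download.

## Worked example

`examples/04_evaluate_and_analyze.py` generates a 21-concept taxonomy and
400 noisy annotated mentions, normalizes the test split with three trigram
encoders fused under the `scale` metric plus the SM-Rule, and prints:

```
split sizes: 320/40/40
                   Acc@1  Acc@2  Acc@3  Acc@4  Acc@5  Acc@6  Acc@7  Acc@8  Acc@9  Acc@10
model
ensemble+scale+sm   75.0   82.5   85.0   85.0   85.0   85.0   85.0   85.0   85.0    90.0

top-1 errors: 10, recovered in top 10: 60%
  abbreviation                  50%
  hierarchy_parent_child        20%
  semantic                      10%
  ner_noise                     10%
  ner_multi_concept             10%
```

75% of test mentions resolve to their gold concept at rank 1 and 90%
within the top 10; of the ten top-1 misses, six still carry the gold
concept in their candidate list, and half of the misses are initialisms
the trigram encoder cannot expand. The other examples
(`examples/01..03`) walk the vocabulary/hierarchy, extraction, and
fusion/override stages individually.

## Command line

Each stage is also exposed as a subcommand:

```sh
vonorm synth --preset small --seed 7 --out run/
vonorm extract --interventions run/interventions.csv --vocab run/vocabulary.tsv --out run/mentions.jsonl
vonorm normalize --mentions run/mentions.jsonl --vocab run/vocabulary.tsv --metric scale --sm-rule --k 10 --out run/candidates.jsonl
vonorm evaluate --predictions run/candidates.jsonl --gold run/gold.tsv --out run/report
vonorm analyze-errors --predictions run/candidates.jsonl --gold run/gold.tsv --vocab run/vocabulary.tsv --out run/errors
vonorm build-corpus --vocab run/vocabulary.tsv --out run/pairs.txt
```

Runs are deterministic under a fixed `--seed`, and every command writes a
resolved-config JSON next to its outputs.

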