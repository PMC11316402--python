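"""Classify incorrect top-1 predictions against an ontology-aware error
taxonomy and summarize category shares.

Categories (beyond ``correct``): out-of-vocabulary mentions, multi-concept
mentions, the three hierarchy subclasses (parent-child,
ancestor-descendant, sibling), abbreviation, spelling, stemming,
disambiguation (the gold concept shares a surface label with another
concept), noisy mentions (dosage/number/punctuation-laden), and the
``semantic`` fall-through for gold/predicted pairs spanning more than two
hierarchy levels or otherwise unrelated.

The classification is a fixed-priority cascade — every (mention, gold,
predicted) triple receives exactly one category, and re-running produces
identical summaries.  Thresholds for the fuzzy rules (edit distance,
initialism length, the noise pattern) are module constants and can be
overridden per call.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import edlib

from ._text import normalize_label, round_half_up
from .extraction import Mention
from .retrieval import CandidateList
from .vocabulary import OntologyGraph, VocabularyIndex

CATEGORIES = (
    "correct",
    "ner_multi_concept",
    "ner_noise",
    "abbreviation",
    "disambiguation",
    "hierarchy_parent_child",
    "hierarchy_sibling",
    "hierarchy_ancestor_descendant",
    "semantic",
    "stemming",
    "spelling",
    "oov",
)

# spelling: 1..MAX_EDIT_DISTANCE edits between mention and a gold label
# (distance 0 is an exact match and is left to the disambiguation rule)
MAX_EDIT_DISTANCE = 2
# abbreviation: an initialism needs at least this many source words
MIN_INITIALISM_WORDS = 2
# noise: dosage/units, schedule words, or punctuation-heavy text
NOISE_PATTERN = re.compile(
    r"\b\d+(?:\.\d+)?\s*(?:mg|ml|mcg|ug|µg|iu)\b"
    r"|\b(?:dose|doses|dosage|placebo|injection|booster)\b"
    r"|\b\d{4}\s*[-–]\s*\d{4}\b",
    re.IGNORECASE,
)
_SUFFIXES = ("ization", "ation", "ing", "ies", "ed", "es", "s")


@dataclass
class ErrorRecord:
    mention_text: str
    gold_ids: list[str]
    predicted_id: str
    category: str
    recovered_in_top10: bool = False


@dataclass
class ErrorSummary:
    """Per-category counts and integer-percent shares over the errors."""

    counts: dict[str, int]
    shares: dict[str, int]  # percent, half-up
    total_errors: int
    recovered_count: int
    recovered_share: int  # percent of errors recovered within top 10

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        rows = [{"category": c, "count": self.counts[c], "share_pct": self.shares[c]}
                for c in sorted(self.counts)]
        pd.DataFrame(rows, columns=["category", "count", "share_pct"]).to_csv(
            path, sep="\t", index=False)


def _stem(token: str) -> str:
    for suffix in _SUFFIXES:
        if token.endswith(suffix) and len(token) > len(suffix) + 2:
            return token[: -len(suffix)]
    return token


def _stem_text(text: str) -> str:
    return " ".join(_stem(t) for t in normalize_label(text).split())


def _initialisms(label: str) -> set[str]:
    words = normalize_label(label).split()
    if len(words) < MIN_INITIALISM_WORDS:
        return set()
    return {"".join(w[0] for w in words)}


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b)["editDistance"]


def classify_error(
    mention: Mention | str,
    gold_ids: Sequence[str],
    predicted_id: str,
    vocab: VocabularyIndex,
    graph: OntologyGraph,
    candidate_ids: Sequence[str] = (),
) -> ErrorRecord:
    """Assign one taxonomy category to a (mention, gold, predicted) triple.

    The cascade, first match wins:

    1. ``correct`` — predicted is one of the gold concepts;
    2. ``oov`` — no gold concept exists in the vocabulary;
    3. ``ner_multi_concept`` — the mention maps to more than one concept;
    4. hierarchy subclasses via the is-a graph (parent-child, then
       ancestor-descendant, then sibling);
    5. ``abbreviation`` — a mention token is the initialism of a gold label;
    6. ``spelling`` — small edit distance (1..2) to a gold label;
    7. ``stemming`` — mention equals a gold label after suffix stripping;
    8. ``disambiguation`` — a gold label is shared with another concept;
    9. ``ner_noise`` — dosage/number/punctuation-heavy mention text;
    10. ``semantic`` — everything else (including pairs spanning more than
        two hierarchy levels).

    ``candidate_ids`` (the mention's full ranked list) only sets the
    ``recovered_in_top10`` flag.
    """
    text = mention.text if isinstance(mention, Mention) else mention
    if predicted_id not in vocab:
        raise KeyError(f"predicted concept {predicted_id!r} not in vocabulary")
    gold_ids = list(gold_ids)
    recovered = bool(set(gold_ids) & set(candidate_ids[:10]))

    def rec(category: str) -> ErrorRecord:
        return ErrorRecord(text, gold_ids, predicted_id, category, recovered)

    if predicted_id in gold_ids:
        return ErrorRecord(text, gold_ids, predicted_id, "correct", True)
    in_vocab = [g for g in gold_ids if g in vocab]
    if not in_vocab:
        return rec("oov")
    if len(gold_ids) > 1:
        return rec("ner_multi_concept")

    gold = in_vocab[0]
    if gold in graph and predicted_id in graph:
        from .vocabulary import hierarchy_relation

        relation = hierarchy_relation(graph, gold, predicted_id).label
        if relation == "parent_child":
            return rec("hierarchy_parent_child")
        if relation == "ancestor_descendant":
            return rec("hierarchy_ancestor_descendant")
        if relation == "sibling":
            return rec("hierarchy_sibling")

    gold_labels = vocab.concepts[gold].labels
    mention_tokens = set(normalize_label(text).split())
    for label in gold_labels:
        if _initialisms(label) & mention_tokens:
            return rec("abbreviation")
    text_norm = normalize_label(text)
    for label in gold_labels:
        if 1 <= _edit_distance(text_norm, normalize_label(label)) <= MAX_EDIT_DISTANCE:
            return rec("spelling")
    for label in gold_labels:
        if _stem_text(text) == _stem_text(label) and text_norm != normalize_label(label):
            return rec("stemming")
    for label in gold_labels:
        if len(vocab.lookup_label(label)) > 1:
            return rec("disambiguation")
    if NOISE_PATTERN.search(text):
        return rec("ner_noise")
    return rec("semantic")


def classify_predictions(
    mentions: Sequence[Mention],
    predictions: Sequence[CandidateList],
    vocab: VocabularyIndex,
    graph: OntologyGraph | None = None,
) -> list[ErrorRecord]:
    """Classify every mention's top-1 prediction; empty candidate lists are
    classified against a sentinel absent prediction (always an error)."""
    if graph is None:
        graph = vocab.graph()
    records = []
    for m, cand in zip(mentions, predictions):
        ids = cand.concept_ids()
        if not ids:
            records.append(ErrorRecord(m.text, list(m.gold_ids), "", "oov"
                                       if not any(g in vocab for g in m.gold_ids)
                                       else "semantic"))
            continue
        records.append(classify_error(m, m.gold_ids, ids[0], vocab, graph,
                                      candidate_ids=ids))
    return records


def summarize(errors: Sequence[ErrorRecord]) -> ErrorSummary:
    """Integer-percent category shares over the non-correct records."""
    wrong = [e for e in errors if e.category != "correct"]
    counts = Counter(e.category for e in wrong)
    total = len(wrong)
    shares = {c: int(round_half_up(100.0 * n / total, 0)) if total else 0
              for c, n in counts.items()}
    recovered = sum(1 for e in wrong if e.recovered_in_top10)
    rec_share = int(round_half_up(100.0 * recovered / total, 0)) if total else 0
    return ErrorSummary(dict(counts), shares, total, recovered, rec_share)


def write_errors_jsonl(errors: Sequence[ErrorRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in errors:
            fh.write(json.dumps({
                "mention": e.mention_text,
                "gold_ids": e.gold_ids,
                "predicted_id": e.predicted_id,
                "category": e.category,
                "recovered_in_top10": e.recovered_in_top10,
            }, ensure_ascii=False) + "\n")
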