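"""Extract vaccine mentions from an exported clinical-trial interventions table.

Replicates the WHERE-clause semantics of the two SQL screening queries a
registry export would be filtered with — (1) Biological interventions whose
name contains a vocabulary label as a case-insensitive substring, and
(2) Biological interventions whose name contains the keyword "vaccine" —
plus the TF-IDF string-similarity step that picks one label when a single
intervention matches several vocabulary terms.  The table is consumed as a
CSV/TSV export (AACT "interventions" column names: id, nct_id,
intervention_type, name) rather than over a live database connection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import TfidfVectorizer

from ._text import normalize_label
from .vocabulary import VocabularyIndex

INTERVENTION_COLUMNS = ["id", "nct_id", "intervention_type", "name"]

MatchedVia = Literal["vo_label", "vaccine_keyword", "both"]


@dataclass(frozen=True)
class InterventionRecord:
    """One row of the interventions table."""

    id: str
    nct_id: str
    intervention_type: str
    name: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError(f"intervention {self.id!r}: empty name")


@dataclass
class Mention:
    """A vaccine surface string with provenance and (optional) gold concepts.

    ``gold_ids`` is a list because one vaccine name may legitimately map to
    multiple concepts (e.g. a combination shot naming two products).
    """

    text: str
    source_id: str
    matched_via: MatchedVia = "vo_label"
    gold_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("mention text must be non-empty")


def read_interventions(path: str | Path) -> list[InterventionRecord]:
    """Read an interventions CSV/TSV export (delimiter sniffed from suffix)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in INTERVENTION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return [
        InterventionRecord(r.id, r.nct_id, r.intervention_type, r.name)
        for r in frame.itertuples(index=False)
    ]


def query_label_match(
    records: Iterable[InterventionRecord], vocab: VocabularyIndex
) -> dict[InterventionRecord, list[str]]:
    """Screening query 1: Biological rows containing a vocabulary label.

    Matches the lowercased name against every lowercased vocabulary label
    by plain substring containment (``position(lower(label) IN
    lower(name)) > 0`` semantics).  Returns each matching record with all
    the labels that hit.
    """
    if not len(vocab):
        raise ValueError("vocabulary is empty")
    labels = sorted(vocab.label_map)
    out: dict[InterventionRecord, list[str]] = {}
    for rec in records:
        if rec.intervention_type != "Biological":
            continue
        name = rec.name.lower()
        hits = [lab for lab in labels if lab in name]
        if hits:
            out[rec] = hits
    return out


def query_keyword_match(records: Iterable[InterventionRecord]) -> list[InterventionRecord]:
    """Screening query 2: Biological rows whose name contains "vaccine"."""
    return [
        rec
        for rec in records
        if rec.intervention_type == "Biological" and "vaccine" in rec.name.lower()
    ]


def union_distinct(
    a: Iterable[InterventionRecord], b: Iterable[InterventionRecord]
) -> list[Mention]:
    """Combine both query results, one Mention per distinct normalized name.

    Duplicate names are filtered by their normalized form (lowercase,
    whitespace-collapsed); ``matched_via`` records which query (or both)
    selected the name.  Output is sorted by normalized name then source id,
    so repeated runs are byte-identical.
    """
    a_names: dict[str, InterventionRecord] = {}
    for rec in a:
        a_names.setdefault(normalize_label(rec.name), rec)
    b_names: dict[str, InterventionRecord] = {}
    for rec in b:
        b_names.setdefault(normalize_label(rec.name), rec)

    mentions = []
    for norm in sorted(set(a_names) | set(b_names)):
        in_a, in_b = norm in a_names, norm in b_names
        rec = a_names.get(norm) or b_names[norm]
        via: MatchedVia = "both" if (in_a and in_b) else ("vo_label" if in_a else "vaccine_keyword")
        mentions.append(Mention(text=rec.name, source_id=rec.id, matched_via=via))
    mentions.sort(key=lambda m: (normalize_label(m.text), m.source_id))
    return mentions


# word unigrams incl. single-character tokens; sklearn's default drops 1-char words
_TOKEN_PATTERN = r"(?u)\b\w+\b"


def tfidf_disambiguate(mention_text: str, candidate_labels: Sequence[str]) -> tuple[str, float]:
    """Pick the candidate label closest to the mention under TF-IDF cosine.

    The vectorizer is fit on the corpus {mention} ∪ candidates with
    lowercase word-unigram tokens, smoothed idf ln((1+N)/(1+df))+1 and
    L2-normalized rows.  Ties are broken by longest label, then
    lexicographic order, so the result is independent of candidate order.
    """
    if not candidate_labels:
        raise ValueError("candidate_labels must be non-empty")
    corpus = [mention_text, *candidate_labels]
    vec = TfidfVectorizer(lowercase=True, token_pattern=_TOKEN_PATTERN, norm="l2",
                          smooth_idf=True, sublinear_tf=False)
    try:
        matrix = vec.fit_transform(corpus)
    except ValueError:  # corpus of empty/stop-only strings: all-zero vectors
        matrix = None
    if matrix is None:
        sims = np.zeros(len(candidate_labels))
    else:
        sims = (matrix[1:] @ matrix[0].T).toarray().ravel()
    order = sorted(
        range(len(candidate_labels)),
        key=lambda i: (-sims[i], -len(candidate_labels[i]), candidate_labels[i]),
    )
    best = order[0]
    return candidate_labels[best], float(sims[best])


def extract_mentions(
    records: Iterable[InterventionRecord], vocab: VocabularyIndex
) -> list[Mention]:
    """Full extraction stage: both queries, combined and de-duplicated."""
    records = list(records)
    by_label = query_label_match(records, vocab)
    by_keyword = query_keyword_match(records)
    return union_distinct(by_label, by_keyword)


def write_mentions_jsonl(mentions: Iterable[Mention], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(json.dumps({
                "text": m.text,
                "source_id": m.source_id,
                "matched_via": m.matched_via,
                "gold_ids": m.gold_ids,
            }, ensure_ascii=False) + "\n")


def read_mentions_jsonl(path: str | Path) -> list[Mention]:
    mentions = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                obj = json.loads(line)
                mentions.append(Mention(
                    text=obj["text"],
                    source_id=obj.get("source_id", ""),
                    matched_via=obj.get("matched_via", "vo_label"),
                    gold_ids=list(obj.get("gold_ids", [])),
                ))
    return mentions
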