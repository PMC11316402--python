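"""Weighted rank fusion of per-model candidate lists, plus the SM-Rule.

Three fusion metrics combine the candidate lists produced by several
encoder backends for the same mention:

- ``score``: weighted sum of raw cosine scores (absent candidate -> 0);
- ``scale``: weighted sum after min-max scaling each model's scores within
  its own list to [0, 1] (a constant list scales to all 1);
- ``rank``: weighted Borda-style points (k - r + 1)/k for 1-based rank r,
  absent -> 0.

Model weights default to validation-Acc@1-proportional weights over the
top-m models, giving more influence to the models that ranked better on
held-out data.  After fusion, the string-matching rule (SM-Rule) promotes
the concept whose vocabulary label occurs verbatim (case-insensitive, at
word boundaries) inside the mention, preferring the longest such label —
this encodes the annotation convention that a product name ("FluMist")
beats the general name ("influenza vaccine") it appears alongside.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from ._text import normalize_label
from .extraction import Mention
from .retrieval import CandidateList
from .vocabulary import OntologyGraph, VocabularyIndex

logger = logging.getLogger(__name__)

Metric = Literal["score", "scale", "rank"]


@dataclass
class EnsembleConfig:
    """Fusion settings: metric, per-model weights, candidate depth k."""

    metric: Metric = "scale"
    weights: dict[str, float] = field(default_factory=dict)
    top_m_models: int = 3
    k: int = 10
    sm_rule: bool = True

    def __post_init__(self) -> None:
        if self.metric not in ("score", "scale", "rank"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.weights:
            if any(w < 0 for w in self.weights.values()):
                raise ValueError("weights must be non-negative")
            if sum(self.weights.values()) <= 0:
                raise ValueError("at least one weight must be positive")


def select_models(validation_report: Mapping[str, float], m: int = 3) -> dict[str, float]:
    """Keep the m best models by validation Acc@1, with accuracy-proportional
    weights.

    Ties are broken by model name; if every accuracy is zero the kept
    models get uniform weights (with a warning).
    """
    if not validation_report:
        raise ValueError("validation report is empty")
    if m < 1:
        raise ValueError("m must be >= 1")
    ranked = sorted(validation_report.items(), key=lambda kv: (-kv[1], kv[0]))[:m]
    total = sum(acc for _, acc in ranked)
    if total <= 0:
        logger.warning("all validation accuracies are zero; using uniform weights")
        return {name: 1.0 / len(ranked) for name, _ in ranked}
    return {name: acc / total for name, acc in ranked}


def _scaled(entries: Sequence[tuple[str, float]]) -> dict[str, float]:
    scores = [s for _, s in entries]
    lo, hi = min(scores), max(scores)
    if hi == lo:  # constant list scales to all 1
        return {cid: 1.0 for cid, _ in entries}
    return {cid: (s - lo) / (hi - lo) for cid, s in entries}


def fuse(lists: Sequence[CandidateList], config: EnsembleConfig) -> CandidateList:
    """Fuse per-model candidate lists for one mention into a single ranking.

    Models absent from ``config.weights`` (when weights are given) get
    weight 0; with no weights configured, models are weighted uniformly.
    Output is sorted by fused score descending with concept_id tie-break
    and truncated to k.
    """
    if not lists:
        raise ValueError("no candidate lists to fuse")
    texts = {cl.mention_text for cl in lists}
    if len(texts) > 1:
        raise ValueError(f"candidate lists refer to different mentions: {sorted(texts)}")

    if config.weights:
        weights = dict(config.weights)
    else:
        weights = {cl.model: 1.0 / len(lists) for cl in lists}

    fused: dict[str, float] = {}
    for cl in sorted(lists, key=lambda c: c.model):
        w = weights.get(cl.model, 0.0)
        if w == 0.0 or not cl.entries:
            continue
        if config.metric == "score":
            contrib = {cid: s for cid, s in cl.entries}
        elif config.metric == "scale":
            contrib = _scaled(cl.entries)
        else:  # rank
            k = config.k
            contrib = {cid: (k - r + 1) / k for r, (cid, _) in enumerate(cl.entries, start=1)}
        for cid, val in contrib.items():
            fused[cid] = fused.get(cid, 0.0) + w * val

    ranked = sorted(fused.items(), key=lambda kv: (-kv[1], kv[0]))[: config.k]
    return CandidateList(
        mention_text=lists[0].mention_text,
        model=f"ensemble+{config.metric}",
        entries=ranked,
    )


def _label_occurs(label_norm: str, text_norm: str) -> bool:
    """Case-insensitive substring match at word boundaries.

    Word boundaries are enforced only where the label starts/ends with a
    word character, so trademark glyphs and punctuation inside labels
    still match; "flu" will not match inside "influenza".
    """
    pattern = re.escape(label_norm).replace(r"\ ", r"\s+")
    if label_norm and label_norm[0].isalnum():
        pattern = r"(?<!\w)" + pattern
    if label_norm and label_norm[-1].isalnum():
        pattern = pattern + r"(?!\w)"
    return re.search(pattern, text_norm) is not None


def sm_rule(
    mention: Mention | str,
    vocab: VocabularyIndex,
    fused: CandidateList,
    k: int | None = None,
    graph: "OntologyGraph | None" = None,
) -> CandidateList:
    """Promote the concept of a vocabulary label found verbatim in the
    mention to rank 1 with score 1.0.

    When several labels hit, labels whose concept is a strict is-a
    ancestor of another hit's concept are discarded first — a mention
    naming both the product ("FluMist") and its general class ("influenza
    vaccine") resolves to the product, matching the annotation convention
    that product names beat general names.  Among the remaining labels the
    longest wins, ties broken by token count then lexicographically; a
    label shared by several concepts promotes the smallest concept_id.
    With no label hit the list is returned unchanged.  The rule is
    idempotent.
    """
    text = mention.text if isinstance(mention, Mention) else mention
    text_norm = normalize_label(text)
    hits = [lab for lab in vocab.label_map if _label_occurs(lab, text_norm)]
    if not hits:
        return fused
    hit_concepts = set().union(*(vocab.label_map[lab] for lab in hits))
    if len(hit_concepts) > 1:
        if graph is None:
            graph = vocab.graph()
        ancestors = {
            c for c in hit_concepts
            if any(o != c and o in graph and c in graph
                   and graph._directed_distance(o, c) is not None
                   for o in hit_concepts)
        }
        survivors = hit_concepts - ancestors or hit_concepts
        hits = [lab for lab in hits if vocab.label_map[lab] & survivors]
    else:
        survivors = hit_concepts
    hits.sort(key=lambda lab: (-len(lab), -len(lab.split()), lab))
    winner = min(vocab.label_map[hits[0]] & survivors)

    entries = [(winner, 1.0)]
    entries.extend((cid, s) for cid, s in fused.entries if cid != winner)
    if k is None:
        k = max(len(fused.entries), 1)
    return CandidateList(mention_text=fused.mention_text, model=fused.model,
                         entries=entries[:k])
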