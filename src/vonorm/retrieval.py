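"""Bi-encoder candidate retrieval: embed mentions and vocabulary labels,
rank concepts by cosine similarity.

The encoder is pluggable behind :class:`EncoderBackend`: any object that
deterministically maps text to an L2-normalized vector qualifies — a
hashed character-trigram encoder ships for fully offline use, and a
sentence-transformer can be wrapped with :class:`CallableBackend`.  A
concept's score against a mention is the max cosine over all of its labels
(preferred label and every synonym), so an exact synonym hit scores 1.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Protocol, Sequence, runtime_checkable

import numpy as np

from .extraction import Mention
from .vocabulary import VocabularyIndex

logger = logging.getLogger(__name__)


@runtime_checkable
class EncoderBackend(Protocol):
    """Contract for text encoders.

    Implementations must be deterministic (same text -> same vector) and
    return L2-normalized vectors (or the zero vector for empty text).
    """

    name: str
    dimension: int

    def embed(self, text: str) -> np.ndarray: ...


@dataclass(frozen=True)
class TrainingConfig:
    """Fine-tuning hyperparameters for transformer backends.

    Defaults follow the published recipe for aligning a biomedical BERT to
    short vaccine-name/concept pairs: a single epoch suffices because the
    pair corpus is simple short text, and more epochs overfit.
    """

    epochs: int = 1
    train_batch_size: int = 256
    learning_rate: float = 2e-5
    max_seq_length: int = 25

    def __post_init__(self) -> None:
        if min(self.epochs, self.train_batch_size, self.max_seq_length) <= 0:
            raise ValueError("epochs, batch size and max_seq_length must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class MockEncoder:
    """Deterministic hashed character-trigram encoder.

    Trigrams are taken over the lowercased text padded with ``#`` boundary
    markers and hashed into ``dimension`` term-frequency buckets with a
    seed-keyed BLAKE2 hash; the vector is L2-normalized.  Strings sharing
    character trigrams get high cosine, which is enough to exercise the
    whole ranking/ensemble/evaluation pipeline without a GPU model.
    """

    def __init__(self, dimension: int = 256, seed: int = 0, name: str | None = None):
        if dimension < 16:
            raise ValueError("dimension must be >= 16")
        self.dimension = dimension
        self.seed = seed
        self.name = name if name is not None else f"mock-{dimension}-{seed}"
        self._key = int(seed).to_bytes(8, "little", signed=True)

    def _bucket(self, trigram: str) -> int:
        digest = hashlib.blake2b(trigram.encode("utf-8"), key=self._key, digest_size=8)
        return int.from_bytes(digest.digest(), "little") % self.dimension

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dimension)
        padded = f"#{text.lower()}#"
        if len(padded) < 3:
            return vec
        for i in range(len(padded) - 2):
            vec[self._bucket(padded[i : i + 3])] += 1.0
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


@dataclass
class CallableBackend:
    """Adapter wrapping any text->vector callable (e.g. a sentence
    transformer's encode) into the backend contract; output is
    re-normalized defensively."""

    name: str
    dimension: int
    fn: Callable[[str], np.ndarray]

    def embed(self, text: str) -> np.ndarray:
        vec = np.asarray(self.fn(text), dtype=float).ravel()
        if vec.shape != (self.dimension,):
            raise ValueError(f"backend {self.name}: expected dimension {self.dimension}, "
                             f"got {vec.shape}")
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


def mock_encoder(dimension: int = 256, seed: int = 0) -> MockEncoder:
    """Construct the deterministic trigram test encoder."""
    return MockEncoder(dimension=dimension, seed=seed)


@dataclass
class ConceptIndex:
    """Embedded vocabulary labels for one backend: one row per
    (concept, label) pair."""

    backend_name: str
    concept_ids: list[str]
    labels: list[str]
    matrix: np.ndarray  # (n_rows, dimension), rows L2-normalized

    def __len__(self) -> int:
        return len(self.concept_ids)


@dataclass
class CandidateList:
    """Ranked (concept_id, cosine score) pairs for one mention from one model."""

    mention_text: str
    model: str
    entries: list[tuple[str, float]] = field(default_factory=list)

    def concept_ids(self) -> list[str]:
        return [cid for cid, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def build_concept_index(vocab: VocabularyIndex, backend: EncoderBackend) -> ConceptIndex:
    """Embed the preferred label and every synonym of every concept."""
    if not len(vocab):
        raise ValueError("vocabulary is empty")
    concept_ids: list[str] = []
    labels: list[str] = []
    rows: list[np.ndarray] = []
    for cid in sorted(vocab.concepts):
        for label in vocab.concepts[cid].labels:
            try:
                vec = backend.embed(label)
            except Exception as exc:
                raise RuntimeError(
                    f"backend {backend.name!r} failed on label {label!r} "
                    f"of concept {cid}"
                ) from exc
            concept_ids.append(cid)
            labels.append(label)
            rows.append(vec)
    return ConceptIndex(backend.name, concept_ids, labels, np.vstack(rows))


def rank_candidates(
    mention: Mention | str, index: ConceptIndex, backend: EncoderBackend, k: int = 10
) -> CandidateList:
    """Top-k concepts by max-over-labels cosine similarity.

    Ties are broken by concept_id ascending for bit-reproducible output.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not len(index):
        raise ValueError("concept index is empty")
    text = mention.text if isinstance(mention, Mention) else mention
    query = backend.embed(text)
    sims = index.matrix @ query
    best: dict[str, float] = {}
    for cid, sim in zip(index.concept_ids, sims):
        s = float(sim)
        if cid not in best or s > best[cid]:
            best[cid] = s
    ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return CandidateList(mention_text=text, model=index.backend_name, entries=ranked)


def build_pair_corpus(
    vocab: VocabularyIndex, mentions: Sequence[Mention] = ()
) -> tuple[list[str], int]:
    """Build a self-alignment training pair corpus.

    One line ``concept_id||surface`` per (concept, label) pair and per
    gold-annotated mention text, de-duplicated and sorted.  Mentions whose
    gold id is not in the vocabulary are skipped with a warning; the count
    of skipped pairs is returned alongside the lines.
    """
    pairs: set[tuple[str, str]] = set()
    for cid in vocab.concepts:
        for label in vocab.concepts[cid].labels:
            pairs.add((cid, label))
    skipped = 0
    for m in mentions:
        for gid in m.gold_ids:
            if gid not in vocab:
                logger.warning("mention %r: unknown gold id %s skipped", m.text, gid)
                skipped += 1
                continue
            pairs.add((gid, m.text))
    lines = [f"{cid}||{surface}" for cid, surface in sorted(pairs)]
    return lines, skipped


def write_candidates_jsonl(lists: Iterable[CandidateList], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cl in lists:
            fh.write(json.dumps({
                "mention": cl.mention_text,
                "model": cl.model,
                "entries": [[cid, round(score, 12)] for cid, score in cl.entries],
            }, ensure_ascii=False) + "\n")


def read_candidates_jsonl(path: str | Path) -> list[CandidateList]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                obj = json.loads(line)
                out.append(CandidateList(
                    mention_text=obj["mention"],
                    model=obj["model"],
                    entries=[(cid, float(s)) for cid, s in obj["entries"]],
                ))
    return out
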