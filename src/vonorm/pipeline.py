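"""Convenience wiring of the full normalization pipeline.

One call takes annotated mentions plus a vocabulary through per-backend
retrieval, weighted fusion and the SM-Rule, which is how the CLI, the
examples and the evaluation harness all drive the library.
"""

from __future__ import annotations

from typing import Sequence

from .ensemble import EnsembleConfig, fuse, sm_rule
from .extraction import Mention
from .retrieval import (
    CandidateList,
    ConceptIndex,
    EncoderBackend,
    build_concept_index,
    mock_encoder,
    rank_candidates,
)
from .vocabulary import VocabularyIndex


def default_backends(seed: int = 0, n: int = 3) -> list[EncoderBackend]:
    """A bank of independent trigram encoders (distinct hash keys and
    dimensions), standing in for a collection of pre-trained models."""
    dims = [192, 256, 320, 384, 448]
    return [mock_encoder(dimension=dims[i % len(dims)], seed=seed * 1000 + i)
            for i in range(n)]


def rank_all(
    mentions: Sequence[Mention],
    vocab: VocabularyIndex,
    backend: EncoderBackend,
    k: int = 10,
    index: ConceptIndex | None = None,
) -> list[CandidateList]:
    """Ranked candidates for every mention from one backend."""
    if index is None:
        index = build_concept_index(vocab, backend)
    return [rank_candidates(m, index, backend, k=k) for m in mentions]


def normalize_mentions(
    mentions: Sequence[Mention],
    vocab: VocabularyIndex,
    backends: Sequence[EncoderBackend],
    config: EnsembleConfig | None = None,
) -> list[CandidateList]:
    """Full normalization: per-backend ranking, fusion, optional SM-Rule."""
    config = config or EnsembleConfig()
    indexes = [build_concept_index(vocab, b) for b in backends]
    graph = vocab.graph() if config.sm_rule else None
    out = []
    for m in mentions:
        per_model = [rank_candidates(m, idx, b, k=config.k)
                     for idx, b in zip(indexes, backends)]
        fused = fuse(per_model, config)
        if config.sm_rule:
            fused = sm_rule(m, vocab, fused, k=config.k, graph=graph)
        out.append(fused)
    return out
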