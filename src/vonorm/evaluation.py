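"""Dataset splitting, top-n accuracy and report tables.

Top-n accuracy is the share of mentions whose gold concept appears among
the first n ranked candidates:

    Acc@n = 100 * #{mentions with a gold id in their top n} / #mentions

A mention annotated with several gold concepts counts as correct when ANY
of them is retrieved (each listed mapping is a valid answer); the stricter
all-gold policy is available behind a flag.  Accuracies are reported as
percentages rounded half-up to one decimal, matching the conventional
Acc@1..Acc@10 table layout.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._text import round_half_up
from .extraction import Mention
from .retrieval import CandidateList

logger = logging.getLogger(__name__)


def split_dataset(
    mentions: Sequence[Mention],
    ratios: tuple[float, float, float] = (8, 1, 1),
    seed: int = 0,
) -> tuple[list[Mention], list[Mention], list[Mention]]:
    """Deterministic train/validation/test split.

    Sizes are ⌊r_train·N⌋ / ⌊r_val·N⌋ / remainder after normalizing the
    ratios; the shuffle is driven entirely by ``seed``.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    n = len(mentions)
    if n < 3:
        raise ValueError(f"need at least 3 mentions to split, got {n}")
    total = sum(ratios)
    n_train = int(n * ratios[0] / total)
    n_val = int(n * ratios[1] / total)
    perm = np.random.RandomState(seed).permutation(n)
    items = [mentions[i] for i in perm]
    return items[:n_train], items[n_train : n_train + n_val], items[n_train + n_val :]


def _is_correct(candidates: CandidateList, gold_ids: Sequence[str], n: int,
                require_all: bool) -> bool:
    top = set(candidates.concept_ids()[:n])
    if require_all:
        return all(g in top for g in gold_ids)
    return any(g in top for g in gold_ids)


def top_n_accuracy(
    predictions: Sequence[CandidateList],
    golds: Sequence[Sequence[str]],
    n: int = 1,
    require_all_golds: bool = False,
) -> float:
    """Acc@n as a percentage rounded half-up to one decimal.

    Mentions without any gold annotation are excluded with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(predictions) != len(golds):
        raise ValueError("predictions and golds must align one-to-one")
    evaluated = correct = 0
    skipped = 0
    for cand, gold in zip(predictions, golds):
        if not gold:
            skipped += 1
            continue
        evaluated += 1
        if _is_correct(cand, gold, n, require_all_golds):
            correct += 1
    if skipped:
        warnings.warn(f"{skipped} mention(s) without gold annotation excluded")
    if evaluated == 0:
        return 0.0
    return round_half_up(100.0 * correct / evaluated, 1)


@dataclass
class EvalReport:
    """Acc@1..Acc@max_n per model plus the underlying counts."""

    accuracies: dict[str, dict[int, float]]  # model -> n -> percentage
    totals: dict[str, int]
    correct: dict[str, dict[int, int]]
    skipped_no_gold: int = 0
    max_n: int = 10

    def delta(self, model_a: str, model_b: str, n: int) -> float:
        """Acc@n(model_a) − Acc@n(model_b), at one decimal."""
        return round_half_up(self.accuracies[model_a][n] - self.accuracies[model_b][n], 1)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {f"Acc@{n}": {m: self.accuracies[m][n] for m in self.accuracies}
             for n in range(1, self.max_n + 1)}
        )
        frame.index.name = "model"
        return frame

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "accuracies": {m: {str(n): v for n, v in accs.items()}
                           for m, accs in self.accuracies.items()},
            "totals": self.totals,
            "correct": {m: {str(n): v for n, v in cs.items()}
                        for m, cs in self.correct.items()},
            "skipped_no_gold": self.skipped_no_gold,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def report(
    models: Sequence[tuple[str, Sequence[CandidateList]]],
    golds: Sequence[Sequence[str]],
    max_n: int = 10,
    require_all_golds: bool = False,
) -> EvalReport:
    """Evaluate several models on the same mentions into one table."""
    if not models:
        raise ValueError("need at least one model")
    accuracies: dict[str, dict[int, float]] = {}
    totals: dict[str, int] = {}
    correct: dict[str, dict[int, int]] = {}
    skipped = sum(1 for g in golds if not g)
    for name, preds in models:
        if len(preds) != len(golds):
            raise ValueError(f"model {name!r}: predictions and golds must align")
        counts = {n: 0 for n in range(1, max_n + 1)}
        evaluated = 0
        for cand, gold in zip(preds, golds):
            if not gold:
                continue
            evaluated += 1
            for n in range(1, max_n + 1):
                if _is_correct(cand, gold, n, require_all_golds):
                    counts[n] += 1
        totals[name] = evaluated
        correct[name] = counts
        accuracies[name] = {
            n: round_half_up(100.0 * counts[n] / evaluated, 1) if evaluated else 0.0
            for n in range(1, max_n + 1)
        }
    return EvalReport(accuracies, totals, correct, skipped, max_n)


def pairwise_deltas(rep: EvalReport, n: int = 1) -> dict[tuple[str, str], float]:
    """All ordered-pair Acc@n differences between models in a report."""
    names = list(rep.accuracies)
    return {(a, b): rep.delta(a, b, n) for a in names for b in names if a != b}
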