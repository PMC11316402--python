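"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (plain dict/queue BFS,
raw numpy cosine, naive per-row scans) and shares no code with the
package paths it checks.
"""

from __future__ import annotations

import math
import random
from collections import deque


def bfs_distance(adjacency: dict[str, set[str]], start: str, goal: str) -> int | None:
    """Plain BFS shortest-path length on an adjacency dict."""
    if start == goal:
        return 0
    seen = {start}
    queue = deque([(start, 0)])
    while queue:
        node, dist = queue.popleft()
        for nxt in adjacency.get(node, ()):
            if nxt == goal:
                return dist + 1
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, dist + 1))
    return None


def oracle_relation(child_to_parents: dict[str, set[str]], nodes: set[str],
                    gold: str, predicted: str) -> str:
    """Definitional hierarchy-relation cascade on raw BFS distances."""
    if gold == predicted:
        return "identical"
    up = {c: set(ps) for c, ps in child_to_parents.items()}
    undirected: dict[str, set[str]] = {n: set() for n in nodes}
    for c, ps in child_to_parents.items():
        for p in ps:
            undirected[c].add(p)
            undirected[p].add(c)
    d_pred_to_gold = bfs_distance(up, predicted, gold)  # gold is ancestor
    d_gold_to_pred = bfs_distance(up, gold, predicted)
    directed = min((d for d in (d_pred_to_gold, d_gold_to_pred) if d is not None),
                   default=None)
    if directed == 1:
        return "parent_child"
    if directed == 2:
        return "ancestor_descendant"
    if directed is None and child_to_parents.get(gold, set()) & child_to_parents.get(
            predicted, set()):
        return "sibling"
    und = bfs_distance(undirected, gold, predicted)
    if und is not None and und > 2:
        return "distant"
    return "disconnected"


def random_dag(n_nodes: int, edge_prob: float, rng: random.Random) -> dict[str, set[str]]:
    """Random DAG as child->parents over nodes n0..n{k-1}; edges only point
    to lower indices, so acyclicity holds by construction."""
    edges: dict[str, set[str]] = {}
    for child in range(1, n_nodes):
        for parent in range(child):
            if rng.random() < edge_prob:
                edges.setdefault(f"n{child}", set()).add(f"n{parent}")
    return edges


def cosine(a, b) -> float:
    num = sum(x * y for x, y in zip(a, b))
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(y * y for y in b))
    if na == 0 or nb == 0:
        return 0.0
    return num / (na * nb)


def oracle_tfidf_best(mention: str, candidates: list[str]) -> tuple[str, float]:
    """Hand-rolled TF-IDF cosine: lowercase word unigrams, smoothed idf
    ln((1+N)/(1+df))+1, L2 normalization implicit in the cosine."""
    import re

    def tokens(text: str) -> list[str]:
        return re.findall(r"\w+", text.lower())

    docs = [tokens(mention)] + [tokens(c) for c in candidates]
    vocab = sorted({t for d in docs for t in d})
    n = len(docs)
    df = {t: sum(1 for d in docs if t in d) for t in vocab}
    idf = {t: math.log((1 + n) / (1 + df[t])) + 1 for t in vocab}

    def vec(doc: list[str]) -> list[float]:
        return [doc.count(t) * idf[t] for t in vocab]

    mvec = vec(docs[0])
    sims = [cosine(mvec, vec(d)) for d in docs[1:]]
    order = sorted(range(len(candidates)),
                   key=lambda i: (-sims[i], -len(candidates[i]), candidates[i]))
    return candidates[order[0]], sims[order[0]]
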