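"""Build a synthetic vaccine vocabulary and query its is-a hierarchy."""

from vonorm import generate_vocabulary, hierarchy_relation

vocab, graph = generate_vocabulary(n_roots=2, depth=3, branching=2, seed=0)
print(f"concepts: {len(vocab)}")

ids = sorted(vocab.concepts)
root, child = ids[0], ids[2]
print(f"{vocab.concepts[root].preferred_label!r}  vs  "
      f"{vocab.concepts[child].preferred_label!r}")
rel = hierarchy_relation(graph, root, child)
print(f"relation: {rel.label}, gold_is_ancestor={rel.gold_is_ancestor}")
# parent_child means the two concepts sit one is-a step apart -- exactly the
# distinction the error taxonomy uses to separate near-miss predictions from
# genuinely unrelated ones.
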