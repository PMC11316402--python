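"""Split an annotated corpus, report Acc@1..Acc@10, and classify the misses."""

from vonorm import (
    EnsembleConfig,
    default_backends,
    generate_mentions,
    generate_vocabulary,
    normalize_mentions,
    report,
    split_dataset,
)
from vonorm.error_analysis import classify_predictions, summarize
from vonorm.synthetic import NoiseProfile

vocab, graph = generate_vocabulary(n_roots=3, depth=3, branching=2, seed=4)
profile = NoiseProfile(typo_swap=0.5, abbreviation=0.35, dosage_tokens=0.3,
                       case_change=0.3, multi_vaccine_join=0.1, seed=5)
mentions = generate_mentions(vocab, 400, profile)
train, val, test = split_dataset(mentions, (8, 1, 1), seed=4)
print(f"split sizes: {len(train)}/{len(val)}/{len(test)}")

backends = default_backends(seed=0, n=3)
preds = normalize_mentions(test, vocab, backends,
                           EnsembleConfig(metric="scale", sm_rule=True, k=10))
golds = [m.gold_ids for m in test]
rep = report([("ensemble+scale+sm", preds)], golds)
print(rep.to_frame().to_string())
# Acc@n = percentage of test mentions whose gold concept is in the top n.

errors = classify_predictions(test, preds, vocab, graph)
summary = summarize(errors)
print(f"\ntop-1 errors: {summary.total_errors}, "
      f"recovered in top 10: {summary.recovered_share}%")
for category, share in sorted(summary.shares.items(), key=lambda kv: -kv[1]):
    print(f"  {category:28s} {share:3d}%")
# shares are integer percentages of the non-correct predictions per category.
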