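"""Screen an interventions table for vaccine mentions.

Two queries emulate the registry screening: Biological rows containing a
vocabulary label, and Biological rows containing the keyword "vaccine";
TF-IDF cosine picks one label when a row matches several.
"""

from vonorm import extract_mentions, generate_vocabulary, tfidf_disambiguate
from vonorm.synthetic import NoiseProfile, generate_interventions

vocab, _ = generate_vocabulary(n_roots=2, depth=3, branching=2, seed=1)
records, gold = generate_interventions(vocab, n_vaccine=20, n_distractor=10,
                                       profile=NoiseProfile(seed=1))
mentions = extract_mentions(records, vocab)
print(f"{len(records)} intervention rows -> {len(mentions)} distinct vaccine mentions")

label, score = tfidf_disambiguate(
    "meningococcal conjugate vaccine",
    ["conjugate vaccine", "meningococcal conjugate vaccine"],
)
print(f"TF-IDF picks {label!r} (cosine {score:.3f})")
# the exact multi-word label wins over its more general substring; a cosine
# of 1.0 means the mention and the label have identical token profiles.
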