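"""Synthetic vocabularies, intervention tables and annotated noisy mentions.

Every pipeline stage is testable offline: :func:`generate_vocabulary`
builds a small templated vaccine taxonomy (disease roots, platform
children, branded products) shaped like the vaccine branch of a real
ontology; :func:`generate_mentions` derives noisy surface strings from
vocabulary labels with known gold mappings; and
:func:`generate_interventions` wraps them in registry-export rows mixed
with distractors.

The perturbation inventory (case changes, typos, parenthetical
manufacturers, initialisms, placebo suffixes, dosage tokens, multi-vaccine
joins) mirrors the noise actually observed in trial intervention names,
so each downstream error category can be triggered on purpose.  Gold
annotations follow the annotation conventions for such data: a placebo
arm keeps the vaccine's own concept, and a name listing two products maps
to both concepts.  All randomness flows through one seeded generator; no
global state.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .extraction import INTERVENTION_COLUMNS, InterventionRecord, Mention
from .vocabulary import Concept, OntologyGraph, VocabularyIndex

_DISEASES = [
    "measles", "influenza", "rabies", "polio", "hepatitis", "typhoid",
    "cholera", "pertussis", "rotavirus", "varicella", "mumps", "rubella",
    "tetanus", "diphtheria", "anthrax", "smallpox", "dengue", "zoster",
    "meningococcal", "pneumococcal",
]
_PLATFORMS = [
    "live attenuated", "inactivated", "conjugate", "recombinant",
    "subunit", "mrna", "vector", "toxoid", "polysaccharide", "split virion",
]
_BRAND_STEMS = ["Vax", "Imu", "Pro", "Shield", "Gard", "Biva", "Tri", "Quad"]
_BRAND_TAILS = ["ix", "ax", "ol", "era", "ion", "is", "ux", "eo"]

_DISTRACTOR_BIOLOGICALS = [
    "normal saline solution",
    "monoclonal antibody infusion",
    "autologous cell therapy",
    "plasma derived immunoglobulin",
    "adjuvant emulsion only",
    "recombinant cytokine product",
]
_DISTRACTOR_TYPES = ["Drug", "Device", "Procedure", "Behavioral"]
_DISTRACTOR_NAMES = [
    "aspirin tablet", "insulin pump", "physical therapy", "dietary counseling",
    "metformin", "stent placement", "cognitive training",
]


@dataclass
class NoiseProfile:
    """Per-perturbation probabilities (all in [0, 1]) and the RNG seed."""

    case_change: float = 0.0
    typo_swap: float = 0.0
    parenthetical_brand: float = 0.0
    abbreviation: float = 0.0
    placebo_suffix: float = 0.0
    dosage_tokens: float = 0.0
    multi_vaccine_join: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("case_change", "typo_swap", "parenthetical_brand", "abbreviation",
                     "placebo_suffix", "dosage_tokens", "multi_vaccine_join"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} probability {p} outside [0, 1]")


def _brand(rng: random.Random, used: set[str]) -> str:
    while True:
        name = rng.choice(_BRAND_STEMS) + rng.choice(_BRAND_TAILS) + str(rng.randrange(10, 99))
        if name.lower() not in used:
            used.add(name.lower())
            return name


def generate_vocabulary(
    n_roots: int = 3, depth: int = 3, branching: int = 2, seed: int = 0
) -> tuple[VocabularyIndex, OntologyGraph]:
    """Templated vaccine taxonomy: n_roots · Σ branching^(ℓ-1) concepts.

    Level 1 holds disease-level vaccines ("measles vaccine"), level 2 adds
    a platform ("live attenuated measles vaccine"), deeper levels are
    branded products with the brand as preferred label and the descriptive
    form as a synonym.  Labels are globally unique by construction.
    """
    if min(n_roots, depth, branching) < 1:
        raise ValueError("n_roots, depth and branching must all be >= 1")
    if depth >= 2 and branching > len(_PLATFORMS):
        raise ValueError(f"branching > {len(_PLATFORMS)} exhausts the platform templates")
    rng = random.Random(seed)
    index = VocabularyIndex()
    used_labels: set[str] = set()
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"SVO:{counter:07d}"

    def add(label: str, parents: tuple[str, ...], synonyms: tuple[str, ...]) -> str:
        cid = next_id()
        index.add(Concept(cid, label, synonyms=synonyms, parent_ids=parents))
        used_labels.add(label.lower())
        for s in synonyms:
            used_labels.add(s.lower())
        return cid

    level: list[tuple[str, str]] = []  # (concept_id, base phrase)
    for r in range(n_roots):
        disease = _DISEASES[r % len(_DISEASES)]
        if r >= len(_DISEASES):
            disease = f"{disease} type {r // len(_DISEASES) + 1}"
        label = f"{disease} vaccine"
        n_syn = rng.randrange(3)  # 0-2 synonyms
        syns = tuple(f"vaccine, {disease}" for _ in range(min(n_syn, 1)))
        level.append((add(label, (), syns), label))

    for lvl in range(2, depth + 1):
        nxt: list[tuple[str, str]] = []
        for parent_id, parent_label in level:
            for b in range(branching):
                if lvl == 2:
                    platform = _PLATFORMS[(b + rng.randrange(2)) % len(_PLATFORMS)]
                    label = f"{platform} {parent_label}"
                    while label.lower() in used_labels:
                        platform = _PLATFORMS[rng.randrange(len(_PLATFORMS))]
                        label = f"{platform} {parent_label}"
                    n_syn = rng.randrange(3)
                    syns = []
                    if n_syn >= 1:
                        syns.append(f"{parent_label}, {platform}")
                    if n_syn >= 2:
                        syns.append(f"{platform} {parent_label} preparation")
                    nxt.append((add(label, (parent_id,), tuple(syns)), label))
                else:
                    brand = _brand(rng, used_labels)
                    label = f"{brand}"
                    n_syn = rng.randrange(3)
                    syns = []
                    if n_syn >= 1:
                        syns.append(f"{brand} {parent_label}")
                    if n_syn >= 2:
                        syns.append(f"{brand} injectable")
                    nxt.append((add(label, (parent_id,), tuple(syns)), label))
        level = nxt
    return index, index.graph()


def _perturb(text: str, profile: NoiseProfile, rng: random.Random) -> str:
    if profile.abbreviation and rng.random() < profile.abbreviation:
        words = text.split()
        if len(words) >= 2:
            text = "".join(w[0] for w in words).lower()
    if profile.typo_swap and rng.random() < profile.typo_swap and len(text) >= 4:
        i = rng.randrange(len(text) - 1)
        text = text[:i] + text[i + 1] + text[i] + text[i + 2:]
    if profile.case_change and rng.random() < profile.case_change:
        text = "".join(c.upper() if rng.random() < 0.5 else c.lower() for c in text)
    if profile.parenthetical_brand and rng.random() < profile.parenthetical_brand:
        text = f"{text} ({rng.choice(['Novapharm', 'Genmed', 'Biocore'])})"
    if profile.placebo_suffix and rng.random() < profile.placebo_suffix:
        text = f"{text} Placebo"
    if profile.dosage_tokens and rng.random() < profile.dosage_tokens:
        text = f"{text} {rng.choice(['0.5 ml', '25 mcg', '2 doses'])} dose"
    return text


def generate_mentions(
    vocab: VocabularyIndex, n: int, profile: NoiseProfile | None = None
) -> list[Mention]:
    """Derive n annotated mentions from vocabulary labels.

    Each mention starts from one concept's label (preferred label with
    probability 0.7, otherwise a synonym) and passes through the sampled
    perturbations.  A multi-vaccine join concatenates a second concept's
    label and records both gold ids; a placebo suffix keeps the vaccine's
    own id.  Deterministic given ``profile.seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not len(vocab):
        raise ValueError("vocabulary is empty")
    profile = profile or NoiseProfile()
    rng = random.Random(profile.seed)
    cids = sorted(vocab.concepts)
    mentions = []
    for i in range(n):
        cid = rng.choice(cids)
        concept = vocab.concepts[cid]
        label = concept.preferred_label
        if concept.synonyms and rng.random() >= 0.7:
            label = rng.choice(concept.synonyms)
        gold = [cid]
        text = label
        if profile.multi_vaccine_join and rng.random() < profile.multi_vaccine_join:
            other = rng.choice([c for c in cids if c != cid] or [cid])
            if other != cid:
                text = f"{label}, {vocab.concepts[other].preferred_label}"
                gold.append(other)
        text = _perturb(text, profile, rng)
        mentions.append(Mention(text=text, source_id=f"synth-{i:05d}", gold_ids=gold))
    return mentions


def generate_interventions(
    vocab: VocabularyIndex,
    n_vaccine: int = 20,
    n_distractor: int = 10,
    profile: NoiseProfile | None = None,
) -> tuple[list[InterventionRecord], list[Mention]]:
    """Registry-export rows: Biological vaccine rows plus distractors.

    Returns the rows together with the gold-annotated mentions underlying
    the vaccine rows.  Distractor rows mix non-Biological interventions and
    Biological products whose names avoid every vocabulary label and the
    word "vaccine", so the extraction stage should recover exactly the
    vaccine rows (modulo duplicate names).
    """
    profile = profile or NoiseProfile()
    rng = random.Random(profile.seed + 1)
    mentions = generate_mentions(vocab, n_vaccine, profile) if n_vaccine else []
    records = []
    for i, m in enumerate(mentions):
        records.append(InterventionRecord(
            id=f"i{i:06d}", nct_id=f"NCT{10000000 + i}", intervention_type="Biological",
            name=m.text,
        ))
    for j in range(n_distractor):
        if j % 2 == 0:
            name = _DISTRACTOR_BIOLOGICALS[j % len(_DISTRACTOR_BIOLOGICALS)]
            itype = "Biological"
        else:
            name = _DISTRACTOR_NAMES[j % len(_DISTRACTOR_NAMES)]
            itype = rng.choice(_DISTRACTOR_TYPES)
        records.append(InterventionRecord(
            id=f"d{j:06d}", nct_id=f"NCT{20000000 + j}", intervention_type=itype,
            name=name,
        ))
    rng.shuffle(records)
    return records, mentions


def write_interventions_csv(records: Sequence[InterventionRecord], path: str | Path) -> None:
    rows = [{"id": r.id, "nct_id": r.nct_id, "intervention_type": r.intervention_type,
             "name": r.name} for r in records]
    pd.DataFrame(rows, columns=INTERVENTION_COLUMNS).to_csv(path, index=False)


def write_gold_tsv(mentions: Sequence[Mention], path: str | Path) -> None:
    """Gold annotations TSV: mention text and pipe-separated concept ids."""
    rows = [{"text": m.text, "source_id": m.source_id, "gold_ids": "|".join(m.gold_ids)}
            for m in mentions]
    pd.DataFrame(rows, columns=["text", "source_id", "gold_ids"]).to_csv(
        path, sep="\t", index=False)


def read_gold_tsv(path: str | Path) -> list[Mention]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [Mention(text=r.text, source_id=r.source_id,
                    gold_ids=[g for g in r.gold_ids.split("|") if g])
            for r in frame.itertuples(index=False)]
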