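"""Reference vocabulary: concepts, label index, and the is-a hierarchy.

The normalization target space is a vaccine-branch slice of an OBO-style
ontology.  A :class:`Concept` carries a preferred label, synonyms, and is-a
parents; a :class:`VocabularyIndex` maps normalized label strings to the
concept ids that carry them (ambiguity is preserved — a label shared by two
concepts maps to both); an :class:`OntologyGraph` holds the is-a DAG used to
classify hierarchy-type normalization errors.

The primary on-disk format is a small TSV (see :func:`load_vocabulary`);
OWL as published on purl.obolibrary.org can be ingested when rdflib is
available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple

import networkx as nx
import pandas as pd

from ._text import normalize_label

logger = logging.getLogger(__name__)

VOCAB_COLUMNS = ["concept_id", "preferred_label", "synonyms", "parent_ids", "is_vaccine"]

RelationLabel = Literal[
    "identical",
    "parent_child",
    "sibling",
    "ancestor_descendant",
    "distant",
    "disconnected",
]


class VocabularyFormatError(ValueError):
    """Raised for malformed vocabulary files (missing columns, duplicate ids)."""


@dataclass(frozen=True)
class Concept:
    """One ontology entry.

    Parameters
    ----------
    concept_id : opaque identifier (e.g. a CURIE such as ``VO:0000001``).
    preferred_label : canonical human-readable name, non-empty.
    synonyms : alternative surface forms, possibly empty.
    parent_ids : is-a parents; empty for roots.
    is_vaccine : whether the term sits in the vaccine branch of the
        ontology.  Non-vaccine terms can be filtered at load time.
    """

    concept_id: str
    preferred_label: str
    synonyms: tuple[str, ...] = ()
    parent_ids: tuple[str, ...] = ()
    is_vaccine: bool = True

    def __post_init__(self) -> None:
        if not normalize_label(self.preferred_label):
            raise ValueError(f"concept {self.concept_id!r}: empty preferred label")

    @property
    def labels(self) -> tuple[str, ...]:
        """Preferred label followed by synonyms."""
        return (self.preferred_label, *self.synonyms)


@dataclass
class VocabularyIndex:
    """Concepts keyed by id plus a normalized-label -> concept-id map."""

    concepts: dict[str, Concept] = field(default_factory=dict)
    label_map: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def add(self, concept: Concept) -> None:
        if concept.concept_id in self.concepts:
            raise VocabularyFormatError(f"duplicate concept_id {concept.concept_id!r}")
        self.concepts[concept.concept_id] = concept
        for label in concept.labels:
            norm = normalize_label(label)
            if norm:
                self.label_map.setdefault(norm, set()).add(concept.concept_id)

    def lookup_label(self, label: str) -> set[str]:
        """Concept ids carrying this label (after normalization); empty set if none."""
        return set(self.label_map.get(normalize_label(label), set()))

    def graph(self) -> "OntologyGraph":
        return OntologyGraph.from_concepts(self.concepts.values())

    def to_tsv(self, path: str | Path) -> None:
        """Write the index in the TSV dialect accepted by :func:`load_vocabulary`."""
        rows = [
            {
                "concept_id": c.concept_id,
                "preferred_label": c.preferred_label,
                "synonyms": "|".join(c.synonyms),
                "parent_ids": "|".join(c.parent_ids),
                "is_vaccine": int(c.is_vaccine),
            }
            for c in self.concepts.values()
        ]
        pd.DataFrame(rows, columns=VOCAB_COLUMNS).to_csv(path, sep="\t", index=False)


class OntologyGraph:
    """Is-a DAG over vocabulary concepts (edges child -> parent)."""

    def __init__(self, edges: dict[str, set[str]], nodes: Iterable[str] = ()) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for child, parents in edges.items():
            for parent in parents:
                g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"is-a hierarchy contains a cycle: {cycle}")
        self._g = g
        self._und = g.to_undirected(as_view=True)

    @classmethod
    def from_concepts(cls, concepts: Iterable[Concept]) -> "OntologyGraph":
        concepts = list(concepts)
        known = {c.concept_id for c in concepts}
        edges: dict[str, set[str]] = {}
        for c in concepts:
            for p in c.parent_ids:
                if p not in known:
                    logger.warning(
                        "concept %s: parent %s not in vocabulary, dropped", c.concept_id, p
                    )
                    continue
                edges.setdefault(c.concept_id, set()).add(p)
        return cls(edges, nodes=known)

    def __contains__(self, node: str) -> bool:
        return node in self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def parents(self, node: str) -> set[str]:
        return set(self._g.successors(node))

    def _directed_distance(self, descendant: str, ancestor: str) -> int | None:
        """Shortest is-a path length descendant -> ancestor, or None."""
        try:
            return nx.shortest_path_length(self._g, descendant, ancestor)
        except nx.NetworkXNoPath:
            return None

    def undirected_distance(self, a: str, b: str) -> int | None:
        try:
            return nx.shortest_path_length(self._und, a, b)
        except nx.NetworkXNoPath:
            return None


class HierarchyRelation(NamedTuple):
    """Relation between a gold and a predicted concept in the is-a DAG.

    ``gold_is_ancestor`` is True/False for directed relations
    (parent_child, ancestor_descendant) and None otherwise, so parent vs
    child is recoverable without doubling the label set.
    """

    label: RelationLabel
    gold_is_ancestor: bool | None


def hierarchy_relation(graph: OntologyGraph, gold: str, predicted: str) -> HierarchyRelation:
    """Classify the is-a relation between a gold and a predicted concept.

    The cascade (first match wins) keeps the three hierarchy error
    subclasses mutually exclusive:

    - ``identical``: same concept.
    - ``parent_child``: directed is-a distance 1 in either direction.
    - ``ancestor_descendant``: directed distance exactly 2 in either
      direction (grandparent/grandchild).
    - ``sibling``: no directed path either way, but ≥1 shared immediate
      parent.
    - ``distant``: connected in the undirected graph at distance > 2
      ("spanning more than two levels").
    - ``disconnected``: everything else.
    """
    for node, role in ((gold, "gold"), (predicted, "predicted")):
        if node not in graph:
            raise KeyError(f"{role} concept {node!r} not in ontology graph")
    if gold == predicted:
        return HierarchyRelation("identical", None)

    up = graph._directed_distance(predicted, gold)  # gold is ancestor
    down = graph._directed_distance(gold, predicted)  # predicted is ancestor
    directed = min((d for d in (up, down) if d is not None), default=None)
    if directed == 1:
        return HierarchyRelation("parent_child", up == directed)
    if directed == 2:
        return HierarchyRelation("ancestor_descendant", up == directed)
    if directed is None and graph.parents(gold) & graph.parents(predicted):
        return HierarchyRelation("sibling", None)
    und = graph.undirected_distance(gold, predicted)
    if und is not None and und > 2:
        return HierarchyRelation("distant", None)
    return HierarchyRelation("disconnected", None)


def _split_multi(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    return tuple(s for s in str(cell).split("|") if s)


def load_vocabulary(path: str | Path, keep_only_vaccines: bool = False) -> VocabularyIndex:
    """Load a vocabulary TSV (or OWL) into a :class:`VocabularyIndex`.

    TSV columns: ``concept_id``, ``preferred_label``, ``synonyms``
    (pipe-separated), ``parent_ids`` (pipe-separated), ``is_vaccine`` (0/1).
    Files ending in ``.owl`` are parsed as OBO-style OWL.

    Parameters
    ----------
    keep_only_vaccines : drop rows with ``is_vaccine = 0``, mirroring the
        manual filtering of non-vaccine terms from the full ontology.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".owl":
        index = _load_owl(path)
    else:
        index = _load_tsv(path)
    if keep_only_vaccines:
        kept = VocabularyIndex()
        for c in index.concepts.values():
            if c.is_vaccine:
                kept.add(c)
        return kept
    return index


def _load_tsv(path: Path) -> VocabularyIndex:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VOCAB_COLUMNS if c not in frame.columns]
    if missing:
        raise VocabularyFormatError(f"{path}: missing required column(s) {missing}")
    index = VocabularyIndex()
    for row in frame.itertuples(index=False):
        index.add(
            Concept(
                concept_id=row.concept_id,
                preferred_label=row.preferred_label,
                synonyms=_split_multi(row.synonyms),
                parent_ids=_split_multi(row.parent_ids),
                is_vaccine=str(row.is_vaccine).strip() in {"1", "true", "True"},
            )
        )
    return index


# VO's vaccine branch root; terms outside it get is_vaccine=False on OWL load.
VACCINE_ROOT_IRI = "http://purl.obolibrary.org/obo/VO_0000001"


def _load_owl(path: Path, vaccine_root: str = VACCINE_ROOT_IRI) -> VocabularyIndex:
    """Parse OBO-style OWL: rdfs:label -> preferred label, exact synonyms,
    rdfs:subClassOf (named classes only) -> parents."""
    try:
        import rdflib
        from rdflib.namespace import OWL, RDF, RDFS
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("OWL ingestion requires rdflib (pip install vonorm[owl])") from exc

    exact_syn = rdflib.URIRef("http://www.geneontology.org/formats/oboInOwl#hasExactSynonym")
    g = rdflib.Graph()
    g.parse(path)

    def curie(iri: rdflib.URIRef) -> str:
        tail = str(iri).rsplit("/", 1)[-1]
        return tail.replace("_", ":", 1) if "_" in tail else tail

    parents: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    synonyms: dict[str, list[str]] = {}
    classes = [s for s in g.subjects(RDF.type, OWL.Class) if isinstance(s, rdflib.URIRef)]
    for cls in classes:
        cid = curie(cls)
        label = g.value(cls, RDFS.label)
        if label is None:
            continue
        labels[cid] = str(label)
        synonyms[cid] = sorted(str(s) for s in g.objects(cls, exact_syn))
        for sup in g.objects(cls, RDFS.subClassOf):
            if isinstance(sup, rdflib.URIRef):
                parents.setdefault(cid, set()).add(curie(sup))

    # vaccine branch = transitive subclasses of the vaccine root
    root_id = curie(rdflib.URIRef(vaccine_root))
    children: dict[str, set[str]] = {}
    for child, ps in parents.items():
        for p in ps:
            children.setdefault(p, set()).add(child)
    branch: set[str] = set()
    stack = [root_id]
    while stack:
        node = stack.pop()
        if node in branch:
            continue
        branch.add(node)
        stack.extend(children.get(node, ()))

    index = VocabularyIndex()
    for cid in sorted(labels):
        index.add(
            Concept(
                concept_id=cid,
                preferred_label=labels[cid],
                synonyms=tuple(synonyms.get(cid, ())),
                parent_ids=tuple(sorted(p for p in parents.get(cid, ()) if p in labels)),
                is_vaccine=cid in branch,
            )
        )
    return index


def apply_override_tsv(index: VocabularyIndex, path: str | Path) -> VocabularyIndex:
    """Apply a manual-curation override: TSV with concept_id, is_vaccine (0/1)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    flags = {r.concept_id: str(r.is_vaccine).strip() in {"1", "true", "True"}
             for r in frame.itertuples(index=False)}
    out = VocabularyIndex()
    for c in index.concepts.values():
        if c.concept_id in flags:
            c = Concept(c.concept_id, c.preferred_label, c.synonyms, c.parent_ids,
                        flags[c.concept_id])
        out.add(c)
    return out
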