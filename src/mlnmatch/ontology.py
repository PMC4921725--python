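"""In-memory ontology model and readers/writers.

An :class:`Ontology` holds named classes with human-readable labels plus the
three structural relations the matcher consumes: ``is_a`` (subsumption),
``part_of`` (partonomy) and ``disjointWith``.  Two serializations are
supported: OWL (RDF/XML, the format anatomy ontologies such as the adult
mouse anatomy and the NCI Thesaurus are published in) and a line-oriented
native text format convenient for fixtures and synthetic data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
from rdflib import Graph, Literal as RDFLiteral, Namespace, RDF, RDFS, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL

__all__ = [
    "OntologyClass",
    "Ontology",
    "Correspondence",
    "Alignment",
    "OntologyFormatError",
    "OntologyValidationError",
    "load_owl_ontology",
    "write_owl_ontology",
    "load_native_ontology",
    "write_native_ontology",
    "ancestors",
]

Relation = Literal["is_a", "part_of"]


class OntologyFormatError(ValueError):
    """A file could not be parsed in the expected serialization."""


class OntologyValidationError(ValueError):
    """Parsed input violates an ontology invariant (cycles, dangling ids...)."""


@dataclass(frozen=True)
class OntologyClass:
    """A named class: opaque id (e.g. an IRI fragment) plus its labels.

    Labels are kept verbatim; all normalization happens in the similarity
    module.  A class with no labels is allowed but can never enter a
    candidate correspondence.
    """

    id: str
    labels: tuple[str, ...] = ()


@dataclass
class Ontology:
    """Classes plus direct is_a / part_of edges and disjointness pairs.

    Edges are the *asserted* (direct) relations; transitive closure is
    available through :func:`ancestors`.  Disjointness is stored as unordered
    pairs because emptiness of an intersection is symmetric.
    """

    name: str
    classes: dict[str, OntologyClass] = field(default_factory=dict)
    sub_edges: set[tuple[str, str]] = field(default_factory=set)
    part_edges: set[tuple[str, str]] = field(default_factory=set)
    disjoint_pairs: set[frozenset[str]] = field(default_factory=set)

    def add_class(self, cid: str, labels: Iterable[str] = ()) -> None:
        if cid in self.classes:
            raise OntologyValidationError(f"duplicate class id {cid!r}")
        self.classes[cid] = OntologyClass(cid, tuple(labels))

    def validate(self) -> None:
        """Check referential closure, acyclicity and disjointness sanity."""
        for rel, edges in (("is_a", self.sub_edges), ("part_of", self.part_edges)):
            for a, b in edges:
                for cid in (a, b):
                    if cid not in self.classes:
                        raise OntologyValidationError(
                            f"{rel} edge ({a!r}, {b!r}) references unknown class {cid!r}"
                        )
            graph = nx.DiGraph(edges)
            if not nx.is_directed_acyclic_graph(graph):
                cycle = nx.find_cycle(graph)
                raise OntologyValidationError(f"cyclic {rel} hierarchy: {cycle}")
        for pair in self.disjoint_pairs:
            if len(pair) != 2:
                raise OntologyValidationError(f"class disjoint with itself: {set(pair)}")
            for cid in pair:
                if cid not in self.classes:
                    raise OntologyValidationError(
                        f"disjoint pair {set(pair)} references unknown class {cid!r}"
                    )

    def structural_key(self):
        """Hashable structural content, for equality across serializations."""
        return (
            {c.id: tuple(c.labels) for c in self.classes.values()},
            frozenset(self.sub_edges),
            frozenset(self.part_edges),
            frozenset(self.disjoint_pairs),
        )


@dataclass(frozen=True, order=True)
class Correspondence:
    """An equivalence correspondence between one class per ontology."""

    id1: str
    id2: str
    confidence: float = 1.0
    relation: str = "="


@dataclass
class Alignment:
    """A set of correspondences; 1:1 after MAP inference."""

    correspondences: set[Correspondence] = field(default_factory=set)

    def pairs(self) -> set[tuple[str, str]]:
        return {(c.id1, c.id2) for c in self.correspondences}

    def is_one_to_one(self) -> bool:
        ids1 = [c.id1 for c in self.correspondences]
        ids2 = [c.id2 for c in self.correspondences]
        return len(set(ids1)) == len(ids1) and len(set(ids2)) == len(ids2)

    def __len__(self) -> int:
        return len(self.correspondences)


# ---------------------------------------------------------------------------
# transitive closure


def ancestors(o: Ontology, relation: Relation, cid: str) -> set[str]:
    """Classes reachable from ``cid`` by following the relation's direct
    edges, excluding ``cid`` itself."""
    if cid not in o.classes:
        raise KeyError(f"unknown class id {cid!r} in ontology {o.name!r}")
    edges = o.sub_edges if relation == "is_a" else o.part_edges
    adj: dict[str, list[str]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
    seen: set[str] = set()
    stack = list(adj.get(cid, ()))
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        stack.extend(adj.get(node, ()))
    return seen


# ---------------------------------------------------------------------------
# native line-oriented format
#
#   class <id> <tab> <label>[|<label>...]
#   is_a <id> <id>
#   part_of <id> <id>
#   disjoint <id> <id>
#   # comment


def load_native_ontology(path: str | Path, name: str = "") -> Ontology:
    path = Path(path)
    onto = Ontology(name=name or path.stem)
    sub: list[tuple[str, str]] = []
    part: list[tuple[str, str]] = []
    dis: list[tuple[str, str]] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        kind, _, rest = line.partition(" ")
        if kind == "class":
            cid, _, labelpart = rest.partition("\t")
            cid = cid.strip()
            if not cid:
                raise OntologyFormatError(f"{path}:{lineno}: class line without id")
            labels = [l for l in labelpart.split("|") if l] if labelpart else []
            onto.add_class(cid, labels)
        elif kind in ("is_a", "part_of", "disjoint"):
            fields = rest.split()
            if len(fields) != 2:
                raise OntologyFormatError(
                    f"{path}:{lineno}: {kind} needs exactly two class ids, got {rest!r}"
                )
            {"is_a": sub, "part_of": part, "disjoint": dis}[kind].append(tuple(fields))
        else:
            raise OntologyFormatError(f"{path}:{lineno}: unknown directive {kind!r}")
    onto.sub_edges = set(sub)
    onto.part_edges = set(part)
    onto.disjoint_pairs = {frozenset(p) for p in dis}
    onto.validate()
    return onto


def write_native_ontology(o: Ontology, path: str | Path) -> None:
    lines = [f"# ontology {o.name}: {len(o.classes)} classes"]
    for cid in sorted(o.classes):
        cls = o.classes[cid]
        lines.append(f"class {cid}\t{'|'.join(cls.labels)}")
    for a, b in sorted(o.sub_edges):
        lines.append(f"is_a {a} {b}")
    for a, b in sorted(o.part_edges):
        lines.append(f"part_of {a} {b}")
    for pair in sorted(o.disjoint_pairs, key=sorted):
        a, b = sorted(pair)
        lines.append(f"disjoint {a} {b}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# OWL (RDF/XML)

#: default partonomy property, the OBO convention used by the OAEI anatomy files
DEFAULT_PART_OF = "part_of"


def _local_name(iri: URIRef) -> str:
    text = str(iri)
    if "#" in text:
        return text.rsplit("#", 1)[1]
    return text.rstrip("/").rsplit("/", 1)[-1]


def _is_part_of_property(prop: URIRef, part_of_property: str) -> bool:
    return str(prop) == part_of_property or _local_name(prop) == part_of_property


def load_owl_ontology(
    path: str | Path,
    part_of_property: str = DEFAULT_PART_OF,
    label_property: str | URIRef = RDFS.label,
    name: str = "",
) -> Ontology:
    """Load a named-class ontology from an RDF/XML OWL file.

    ``part_of`` edges are read from the OBO-in-OWL encoding: a subClassOf
    axiom whose object is an existential restriction (someValuesFrom) on a
    property whose IRI or local name equals ``part_of_property``.  Anonymous
    classes, property axioms and individuals are ignored; the matcher models
    class correspondences only.
    """
    path = Path(path)
    graph = Graph()
    try:
        graph.parse(str(path), format="xml")
    except Exception as exc:  # rdflib raises several parser exception types
        raise OntologyFormatError(f"cannot parse {path} as RDF/XML OWL: {exc}") from exc

    label_pred = URIRef(label_property) if not isinstance(label_property, URIRef) else label_property

    named = {s for s in graph.subjects(RDF.type, OWL.Class) if isinstance(s, URIRef)}
    onto = Ontology(name=name or path.stem)
    for iri in sorted(named):
        labels = sorted(
            str(lbl) for lbl in graph.objects(iri, label_pred) if isinstance(lbl, RDFLiteral)
        )
        onto.add_class(_local_name(iri), labels)

    for s, _, obj in graph.triples((None, RDFS.subClassOf, None)):
        if s not in named:
            continue
        if isinstance(obj, URIRef) and obj in named:
            onto.sub_edges.add((_local_name(s), _local_name(obj)))
        elif (obj, RDF.type, OWL.Restriction) in graph:
            prop = graph.value(obj, OWL.onProperty)
            filler = graph.value(obj, OWL.someValuesFrom)
            if (
                isinstance(prop, URIRef)
                and isinstance(filler, URIRef)
                and filler in named
                and _is_part_of_property(prop, part_of_property)
            ):
                onto.part_edges.add((_local_name(s), _local_name(filler)))

    for s, _, obj in graph.triples((None, OWL.disjointWith, None)):
        if s in named and obj in named and s != obj:
            onto.disjoint_pairs.add(frozenset({_local_name(s), _local_name(obj)}))
    for node in graph.subjects(RDF.type, OWL.AllDisjointClasses):
        members_node = graph.value(node, OWL.members)
        if members_node is None:
            continue
        members = [m for m in Collection(graph, members_node) if m in named]
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if a != b:
                    onto.disjoint_pairs.add(frozenset({_local_name(a), _local_name(b)}))

    onto.validate()
    return onto


#: namespace used when serializing synthetic ontologies to OWL
_SYNTH_NS = "http://mlnmatch.example.org/onto#"


def write_owl_ontology(o: Ontology, path: str | Path, part_of_property: str = DEFAULT_PART_OF) -> None:
    """Serialize to RDF/XML using the same conventions the loader reads."""
    graph = Graph()
    ns = Namespace(_SYNTH_NS)
    graph.bind("owl", OWL)
    if not re.fullmatch(r"https?://.*", part_of_property):
        part_of_property = str(ns[part_of_property])
    part_prop = URIRef(part_of_property)
    graph.add((part_prop, RDF.type, OWL.ObjectProperty))

    def iri(cid: str) -> URIRef:
        return ns[cid]

    for cid in sorted(o.classes):
        graph.add((iri(cid), RDF.type, OWL.Class))
        for label in o.classes[cid].labels:
            graph.add((iri(cid), RDFS.label, RDFLiteral(label)))
    for a, b in sorted(o.sub_edges):
        graph.add((iri(a), RDFS.subClassOf, iri(b)))
    for a, b in sorted(o.part_edges):
        from rdflib import BNode

        node = BNode()
        graph.add((node, RDF.type, OWL.Restriction))
        graph.add((node, OWL.onProperty, part_prop))
        graph.add((node, OWL.someValuesFrom, iri(b)))
        graph.add((iri(a), RDFS.subClassOf, node))
    for pair in sorted(o.disjoint_pairs, key=sorted):
        a, b = sorted(pair)
        graph.add((iri(a), OWL.disjointWith, iri(b)))
    graph.serialize(destination=str(path), format="xml")
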