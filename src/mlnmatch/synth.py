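"""Synthetic ontology pairs with known ground-truth alignments.

The generator emulates the shape of anatomy ontologies: an is_a tree with
multiple children per term, part_of cross-links (partonomy is pervasive in
anatomy vocabularies), sibling disjointness declared in only one of the two
ontologies (as in the human/mouse benchmark pair, where only the human
anatomy asserts disjointWith), and labels built from anatomical tokens.

The second ontology is a structural clone of the first with fresh ids,
labels perturbed by per-character edits, and a fraction of classes dropped.
The surviving original/clone pairs are the ground truth, which makes every
stage of the matcher testable end to end without external downloads.

What this does *not* emulate: the real ontologies' size, their multiple
inheritance, synonym lists, or vocabulary overlap between unrelated terms
beyond what random token collisions produce.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .ontology import Alignment, Correspondence, Ontology

__all__ = ["SynthParams", "generate_pair", "ANATOMY_TOKENS"]

#: token vocabulary for label phrases; anatomy-flavored so that Levenshtein
#: similarities spread over [0, 1] and near-miss bait pairs occur naturally
ANATOMY_TOKENS = (
    "artery", "vein", "capillary", "vessel", "vascular", "endothelium",
    "epithelium", "membrane", "muscle", "tendon", "ligament", "cartilage",
    "bone", "marrow", "joint", "skull", "vertebra", "rib", "sternum",
    "femur", "tibia", "tarsal", "carpal", "phalanx", "cortex", "medulla",
    "lobe", "lobule", "gland", "duct", "follicle", "mucosa", "serosa",
    "plexus", "ganglion", "nerve", "neuron", "axon", "dendrite", "spinal",
    "cranial", "thoracic", "lumbar", "cervical", "dorsal", "ventral",
    "lateral", "medial", "proximal", "distal", "anterior", "posterior",
    "superior", "inferior", "left", "right", "heart", "atrium", "ventricle",
    "aorta", "lung", "bronchus", "alveolus", "trachea", "larynx", "pharynx",
    "esophagus", "stomach", "intestine", "colon", "rectum", "liver",
    "hepatic", "pancreas", "spleen", "kidney", "renal", "ureter", "bladder",
    "urethra", "gonad", "ovary", "testis", "uterus", "placenta", "retina",
    "cornea", "iris", "lens", "cochlea", "tympanum", "dermis", "epidermis",
)

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class SynthParams:
    """Generator knobs; all rates are probabilities in [0, 1].

    ``is_a_branching`` is the mean number of children drawn per expanded
    node (Poisson), controlling tree width versus depth.
    """

    n_classes: int = 100
    is_a_branching: float = 2.5
    part_of_rate: float = 0.3
    disjoint_sibling_rate: float = 0.2
    label_mutation_rate: float = 0.05
    drop_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        for name in ("part_of_rate", "disjoint_sibling_rate", "label_mutation_rate", "drop_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


def _fresh_label(rng: random.Random, used: set[str]) -> str:
    """A 1-4 token phrase whose (already lowercase) form is unused."""
    while True:
        k = rng.choice((1, 2, 2, 3, 3, 4))
        tokens: list[str] = []
        while len(tokens) < k:
            tok = rng.choice(ANATOMY_TOKENS)
            if not tokens or tok != tokens[-1]:
                tokens.append(tok)
        label = " ".join(tokens)
        if label not in used:
            used.add(label)
            return label


def _mutate_label(rng: random.Random, label: str, rate: float) -> str:
    """Per-character substitute/insert/delete with equal probability."""
    if rate <= 0.0:
        return label
    out: list[str] = []
    for ch in label:
        if rng.random() < rate:
            op = rng.choice(("sub", "ins", "del"))
            if op == "sub":
                out.append(rng.choice(_ALPHABET))
            elif op == "ins":
                out.append(ch)
                out.append(rng.choice(_ALPHABET))
            # del: drop the character
        else:
            out.append(ch)
    mutated = "".join(out).strip()
    return mutated if mutated else label


def generate_pair(p: SynthParams) -> tuple[Ontology, Ontology, Alignment]:
    """Build (o1, o2, truth): ontology, perturbed clone, surviving pairs.

    Fully reproducible from ``p.seed``.  The clone preserves every is_a and
    part_of edge between surviving classes, so with zero mutation and zero
    drops the pair is structurally isomorphic with identical labels.
    """
    rng = random.Random(p.seed)
    n = p.n_classes
    ids1 = [f"a{i:04d}" for i in range(n)]

    # is_a tree by breadth-first expansion with Poisson children
    parent: dict[int, int] = {}
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    queue = [0]
    next_id = 1
    while next_id < n:
        node = queue.pop(0) if queue else rng.randrange(next_id)
        k = _poisson(rng, p.is_a_branching)
        for _ in range(k):
            if next_id >= n:
                break
            parent[next_id] = node
            children[node].append(next_id)
            queue.append(next_id)
            next_id += 1

    used_labels: set[str] = set()
    labels1 = [_fresh_label(rng, used_labels) for _ in range(n)]

    o1 = Ontology(name="O1")
    for i in range(n):
        o1.add_class(ids1[i], [labels1[i]])
    o1.sub_edges = {(ids1[i], ids1[parent[i]]) for i in parent}

    # part_of links point to earlier nodes, keeping the partonomy acyclic
    for i in range(1, n):
        if rng.random() < p.part_of_rate:
            target = rng.randrange(i)
            if target != parent.get(i):
                o1.part_edges.add((ids1[i], ids1[target]))

    # sibling disjointness in o1 only (the benchmark pair's asymmetry)
    for node in range(n):
        kids = children[node]
        for x in range(len(kids)):
            for y in range(x + 1, len(kids)):
                if rng.random() < p.disjoint_sibling_rate:
                    o1.disjoint_pairs.add(frozenset({ids1[kids[x]], ids1[kids[y]]}))

    # clone with fresh ids, label noise and drops
    survivors = [i for i in range(n) if rng.random() >= p.drop_rate]
    keep = set(survivors)
    ids2 = {i: f"b{i:04d}" for i in survivors}
    o2 = Ontology(name="O2")
    for i in survivors:
        o2.add_class(ids2[i], [_mutate_label(rng, labels1[i], p.label_mutation_rate)])
    o2.sub_edges = {
        (ids2[i], ids2[parent[i]]) for i in survivors if i in parent and parent[i] in keep
    }
    o2.part_edges = {
        (ids2[i], ids2[j])
        for (a, b) in o1.part_edges
        for i, j in [(int(a[1:]), int(b[1:]))]
        if i in keep and j in keep
    }

    o1.validate()
    o2.validate()
    truth = Alignment({Correspondence(ids1[i], ids2[i]) for i in survivors})
    return o1, o2, truth


def _poisson(rng: random.Random, lam: float) -> int:
    """Knuth's algorithm; lambda is small here so this is fast."""
    import math

    limit = math.exp(-lam)
    k, prod = 0, rng.random()
    while prod > limit:
        k += 1
        prod *= rng.random()
    return k
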