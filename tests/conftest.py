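import random

import pytest

from mlnmatch.grounding import GroundModel, HardConstraint, SoftConjunction, SoftImplication
from mlnmatch.ontology import Ontology
from mlnmatch.similarity import Candidate


def dp_levenshtein(s: str, t: str) -> int:
    """Independent full dynamic-programming edit distance (test oracle)."""
    prev = list(range(len(t) + 1))
    for i, cs in enumerate(s, 1):
        cur = [i]
        for j, ct in enumerate(t, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (cs != ct)))
        prev = cur
    return prev[-1]


def make_ontology(name, classes, sub=(), part=(), disjoint=()):
    """Compact ontology builder: classes is {id: label-or-label-list}."""
    o = Ontology(name=name)
    for cid, labels in classes.items():
        if isinstance(labels, str):
            labels = [labels]
        o.add_class(cid, labels)
    o.sub_edges = set(sub)
    o.part_edges = set(part)
    o.disjoint_pairs = {frozenset(p) for p in disjoint}
    o.validate()
    return o


def random_ground_model(rng: random.Random, n_vars: int) -> GroundModel:
    """Random well-formed ground model with mixed constraint/clause types."""
    keys = [(f"a{i}", f"b{rng.randrange(max(1, n_vars - 2))}") for i in range(n_vars)]
    keys = sorted(set(keys))
    cands = [Candidate(k[0], k[1], round(rng.uniform(0.65, 1.0), 3)) for k in keys]
    model = GroundModel(
        variables={c.key: c for c in cands},
        prior_terms={c.key: c.sigma for c in cands},
    )
    keys = sorted(model.variables)
    if len(keys) >= 2:
        for _ in range(rng.randrange(0, len(keys))):
            i, j = rng.sample(range(len(keys)), 2)
            kind = rng.choice(["mutual-exclusion", "conj", "impl"])
            if kind == "mutual-exclusion":
                model.hard_constraints.append(
                    HardConstraint("mutual-exclusion", (keys[i], keys[j]))
                )
            elif kind == "conj":
                model.soft_conjunctions.append(
                    SoftConjunction(keys[i], keys[j], -round(rng.uniform(0.0, 0.3), 3))
                )
            else:
                model.soft_implications.append(
                    SoftImplication(keys[i], keys[j], round(rng.uniform(0.0, 0.3), 3))
                )
        if rng.random() < 0.5:
            size = rng.randrange(2, min(4, len(keys)) + 1)
            model.hard_constraints.append(
                HardConstraint("at-most-one-row", tuple(rng.sample(keys, size)))
            )
    model.validate()
    return model


@pytest.fixture
def tiny_pair():
    """Two 4-class ontologies with a mix of structure and similar labels."""
    o1 = make_ontology(
        "O1",
        {"a1": "heart", "a2": "left ventricle", "a3": "aorta", "a4": "cardiac muscle"},
        sub=[("a2", "a1"), ("a3", "a1")],
        part=[("a4", "a1")],
        disjoint=[("a2", "a3")],
    )
    o2 = make_ontology(
        "O2",
        {"b1": "heart", "b2": "left ventricle", "b3": "aorta", "b4": "cardiac muscle"},
        sub=[("b2", "b1"), ("b3", "b1")],
        part=[("b4", "b1")],
    )
    return o1, o2
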