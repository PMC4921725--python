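"""A priori label similarity and candidate generation.

Candidate correspondences are the cross-ontology class pairs whose best
label pair reaches a normalized Levenshtein similarity of at least the
pruning threshold tau.  The similarity sigma doubles as the prior weight of
the candidate's decision variable in the ground model, so this module fixes
the exact normalization convention:

    sigma(l1, l2) = 1 - d(norm(l1), norm(l2)) / max(|norm(l1)|, |norm(l2)|)

with ``norm`` lower-casing, mapping underscores/hyphens to spaces and
collapsing whitespace.  Under this convention the anatomy label pair
"Vascular_Endothelium" / "blood vessel endothelium" has edit distance 11
over a longer length of 24, i.e. sigma = 13/24 = 0.54 to two decimals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import edlib

from .ontology import Ontology, OntologyClass

__all__ = [
    "Candidate",
    "normalize_label",
    "levenshtein_distance",
    "label_similarity",
    "class_similarity",
    "generate_candidates",
    "write_candidates_tsv",
]

_WS = re.compile(r"\s+")


@dataclass(frozen=True, order=True)
class Candidate:
    """A scored potential correspondence (class in O1, class in O2, sigma)."""

    id1: str
    id2: str
    sigma: float
    label1: str = ""
    label2: str = ""

    @property
    def key(self) -> tuple[str, str]:
        return (self.id1, self.id2)


def normalize_label(raw: str) -> str:
    """Lowercase, underscores/hyphens to spaces, collapse whitespace."""
    return _WS.sub(" ", raw.lower().replace("_", " ").replace("-", " ")).strip()


def levenshtein_distance(s: str, t: str) -> int:
    """Exact edit distance (unit-cost insert/delete/substitute)."""
    if not s:
        return len(t)
    if not t:
        return len(s)
    return edlib.align(s, t, mode="NW", task="distance")["editDistance"]


def label_similarity(l1: str, l2: str) -> float:
    """Normalized Levenshtein similarity in [0, 1] on normalized labels.

    Two empty normalized labels count as identical (similarity 1).
    """
    a, b = normalize_label(l1), normalize_label(l2)
    longer = max(len(a), len(b))
    if longer == 0:
        return 1.0
    return 1.0 - levenshtein_distance(a, b) / longer


def class_similarity(c1: OntologyClass, c2: OntologyClass) -> tuple[float, tuple[str, str]]:
    """Best label-pair similarity over the Cartesian product of labels.

    Returns ``(sigma, (label1, label2))``; ties break toward the
    lexicographically smallest label pair.  A class without labels yields
    sigma 0 — it can never become a candidate.
    """
    best_sigma = 0.0
    best_pair = ("", "")
    if not c1.labels or not c2.labels:
        return best_sigma, best_pair
    first = True
    for l1 in c1.labels:
        for l2 in c2.labels:
            sigma = label_similarity(l1, l2)
            if first or sigma > best_sigma or (sigma == best_sigma and (l1, l2) < best_pair):
                best_sigma, best_pair, first = sigma, (l1, l2), False
    return best_sigma, best_pair


def _min_possible_distance(len_a: int, len_b: int) -> int:
    return abs(len_a - len_b)


def generate_candidates(o1: Ontology, o2: Ontology, tau: float) -> list[Candidate]:
    """All cross-ontology class pairs with class similarity >= tau.

    The boundary is inclusive so tau = 1.0 acts as exact-normalized-label
    matching.  A length-gap prefilter skips label pairs whose lengths alone
    force sigma < tau; it is exactly output-preserving because the edit
    distance is bounded below by the length difference.

    Output is sorted by (id1, id2) for determinism.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    norm1 = {
        cid: [normalize_label(l) for l in cls.labels] for cid, cls in o1.classes.items()
    }
    norm2 = {
        cid: [normalize_label(l) for l in cls.labels] for cid, cls in o2.classes.items()
    }
    out: list[Candidate] = []
    for id1 in sorted(o1.classes):
        labels1 = o1.classes[id1].labels
        if not labels1:
            continue
        for id2 in sorted(o2.classes):
            labels2 = o2.classes[id2].labels
            if not labels2:
                continue
            best_sigma, best_pair, first = 0.0, ("", ""), True
            for l1, n1 in zip(labels1, norm1[id1]):
                for l2, n2 in zip(labels2, norm2[id2]):
                    longer = max(len(n1), len(n2))
                    if longer and 1.0 - _min_possible_distance(len(n1), len(n2)) / longer < tau:
                        continue  # cannot reach tau; safe to skip
                    sigma = 1.0 if longer == 0 else 1.0 - levenshtein_distance(n1, n2) / longer
                    if first or sigma > best_sigma or (
                        sigma == best_sigma and (l1, l2) < best_pair
                    ):
                        best_sigma, best_pair, first = sigma, (l1, l2), False
            if best_sigma >= tau:
                out.append(Candidate(id1, id2, best_sigma, *best_pair))
    return out


def write_candidates_tsv(candidates: Iterable[Candidate], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id1\tid2\tsigma\tlabel1\tlabel2\n")
        for c in sorted(candidates):
            fh.write(f"{c.id1}\t{c.id2}\t{c.sigma:.6f}\t{c.label1}\t{c.label2}\n")
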