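"""Grounding the matching formulas over a candidate set.

Five formula families turn two ontologies plus candidates into a ground
model over one binary decision variable per candidate (the hidden ``map``
atoms):

* **prior** — each candidate contributes its label similarity sigma to the
  objective when selected: the a priori confidence of the correspondence.
* **cardinality** (hard) — a class takes part in at most one correspondence
  on each side (1:1 alignment).
* **coherence** (hard) — a subclass pair in one ontology must not map onto a
  disjoint pair in the other; such a combination would make the merged
  ontology incoherent.
* **stability** (soft, weight <= 0) — selecting two candidates whose O1
  classes are in a subclass relation while their O2 classes are not (or
  vice versa) introduces new structural knowledge and is penalized.
* **propagation** (soft, weight >= 0) — if children match and their parents
  (by is_a, or wholes by part_of) are also candidates, selecting the parent
  pair on top of the child pair is rewarded; equivalently, matching the
  children without the parents costs the weight.

Hard families become linear constraints, soft families weighted clauses;
the MAP objective these induce is maximized exactly in
:mod:`mlnmatch.inference`.  Only candidate pairs appear as variables: map
atoms pruned by the similarity threshold are clamped false.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from .ontology import Ontology, ancestors
from .similarity import Candidate

__all__ = [
    "FAMILIES",
    "SETTINGS",
    "MatchConfig",
    "HardConstraint",
    "SoftConjunction",
    "SoftImplication",
    "GroundModel",
    "ground_prior",
    "ground_cardinality",
    "ground_coherence",
    "ground_stability",
    "ground_propagation",
    "ground_model",
]

FAMILIES = ("prior", "cardinality", "coherence", "stability", "propagation")

#: the five ablation settings: cumulative formula families
SETTINGS: dict[str, frozenset[str]] = {
    "prior": frozenset({"prior"}),
    "ca": frozenset({"prior", "cardinality"}),
    "ca+co": frozenset({"prior", "cardinality", "coherence"}),
    "ca+co+st": frozenset({"prior", "cardinality", "coherence", "stability"}),
    "ca+co+st+mp": frozenset(FAMILIES),
}


@dataclass(frozen=True)
class MatchConfig:
    """Threshold, soft-formula weights and enabled formula families.

    Defaults follow the matcher's reference configuration: tau = 0.8,
    stability weight -0.01, propagation weight +0.05, all families on.
    Coherence tests subsumption on the transitive closure (disjointness
    semantically propagates to subclasses); soft families use direct edges
    to avoid redundant penalty stacking along chains.  Both are flags.
    """

    tau: float = 0.8
    w_stability: float = -0.01
    w_propagation: float = 0.05
    enabled: frozenset[str] = frozenset(FAMILIES)
    use_transitive_sub_for_coherence: bool = True
    use_direct_sub_for_soft: bool = True

    def __post_init__(self) -> None:
        unknown = self.enabled - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown formula families: {sorted(unknown)}")
        if "prior" not in self.enabled:
            raise ValueError("the prior family is always enabled (objective would be empty)")
        if self.w_stability > 0:
            raise ValueError("stability weight must be <= 0")
        if self.w_propagation < 0:
            raise ValueError("propagation weight must be >= 0")

    @classmethod
    def for_setting(cls, setting: str, **kwargs) -> "MatchConfig":
        """Config for one of the named ablation settings."""
        if setting not in SETTINGS:
            raise ValueError(f"unknown setting {setting!r}; choose from {sorted(SETTINGS)}")
        return replace(cls(**kwargs), enabled=SETTINGS[setting])


Key = tuple[str, str]


@dataclass(frozen=True)
class HardConstraint:
    kind: Literal["at-most-one-row", "at-most-one-col", "mutual-exclusion"]
    variables: tuple[Key, ...]


@dataclass(frozen=True)
class SoftConjunction:
    """Reward ``weight`` (< 0: a penalty) when both variables are selected."""

    var_i: Key
    var_j: Key
    weight: float


@dataclass(frozen=True)
class SoftImplication:
    """Penalty ``weight`` (> 0) when antecedent is selected but consequent is not."""

    antecedent: Key
    consequent: Key
    weight: float


@dataclass
class GroundModel:
    """Binary variables, prior coefficients, hard constraints, soft clauses."""

    variables: dict[Key, Candidate] = field(default_factory=dict)
    prior_terms: dict[Key, float] = field(default_factory=dict)
    hard_constraints: list[HardConstraint] = field(default_factory=list)
    soft_conjunctions: list[SoftConjunction] = field(default_factory=list)
    soft_implications: list[SoftImplication] = field(default_factory=list)

    def validate(self) -> None:
        for hc in self.hard_constraints:
            for key in hc.variables:
                if key not in self.variables:
                    raise ValueError(f"hard constraint references unknown variable {key}")
            if hc.kind == "mutual-exclusion" and len(set(hc.variables)) != 2:
                raise ValueError(f"mutual exclusion needs two distinct variables: {hc}")
        for sc in self.soft_conjunctions:
            if sc.var_i == sc.var_j:
                raise ValueError(f"soft conjunction references one variable twice: {sc}")
            for key in (sc.var_i, sc.var_j):
                if key not in self.variables:
                    raise ValueError(f"soft conjunction references unknown variable {key}")
        for si in self.soft_implications:
            if si.antecedent == si.consequent:
                raise ValueError(f"soft implication references one variable twice: {si}")
            for key in (si.antecedent, si.consequent):
                if key not in self.variables:
                    raise ValueError(f"soft implication references unknown variable {key}")

    def dump(self) -> str:
        """Plain-text debug dump, stable ordering — diffable against oracles."""
        lines = []
        for key in sorted(self.variables):
            lines.append(f"var {key[0]} {key[1]} sigma={self.prior_terms.get(key, 0.0):.6f}")
        for hc in self.hard_constraints:
            vars_txt = " ".join(f"{a}:{b}" for a, b in hc.variables)
            lines.append(f"hard {hc.kind} {vars_txt}")
        for sc in self.soft_conjunctions:
            lines.append(
                f"soft-conj {sc.var_i[0]}:{sc.var_i[1]} {sc.var_j[0]}:{sc.var_j[1]} w={sc.weight}"
            )
        for si in self.soft_implications:
            lines.append(
                f"soft-impl {si.antecedent[0]}:{si.antecedent[1]} -> "
                f"{si.consequent[0]}:{si.consequent[1]} w={si.weight}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# per-family grounding


def ground_prior(candidates: Sequence[Candidate]) -> dict[Key, float]:
    """One objective coefficient per candidate: its sigma."""
    return {c.key: c.sigma for c in sorted(candidates)}


def ground_cardinality(candidates: Sequence[Candidate]) -> list[HardConstraint]:
    """At-most-one constraints per O1 class (row) and per O2 class (column).

    Singleton groups impose nothing and are omitted.
    """
    rows: dict[str, list[Key]] = {}
    cols: dict[str, list[Key]] = {}
    for c in sorted(candidates):
        rows.setdefault(c.id1, []).append(c.key)
        cols.setdefault(c.id2, []).append(c.key)
    out: list[HardConstraint] = []
    for id1 in sorted(rows):
        if len(rows[id1]) > 1:
            out.append(HardConstraint("at-most-one-row", tuple(rows[id1])))
    for id2 in sorted(cols):
        if len(cols[id2]) > 1:
            out.append(HardConstraint("at-most-one-col", tuple(cols[id2])))
    return out


def _sub_relation(o: Ontology, transitive: bool) -> set[tuple[str, str]]:
    if not transitive:
        return set(o.sub_edges)
    closure: set[tuple[str, str]] = set()
    for cid in o.classes:
        for anc in ancestors(o, "is_a", cid):
            closure.add((cid, anc))
    return closure


def ground_coherence(
    o1: Ontology,
    o2: Ontology,
    candidates: Sequence[Candidate],
    cfg: MatchConfig,
) -> list[HardConstraint]:
    """Mutual exclusions forbidding a subclass pair to map onto a disjoint pair.

    For candidates c = (a1, a2) and d = (b1, b2): exclude {c, d} whenever
    a1 is_a b1 while {a2, b2} are disjoint, or {a1, b1} are disjoint while
    a2 is_a b2.  If neither ontology declares disjointness the family
    grounds to nothing (the case for the mouse anatomy ontology).
    """
    sub1 = _sub_relation(o1, cfg.use_transitive_sub_for_coherence)
    sub2 = _sub_relation(o2, cfg.use_transitive_sub_for_coherence)
    cands = sorted(candidates)
    seen: set[frozenset[Key]] = set()
    out: list[HardConstraint] = []
    for c in cands:
        for d in cands:
            if c.key == d.key:
                continue
            a1, a2 = c.key
            b1, b2 = d.key
            violates = ((a1, b1) in sub1 and frozenset({a2, b2}) in o2.disjoint_pairs) or (
                frozenset({a1, b1}) in o1.disjoint_pairs and (a2, b2) in sub2
            )
            if violates:
                pair = frozenset({c.key, d.key})
                if pair not in seen:
                    seen.add(pair)
                    out.append(HardConstraint("mutual-exclusion", tuple(sorted(pair))))
    return out


def ground_stability(
    o1: Ontology,
    o2: Ontology,
    candidates: Sequence[Candidate],
    cfg: MatchConfig,
) -> list[SoftConjunction]:
    """Penalize candidate pairs whose selection asserts a subclass relation
    present in only one ontology.

    One grounding per direction: O1 has the edge and O2 does not, and the
    mirror image.  Both carry ``cfg.w_stability`` (<= 0).
    """
    sub1 = _sub_relation(o1, not cfg.use_direct_sub_for_soft)
    sub2 = _sub_relation(o2, not cfg.use_direct_sub_for_soft)
    cands = sorted(candidates)
    out: list[SoftConjunction] = []
    for c in cands:
        for d in cands:
            if c.key == d.key:
                continue
            a1, a2 = c.key
            b1, b2 = d.key
            o1_edge = (a1, b1) in sub1
            o2_edge = (a2, b2) in sub2
            if o1_edge != o2_edge:  # exactly one side has the edge
                out.append(SoftConjunction(c.key, d.key, cfg.w_stability))
    return out


def ground_propagation(
    o1: Ontology,
    o2: Ontology,
    candidates: Sequence[Candidate],
    cfg: MatchConfig,
) -> list[SoftImplication]:
    """Reward selecting the parent/whole pair when the child/part pair is
    selected and the structural edge exists on both sides.

    Implemented as a penalty on (child pair selected, parent pair not):
    is_a edges ground one implication, part_of edges another; a pair related
    by both grounds both (one per formula).
    """
    sub1 = _sub_relation(o1, not cfg.use_direct_sub_for_soft)
    sub2 = _sub_relation(o2, not cfg.use_direct_sub_for_soft)
    part1 = set(o1.part_edges)
    part2 = set(o2.part_edges)
    cands = sorted(candidates)
    out: list[SoftImplication] = []
    for c in cands:
        for d in cands:
            if c.key == d.key:
                continue
            a1, a2 = c.key
            b1, b2 = d.key
            if (a1, b1) in sub1 and (a2, b2) in sub2:
                out.append(SoftImplication(c.key, d.key, cfg.w_propagation))
            if (a1, b1) in part1 and (a2, b2) in part2:
                out.append(SoftImplication(c.key, d.key, cfg.w_propagation))
    return out


def ground_model(
    o1: Ontology,
    o2: Ontology,
    candidates: Iterable[Candidate],
    cfg: MatchConfig | None = None,
) -> GroundModel:
    """Union of the enabled families' groundings over the candidate variables."""
    cfg = cfg or MatchConfig()
    cands = sorted(candidates)
    model = GroundModel(variables={c.key: c for c in cands})
    model.prior_terms = ground_prior(cands)
    if "cardinality" in cfg.enabled:
        model.hard_constraints.extend(ground_cardinality(cands))
    if "coherence" in cfg.enabled:
        model.hard_constraints.extend(ground_coherence(o1, o2, cands, cfg))
    if "stability" in cfg.enabled and cfg.w_stability != 0.0:
        model.soft_conjunctions.extend(ground_stability(o1, o2, cands, cfg))
    if "propagation" in cfg.enabled and cfg.w_propagation != 0.0:
        model.soft_implications.extend(ground_propagation(o1, o2, cands, cfg))
    model.validate()
    return model
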