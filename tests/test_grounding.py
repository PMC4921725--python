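"""Formula grounding against independent quadratic brute-force scans."""

import random

import pytest

from mlnmatch.grounding import (
    MatchConfig,
    SETTINGS,
    ground_cardinality,
    ground_coherence,
    ground_model,
    ground_prior,
    ground_propagation,
    ground_stability,
)
from mlnmatch.ontology import ancestors
from mlnmatch.similarity import Candidate
from mlnmatch.synth import SynthParams, generate_pair

from conftest import make_ontology


def _sub_closure(o, transitive):
    if not transitive:
        return set(o.sub_edges)
    return {(c, a) for c in o.classes for a in ancestors(o, "is_a", c)}


def random_instance(seed, n_cands=15, n_classes=10):
    """Random ontology pair plus a random (not similarity-driven) candidate set."""
    rng = random.Random(seed)
    o1, o2, _ = generate_pair(
        SynthParams(n_classes=n_classes, disjoint_sibling_rate=0.5, seed=seed)
    )
    ids1, ids2 = sorted(o1.classes), sorted(o2.classes)
    keys = {(rng.choice(ids1), rng.choice(ids2)) for _ in range(n_cands)}
    cands = [Candidate(a, b, round(rng.uniform(0.65, 1.0), 3)) for a, b in sorted(keys)]
    return o1, o2, cands


class TestPrior:
    def test_coefficient_is_sigma(self):
        terms = ground_prior([Candidate("a", "b", 0.54)])
        assert terms == {("a", "b"): 0.54}

    def test_empty_and_counting(self):
        assert ground_prior([]) == {}
        cands = [Candidate(f"a{i}", f"b{i}", 0.9) for i in range(7)]
        assert len(ground_prior(cands)) == 7


class TestCardinality:
    def test_shared_row_yields_one_constraint(self):
        cands = [Candidate("a1", "a2", 0.9), Candidate("a1", "b2", 0.8)]
        cons = ground_cardinality(cands)
        assert len(cons) == 1
        assert cons[0].kind == "at-most-one-row"
        assert set(cons[0].variables) == {("a1", "a2"), ("a1", "b2")}

    def test_all_distinct_yields_nothing(self):
        cands = [Candidate(f"a{i}", f"b{i}", 0.9) for i in range(5)]
        assert ground_cardinality(cands) == []

    def test_k_sharing_one_class_arity_k(self):
        cands = [Candidate("a1", f"b{i}", 0.9) for i in range(4)]
        cons = ground_cardinality(cands)
        assert len(cons) == 1 and len(cons[0].variables) == 4


class TestCoherence:
    def test_no_disjointness_grounds_nothing(self):
        o1 = make_ontology("O1", {"a1": "x", "b1": "y"}, sub=[("a1", "b1")])
        o2 = make_ontology("O2", {"a2": "x", "b2": "y"}, sub=[("a2", "b2")])
        cands = [Candidate("a1", "a2", 0.9), Candidate("b1", "b2", 0.9)]
        assert ground_coherence(o1, o2, cands, MatchConfig()) == []

    def test_direct_instantiation(self):
        o1 = make_ontology("O1", {"a1": "x", "b1": "y"}, sub=[("a1", "b1")])
        o2 = make_ontology("O2", {"a2": "x", "b2": "y"}, disjoint=[("a2", "b2")])
        cands = [Candidate("a1", "a2", 0.9), Candidate("b1", "b2", 0.9)]
        cons = ground_coherence(o1, o2, cands, MatchConfig())
        assert len(cons) == 1
        assert set(cons[0].variables) == {("a1", "a2"), ("b1", "b2")}

    def test_transitive_vs_direct_flag(self):
        # a1 is_a m1 is_a b1: only the transitive closure sees (a1, b1)
        o1 = make_ontology(
            "O1", {"a1": "x", "m1": "m", "b1": "y"}, sub=[("a1", "m1"), ("m1", "b1")]
        )
        o2 = make_ontology("O2", {"a2": "x", "b2": "y"}, disjoint=[("a2", "b2")])
        cands = [Candidate("a1", "a2", 0.9), Candidate("b1", "b2", 0.9)]
        assert len(ground_coherence(o1, o2, cands, MatchConfig())) == 1
        cfg_direct = MatchConfig(use_transitive_sub_for_coherence=False)
        assert ground_coherence(o1, o2, cands, cfg_direct) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_scan(self, seed):
        o1, o2, cands = random_instance(seed)
        cfg = MatchConfig()
        got = {frozenset(c.variables) for c in ground_coherence(o1, o2, cands, cfg)}
        sub1 = _sub_closure(o1, True)
        sub2 = _sub_closure(o2, True)
        expected = set()
        for c in cands:
            for d in cands:
                if c.key == d.key:
                    continue
                a1, a2 = c.key
                b1, b2 = d.key
                if ((a1, b1) in sub1 and frozenset({a2, b2}) in o2.disjoint_pairs) or (
                    frozenset({a1, b1}) in o1.disjoint_pairs and (a2, b2) in sub2
                ):
                    expected.add(frozenset({c.key, d.key}))
        assert got == expected


class TestStability:
    def test_structural_disagreement_penalized(self):
        o1 = make_ontology("O1", {"a1": "x", "b1": "y"}, sub=[("a1", "b1")])
        o2 = make_ontology("O2", {"a2": "x", "b2": "y"})
        cands = [Candidate("a1", "a2", 0.9), Candidate("b1", "b2", 0.9)]
        scs = ground_stability(o1, o2, cands, MatchConfig())
        assert len(scs) == 1
        assert scs[0].weight == -0.01
        assert {scs[0].var_i, scs[0].var_j} == {("a1", "a2"), ("b1", "b2")}

    def test_isomorphic_hierarchies_ground_nothing(self):
        o1 = make_ontology("O1", {"a1": "x", "b1": "y"}, sub=[("a1", "b1")])
        o2 = make_ontology("O2", {"a2": "x", "b2": "y"}, sub=[("a2", "b2")])
        cands = [Candidate("a1", "a2", 0.9), Candidate("b1", "b2", 0.9)]
        assert ground_stability(o1, o2, cands, MatchConfig()) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_scan(self, seed):
        o1, o2, cands = random_instance(seed)
        cfg = MatchConfig()
        got = {(sc.var_i, sc.var_j) for sc in ground_stability(o1, o2, cands, cfg)}
        sub1, sub2 = set(o1.sub_edges), set(o2.sub_edges)
        expected = set()
        for c in cands:
            for d in cands:
                if c.key == d.key:
                    continue
                a1, a2 = c.key
                b1, b2 = d.key
                if ((a1, b1) in sub1) != ((a2, b2) in sub2):
                    expected.add((c.key, d.key))
        assert got == expected


class TestPropagation:
    def test_matched_edge_on_both_sides(self):
        o1 = make_ontology("O1", {"a1": "x", "b1": "y"}, sub=[("a1", "b1")])
        o2 = make_ontology("O2", {"a2": "x", "b2": "y"}, sub=[("a2", "b2")])
        cands = [Candidate("a1", "a2", 0.9), Candidate("b1", "b2", 0.9)]
        sis = ground_propagation(o1, o2, cands, MatchConfig())
        assert len(sis) == 1
        assert sis[0].weight == 0.05
        assert sis[0].antecedent == ("a1", "a2") and sis[0].consequent == ("b1", "b2")

    def test_no_edges_grounds_nothing(self):
        o1 = make_ontology("O1", {"a1": "x"})
        o2 = make_ontology("O2", {"a2": "x"})
        assert ground_propagation(o1, o2, [Candidate("a1", "a2", 1.0)], MatchConfig()) == []

    def test_sub_and_part_both_hold_two_groundings(self):
        o1 = make_ontology("O1", {"a1": "x", "b1": "y"}, sub=[("a1", "b1")], part=[("a1", "b1")])
        o2 = make_ontology("O2", {"a2": "x", "b2": "y"}, sub=[("a2", "b2")], part=[("a2", "b2")])
        cands = [Candidate("a1", "a2", 0.9), Candidate("b1", "b2", 0.9)]
        assert len(ground_propagation(o1, o2, cands, MatchConfig())) == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_scan(self, seed):
        o1, o2, cands = random_instance(seed)
        got = [
            (si.antecedent, si.consequent)
            for si in ground_propagation(o1, o2, cands, MatchConfig())
        ]
        expected = []
        for c in cands:
            for d in cands:
                if c.key == d.key:
                    continue
                a1, a2 = c.key
                b1, b2 = d.key
                if (a1, b1) in o1.sub_edges and (a2, b2) in o2.sub_edges:
                    expected.append((c.key, d.key))
                if (a1, b1) in o1.part_edges and (a2, b2) in o2.part_edges:
                    expected.append((c.key, d.key))
        assert sorted(got) == sorted(expected)


class TestGroundModel:
    def test_prior_only_ablation(self):
        o1, o2, cands = random_instance(1)
        model = ground_model(o1, o2, cands, MatchConfig.for_setting("prior"))
        assert len(model.prior_terms) == len(cands)
        assert model.hard_constraints == []
        assert model.soft_conjunctions == [] and model.soft_implications == []

    def test_full_setting_is_union_of_families(self):
        o1, o2, cands = random_instance(2)
        cfg = MatchConfig()
        model = ground_model(o1, o2, cands, cfg)
        assert len(model.hard_constraints) == len(ground_cardinality(cands)) + len(
            ground_coherence(o1, o2, cands, cfg)
        )
        assert model.soft_conjunctions == ground_stability(o1, o2, cands, cfg)
        assert model.soft_implications == ground_propagation(o1, o2, cands, cfg)

    def test_ablations_only_add_clauses(self):
        o1, o2, cands = random_instance(3)
        order = ["prior", "ca", "ca+co", "ca+co+st", "ca+co+st+mp"]
        prev_counts = (0, 0, 0)
        for setting in order:
            model = ground_model(o1, o2, cands, MatchConfig.for_setting(setting))
            counts = (
                len(model.hard_constraints),
                len(model.soft_conjunctions),
                len(model.soft_implications),
            )
            assert all(c >= p for c, p in zip(counts, prev_counts))
            prev_counts = counts

    def test_deterministic(self):
        o1, o2, cands = random_instance(4)
        m1 = ground_model(o1, o2, cands, MatchConfig())
        m2 = ground_model(o1, o2, list(reversed(cands)), MatchConfig())
        assert m1.dump() == m2.dump()

    def test_clauses_reference_only_candidates(self):
        o1, o2, cands = random_instance(5)
        model = ground_model(o1, o2, cands, MatchConfig())
        model.validate()  # raises on any foreign variable

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MatchConfig(w_stability=0.5)
        with pytest.raises(ValueError):
            MatchConfig(w_propagation=-0.5)
        with pytest.raises(ValueError):
            MatchConfig(enabled=frozenset({"cardinality"}))  # prior missing
        with pytest.raises(ValueError):
            MatchConfig.for_setting("bogus")
        assert SETTINGS["ca+co+st+mp"] == MatchConfig().enabled
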