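# Methods

## Problem and model

`mlnmatch` aligns two anatomy ontologies: it selects a one-to-one set of
equivalence correspondences between classes of ontology O1 (e.g. the NCI
Thesaurus human anatomy subset) and O2 (e.g. the adult mouse anatomy). The
model is a Markov logic network: weighted first-order formulas over
observed predicates describing the ontologies (`class_i`, `label_i`,
`sub_i` for is_a, `part_i` for part_of, `dis_i` for disjointness, and
`sim` for label similarity) and one hidden predicate `map(c1, c2)` per
potential correspondence. The output alignment is the MAP state of the
hidden atoms: the truth assignment maximizing the weighted sum of satisfied
ground formulas given the evidence.

Matching runs in three stages:

1. **Candidate pruning.** For every cross-ontology class pair, the a priori
   similarity sigma is the best normalized Levenshtein similarity over the
   two classes' label sets:
   `sigma = 1 - d(norm(l1), norm(l2)) / max(|norm(l1)|, |norm(l2)|)`,
   where `norm` lowercases, maps underscores and hyphens to spaces and
   collapses whitespace. Pairs with sigma below a threshold tau are pruned:
   their `map` atoms are clamped false and never become variables. This
   normalization is anchored by the worked anatomy pair
   "Vascular_Endothelium" / "blood vessel endothelium": edit distance 11
   over a longer normalized length of 24 gives sigma = 13/24 = 0.54 at two
   decimals. The threshold boundary is inclusive (`sigma >= tau`) so that
   tau = 1.0 degenerates to exact-normalized-label matching.

2. **Grounding.** Five formula families are instantiated over the candidate
   set (module `grounding`):
   - *prior*: selecting candidate c contributes `sigma_c` to the objective;
   - *cardinality* (hard): at most one selected candidate per O1 class and
     per O2 class;
   - *coherence* (hard): candidates (a1,a2) and (b1,b2) are mutually
     exclusive when a1 is a subclass of b1 while a2,b2 are disjoint, or
     symmetrically;
   - *stability* (soft, weight w_st <= 0): selecting (a1,a2) and (b1,b2)
     when the subclass edge a1->b1 exists in only one ontology incurs w_st
     — the alignment should not invent structural knowledge;
   - *propagation* (soft, weight w_mp >= 0): when the child/part pair is
     selected and the is_a (or part_of) edge exists on both sides, not
     selecting the parent/whole pair costs w_mp — confidence flows along
     shared structure. A candidate pair related by both is_a and part_of
     grounds one clause per relation.

3. **MAP inference.** The objective
   `sum sigma_c x_c + sum w_st x_i x_j - sum w_mp x_a (1 - x_c)`
   (constants from groundings whose truth is fixed by evidence are
   dropped; dropping them does not move the argmax) is maximized subject to
   the hard constraints, compiled to a mixed-integer linear program and
   solved exactly with HiGHS via `scipy.optimize.milp`.

## ILP compilation

Candidate variables are binary. Each stability conjunction introduces an
auxiliary y with `y >= x_i + x_j - 1`; since its objective coefficient
w_st is non-positive, minimization presses y onto `max(0, x_i + x_j - 1)`,
so y can stay continuous in [0,1] and is integral at every optimum. Each
propagation implication introduces a penalty p with `p >= x_a - x_c` and
objective `-w_mp * p`; the optimizer presses p onto `max(0, x_a - x_c)`.
At-most-one groups become `sum x <= 1`, mutual exclusions `x_i + x_j <= 1`.
The all-zero selection is always feasible, so the program is never
infeasible. On timeout (default limit 300 s) the best incumbent is
returned with status `"feasible"`; at the problem sizes exercised here the
solver always proves optimality in well under a second.

The reported objective of a solution is always *recomputed from scratch*
from the selection (`objective_value`), never read off the solver, and the
brute-force oracle (`brute_force_map`, exhaustive over <= 20 variables,
ties broken toward the lexicographically smallest selection) provides an
independent check: tests compare ILP and oracle objectives exactly (within
1e-9) on hundreds of random models. Equal-objective optima may differ in
selection between solvers; contracts are therefore stated on the objective
and on invariants, except where a unique optimum is forced.

## Parameters

| parameter | default | meaning |
|---|---|---|
| tau | 0.8 | similarity threshold for candidate pruning; 0.8 is where the full model peaks on F in threshold sweeps |
| w_stability | -0.01 | penalty per violated stability grounding |
| w_propagation | +0.05 | penalty per unsatisfied propagation grounding |
| enabled | all five | formula families; the named ablations are `prior`, `ca`, `ca+co`, `ca+co+st`, `ca+co+st+mp` |
| time_limit | 300 s | ILP budget |

Weights are set manually, not learned: training alignments are rarely
available, and learning from the reference alignment would overfit the
benchmark. The sign constraints (w_stability <= 0, w_propagation >= 0) are
enforced at construction.

Two open representation choices are exposed as flags with deliberate
defaults. Coherence tests subsumption on the *transitive closure*
(`use_transitive_sub_for_coherence=True`): disjointness semantically
propagates to all subclasses, and hard constraints should not depend on
how a chain happens to be asserted. The soft families use *direct* edges
(`use_direct_sub_for_soft=True`): grounding them on the closure would
stack redundant penalties along chains, effectively rescaling the weights
by chain length. The prior coefficient is sigma itself, not sigma minus
tau.

## Degenerate inputs and conventions

- A class with no labels never yields candidates (sentinel sigma 0).
- Two empty normalized labels count as identical (similarity 1).
- Formula groundings where the two candidate atoms coincide are skipped.
- Coherence mutual exclusions are deduplicated as unordered pairs;
  cardinality groups of size one are omitted.
- An empty computed alignment scores precision 0 (pessimistic convention;
  keeps F defined and equal to 0).
- Only equivalence cells of a reference alignment file are scored; other
  relations are skipped with a warning.
- Cyclic is_a/part_of inputs are rejected at load time with one offending
  cycle named; edges referencing undeclared classes are rejected.
- part_of participates only in propagation; stability and coherence are
  defined over is_a only.

## Synthetic data generator

`synth.generate_pair` builds O1 as a random is_a tree (breadth-first
expansion, Poisson(2.5) children per node), adds part_of links from a node
to a random earlier node with probability 0.3 (partonomy is pervasive in
anatomy ontologies), and declares random sibling pairs disjoint with
probability 0.2 — in O1 only, mirroring the benchmark asymmetry where only
the human anatomy ontology asserts disjointWith. Labels are unique 1-4
token phrases over an anatomy-flavored vocabulary, so Levenshtein
similarities spread over [0,1] and near-miss bait pairs (the
"Spiral_Artery" / "sural artery" failure mode) occur naturally. O2 is a
clone with fresh ids, per-character label edits
(substitute/insert/delete, rate 0.05 by default) and classes dropped with
probability 0.05; the surviving original/clone pairs are the ground truth.
Everything is reproducible from the seed.

The default noise rates (5% character edits, 5% drops) represent moderate
cross-species vocabulary drift: roughly one edit per label, keeping most
true pairs above tau = 0.8 while creating genuine ambiguity. What the
generator does **not** emulate: the real ontologies' size (thousands of
classes), multiple inheritance, synonym lists, or systematic (rather than
random) terminology differences between species. Passing recovery tests
therefore demonstrates correctness of the pipeline mechanics and the
qualitative value of the formula families, not benchmark-level accuracy on
the real mouse/human pair — for that the OWL files and reference alignment
can be supplied to the same entry points.

## Problem sizes in tests

The test suite exercises synthetic pairs of 30-150 classes, oracle
comparisons on 200+ random ground models of up to 15 candidates, and
exhaustive enumerations up to 20 variables; the full suite runs in well
under a minute. These sizes were chosen so every solver call can be
verified against an exhaustive or brute-force oracle; the pipeline itself
streams constraints sparsely and handles thousands of candidates.

## Known limitations

- Equal-objective MAP optima are solver-tie-broken; only the objective is
  contractual.
- The similarity scale reproduces the worked anatomy value, but other
  historical implementations may scale Levenshtein scores differently at
  the second decimal.
- No lexicon expansion (WordNet/UMLS): dissimilar synonym labels such as
  "Tarsal_Plate" / "eyelid tarsus" (sigma 0.08) are unreachable by the
  prior and recoverable only through structural propagation.
- Weight learning is out of scope; marginal probabilities per
  correspondence are not computed (MAP only).
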