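# mlnmatch

Anatomy ontology matching by MAP inference in a Markov logic network.

Anatomy ontologies — the adult mouse anatomy, the NCI Thesaurus human
anatomy, the zebrafish anatomy — standardize how experimental data such as
gene expression patterns are annotated. Comparing such data *between*
species requires an alignment: a set of equivalence correspondences
between classes of two ontologies. `mlnmatch` computes such alignments for
researchers and ontology engineers integrating model-organism data, and
reproduces a Markov-logic formulation of the task in which string
similarity and ontology structure are combined in one joint optimization.

## The model

Each cross-ontology class pair whose labels reach a normalized Levenshtein
similarity

    σ(l1, l2) = 1 − d(norm(l1), norm(l2)) / max(|norm(l1)|, |norm(l2)|) ≥ τ

becomes a candidate with one binary decision variable `map(c1, c2)`. Five
formula families define the ground Markov network over these variables:

| family | type | effect |
|---|---|---|
| a priori confidence | soft, weight σ | selecting a candidate earns its similarity |
| cardinality | hard | ≤ 1 correspondence per class on each side (1:1) |
| coherence | hard | a subclass pair must not map onto a disjoint pair |
| stability | soft, ω ≤ 0 (default −0.01) | penalize correspondences asserting a subclass edge present in only one ontology |
| match propagation | soft, ω ≥ 0 (default +0.05) | reward matching parents (is_a) / wholes (part_of) of matched classes |

The alignment is the MAP state

    max_y P(y | x) = max_y Σ_i ω_i n_i(x, y)

over the hidden `map` atoms y given the observed ontology structure x —
computed exactly by compiling the ground model to an integer linear
program (HiGHS via `scipy.optimize.milp`). Precision, recall and
F-measure (harmonic mean) score the result against a reference alignment.

## Worked example

`python examples/02_match_synthetic_pair.py` generates an anatomy-flavored
ontology of 100 classes, clones it with 5% per-character label noise and
5% dropped classes, matches the pair with the full formula set at τ = 0.8,
and prints:

    O1: 100 classes, 99 is_a, 22 part_of, 16 disjoint pairs
    O2 (noisy clone): 94 classes; truth: 94 pairs
    tau=0.8 enabled=cardinality+coherence+prior+propagation+stability
    candidates=94
    hard_constraints=0
    soft_conjunctions=0
    soft_implications=106
    solver_status=optimal objective=89.984078
    alignment_size=94
    precision=1.0000 recall=1.0000 f_measure=1.0000

The 94 candidates are the class pairs surviving the τ-pruning; 106
propagation implications reward structurally consistent selections; the
objective 89.98 is the sum of the 94 selected priors (each slightly below
1 because of label noise) with no soft penalties incurred; the MAP
alignment recovers the generated ground truth exactly.

The other examples show the similarity measure on published anatomy label
pairs (`01`), an ablation over the five formula settings where the 1:1
cardinality constraint lifts precision from 0.68 to 1.00 on a noisy pair
(`03`), and matching from OWL files (`04`).

A command-line interface wraps the same pipeline:

    mlnmatch synth --n-classes 100 --seed 1 --out-dir demo
    mlnmatch match demo/o1.native demo/o2.native --out demo/alignment.tsv \
        --reference demo/truth.tsv
    mlnmatch sweep demo/o1.native demo/o2.native demo/truth.tsv

`match` accepts the OAEI anatomy OWL files directly
(`--format owl --part-of-iri part_of`) together with the reference
alignment in Alignment-RDF format.

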