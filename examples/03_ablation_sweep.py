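"""Ablation study: how much each formula family contributes.

Matches one noisy synthetic pair under the five cumulative settings
(prior, ca, ca+co, ca+co+st, ca+co+st+mp) at two thresholds and prints the
precision/recall/F table.  Cardinality (the 1:1 constraint) typically gives
the largest jump in precision; the soft structural formulas refine choices
among conflicting candidates.
"""

from mlnmatch import (
    MatchConfig,
    SETTINGS,
    SynthParams,
    generate_pair,
    match_ontologies,
    score_alignment,
)

o1, o2, truth = generate_pair(
    SynthParams(n_classes=150, label_mutation_rate=0.2, drop_rate=0.1, seed=9)
)

print("tau   setting      P       R       F")
for tau in (0.5, 0.6):
    for setting in ("prior", "ca", "ca+co", "ca+co+st", "ca+co+st+mp"):
        cfg = MatchConfig.for_setting(setting, tau=tau)
        alignment, *_ = match_ontologies(o1, o2, cfg)
        r = score_alignment(alignment, truth)
        print(f"{tau:.2f}  {setting:<11}  {r.precision:.4f}  {r.recall:.4f}  {r.f_measure:.4f}")

print()
print("Lower tau admits more (noisier) candidates, so the hard and soft")
print("formulas matter more there; at high tau the candidate set is already")
print("nearly clean and the settings converge.")
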