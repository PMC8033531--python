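"""Classify disease status from cell-type proportions with a permutation null.

Cell-type composition alone separates ILD from control when a disease-only
state is present; label permutation shows the chance-level baseline.
"""

import fibroscope as fs

cfg = fs.SimulationConfig(disease_state_proportion=0.06, at2_depletion=0.3)
props, labels, _ = fs.simulate_proportions(cfg, seed=3, n_per_arm=20)

result = fs.disease_classifier_cv(
    props, labels, k=5, n_trees=200, n_permutations=10, seed=17
)
print(f"mean CV accuracy:        {result['mean_accuracy']:.2f}")
print(f"permuted-label accuracy: {result['permuted_accuracies'].mean():.2f}"
      f" (chance ≈ {result['majority_class_rate']:.2f})")
print("\ntop importances:")
print(result["importances"].head(3).round(3))
# High true-label accuracy with chance-level permuted accuracy means the
# composition signal is real; the disease-only state should dominate the
# feature importances.
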