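"""Detect confounding patients by four-classifier consensus.

A patient is a confounder when gradient-boosted trees, random forest, naive
Bayes and an SVM all misclassify it in a majority of 20 repeated 5-fold CV
rounds.  The generator's ground truth tells us how many planted label flips
the procedure recovered, and Cohen's-kappa maps show the classifiers agreeing
more once the confounders are removed.
"""

import numpy as np

from ide_ensemble import (
    GeneratorConfig,
    consensus_maps,
    generate_cohort,
    identify_confounders,
    impute_missing,
    label_endpoint,
    tally_misclassifications,
)
from ide_ensemble.cleanup import CLASSIFIERS

cohort = impute_missing(
    generate_cohort(GeneratorConfig(n_patients=600, seed=13, noise_rate=0.1))
)
ds = label_endpoint(cohort, 60)
flipped = set(cohort.ground_truth.flipped_ids) & set(ds.patient_ids.tolist())

tally = tally_misclassifications(ds, rounds=20, inner_k=5, seed=2, n_estimators=50)
partition = identify_confounders(tally)
found = set(partition.confounder_ids.tolist())

print(f"eligible patients: {len(ds)}, planted flips among them: {len(flipped)}")
print(f"confounders found: {len(found)}")
print(f"planted flips recovered: {len(found & flipped)} "
      f"({len(found & flipped) / len(flipped):.0%})")

before, after = consensus_maps(ds, partition, rounds=5, inner_k=5, seed=2,
                               n_estimators=50, tally=tally)
print(f"\nclassifiers: {CLASSIFIERS}")
print("pairwise kappa before cleaning:")
print(np.round(before.values, 2))
print("pairwise kappa after cleaning:")
print(np.round(after.values, 2))
print(f"mean off-diagonal kappa: {before.mean_off_diagonal():.3f} -> "
      f"{after.mean_off_diagonal():.3f}")
# The recovery rate shows the consensus rule finding the planted label noise;
# the rising mean kappa shows the remaining patients are more homogeneous.
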