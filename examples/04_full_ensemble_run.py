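"""Run the complete abstaining-ensemble experiment for the 5-year horizon.

Synthetic cohort -> imputation -> endpoint -> 10-fold outer CV; per fold:
confounder cleanup, three base models with nested shadow-feature selection;
then the quantile-anchored rule grid, the constrained grid search (median
"no answer" <= 25%) and the abstention-aware evaluation.  Takes a couple of
minutes on one CPU at the reduced "desk" sizes.
"""

import numpy as np

from ide_ensemble import PipelineConfig, run_pipeline

config = PipelineConfig.desk(seed=1, horizons=(60,))
results, manifest = run_pipeline(config)
res = results[60]

print("per-metric summary over the ten outer test folds (median [q1, q3]):")
for metric, row in res.summary.iterrows():
    print(f"  {metric:>12}: {row['median']:.3f}  [{row['q1']:.3f}, {row['q3']:.3f}]")

report = res.grid_report
print(f"\ngrid combinations evaluated: {report.n_combinations}"
      f" (feasible under the 25% budget: {int(report.feasible.sum())})")
print(f"selected combination's median abstention: "
      f"{report.median_abstain_pct[report.best_index]:.1f}%")
print(f"selected rule parameters: {res.params}")

print(f"\nensemble vs raw-data model, median AUC over folds: "
      f"{np.nanmedian(res.per_fold['auc']):.3f} vs "
      f"{np.median(res.per_fold['model1_auc']):.3f}")

print("\nexample decisions (one per rule branch where available):")
for rule in ("strong_consensus", "confounder_arbitration", "weak_consensus",
             "abstain"):
    hit = res.decisions[res.decisions["rule_fired"] == rule].head(1)
    for _, row in hit.iterrows():
        score = "-" if np.isnan(row["final_score"]) else f"{row['final_score']:.3f}"
        print(f"  patient {row['patient_id']:>4}  verdict {row['verdict']:>8}  "
              f"score {score:>6}  via {rule}")
# The ensemble answers ~75-80% of patients and its median AUC sits above the
# raw-data model's; each verdict names the rule branch that produced it.
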