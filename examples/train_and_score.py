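"""Train the random-forest classifier on a synthetic labeled cohort.

The generator plants the contrasts seen in real curated cohorts: pathogenic
variants carry longer, more hydrophobic, aggregation-prone extensions on
GC-richer 3'UTRs.  A forest trained on 620 variants (1:1 classes) is then
evaluated on an imbalanced held-out cohort (187 vs 371).
"""

import stopext as se

spec = se.CohortSpec(seed=7)
train_cohort = se.gen_labeled_cohort(spec)
test_cohort = se.gen_labeled_cohort(spec.test_set())

model = se.train(train_cohort.features, train_cohort.labels, seed=7)
print(f"hyperparameters: {model.hyperparams}")
print(f"5-fold CV AUROC (training cohort): {model.cv_auroc:.3f}")

scores = se.predict(model, test_cohort.features)
metrics = se.evaluate(scores, test_cohort.labels)
print(f"held-out AUROC {metrics['auroc']:.3f}, AUPRC {metrics['auprc']:.3f}")

print("\ntop 5 features by normalized Gini importance:")
print(se.importance(model).head(5).to_string(index=False))
print("\nHigh AUROC reflects the planted class separation; the top features "
      "should include the planted extension-length/hydrophobicity signals.")
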