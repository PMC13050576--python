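"""Leakage-safe preprocessing: encode, impute, split, scale, SMOTE.

Shows the fixed pipeline order and the class counts before and after
SMOTE rebalancing of the training partition (the test partition keeps the
natural imbalance).
"""

from gdmrisk import GeneratorConfig, generate_cohort, prepare

cohort = generate_cohort(GeneratorConfig(n_patients=10_000, seed=42))
balanced_train, test, split = prepare(cohort, train_fraction=0.8, split_seed=42)

print(f"cohort: {len(cohort)} rows, {cohort['gdm'].mean():.1%} GDM-positive")
print(f"split (seed 42): train {len(split.train.values)}, test {len(test.values)}")
print(f"train class counts pre-SMOTE:  {split.train.labels.value_counts().to_dict()}")
print(f"train class counts post-SMOTE: {balanced_train.labels.value_counts().to_dict()}")
print(f"test class counts (untouched): {test.labels.value_counts().to_dict()}")
print()
mean, sd = split.train.scaling_params["hba1c"]
print(f"HbA1c standardized with train-only moments: mean {mean:.3f}%, SD {sd:.3f}%")
print("-> scaling parameters are fitted exclusively on the training rows, so no")
print("   test-set information leaks into the transformation.")
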