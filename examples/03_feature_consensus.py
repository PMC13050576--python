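"""Seven-method consensus feature importance.

Each method's raw importances are min-max normalized; the consensus table
averages them and reports the cross-method rank standard deviation (low
rank SD = the methods agree on where the feature sits).
"""

from gdmrisk import GeneratorConfig, generate_cohort, prepare
from gdmrisk.select import compute_all_importances, consensus_rank, select_top_k

cohort = generate_cohort(GeneratorConfig(n_patients=10_000, seed=42))
balanced_train, _, _ = prepare(cohort)

vectors = compute_all_importances(balanced_train, seed=42)
table = consensus_rank(vectors)

print(table[["feature", "average", "rank_sd"]].head(10).to_string(index=False))
print()
print("top-3 consensus predictors:", ", ".join(select_top_k(table, 3)))
print("-> glycaemic exposure (HbA1c) and adiposity (BMI) dominate; maternal age")
print("   and family history contest the third slot because their effect sizes")
print("   are nearly identical under this operationalization.")
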