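"""Additive per-feature attribution for one trained model.

A background sample of test rows anchors the expected prediction; each
explained instance's prediction is decomposed into additive per-feature
contributions (Shapley values, kernel-estimated). Writes convenience
beeswarm-style importance and waterfall plots next to the script.
"""

from gdmrisk import GeneratorConfig, generate_cohort, prepare
from gdmrisk.bench import default_model_specs, tune_and_train
from gdmrisk.explain import attribute, global_importance, sample_explain_sets, waterfall
from gdmrisk.plots import plot_global_importance, plot_waterfall

cohort = generate_cohort(GeneratorConfig(n_patients=4_000, seed=42))
balanced_train, test, _ = prepare(cohort)

model, _ = tune_and_train(
    default_model_specs(seed=42, tuned=False, models=("mlp",))[0], balanced_train
)

background, instances, labels = sample_explain_sets(
    test, n_background=100, n_explain=50, seed=42
)
attributions = attribute(model, background, instances, n_coalitions=1024, seed=42)

print(f"baseline expected prediction over background: {attributions.base_value:.3f}")
print(f"max additivity gap over 50 instances: {attributions.additivity_gap().max():.2e}")
print()
print("global importance (mean |contribution|):")
print(global_importance(attributions).head(8).round(4).to_string(index=False))
print()
ledger = waterfall(attributions, instance=0)
print("waterfall for instance 0 (largest contributions first):")
print(ledger.head(6).round(3).to_string(index=False))
print(f"final prediction: {attributions.predictions[0]:.3f} "
      f"(= base {attributions.base_value:.3f} + sum of contributions)")

plot_global_importance(attributions, "shap_importance.png")
plot_waterfall(attributions, "waterfall.png", instance=0)
print("\nwrote shap_importance.png and waterfall.png")
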