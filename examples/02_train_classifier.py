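"""Train the skip-concatenation CNN-LSTM on synthetic data and score it.

Simulates a small cohort, windows it into 1 s examples, splits 70/30,
trains the full model for a short run and prints the evaluation report.
Takes about half a minute.
"""

from gaitphase import (
    ModelConfig,
    TrainConfig,
    build_examples_cohort,
    build_model,
    evaluate,
    predict_class,
    simulate_cohort,
    split_train_test,
    train,
)

recs = simulate_cohort(speed=1.0, n_subjects=2, duration_s=30.0, seed=7)
examples = build_examples_cohort(recs)
train_set, test_set = split_train_test(examples)
print(f"{len(train_set)} training / {len(test_set)} test examples "
      f"(windows of {examples.spec.span} samples, labeled at the last sample)")

model = build_model("fmsnet", ModelConfig(seed=0))
print(f"fmsnet: {model.n_params()} parameters, "
      f"conv feature maps {model.conv_shapes()[1:]}")

result = train(model, train_set, TrainConfig(iterations=800, seed=0))
print(f"cross-entropy: {result.initial_loss:.3f} -> {result.final_loss:.3f} "
      f"(chance level is ln 4 = 1.386)")

probs = model.predict_proba(test_set)
report = evaluate(test_set.labels, predict_class(probs), probs)
print()
print(report.to_text())

# Per-class rows give one-vs-rest precision/recall/F1 in percent; macro-F1
# is the harmonic mean of macro-averaged precision and recall; macro-AUC
# averages the four one-vs-rest ROC areas.  Heel strike (HS), the shortest
# phase, is typically the weakest row.
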