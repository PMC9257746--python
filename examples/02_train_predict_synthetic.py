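"""Fit a PLS-DA model on a synthetic screen and plot its score space.

Generates a 60-pair two-class descriptor screen, fits a two-latent-
variable PLS-DA model, reports leave-one-out accuracy, and writes the
LV1/LV2 score plot with the decision boundary to example_output/.
"""

from pathlib import Path

from coamscreen import (
    SyntheticConfig,
    decision_boundary_lv,
    evaluate_screen,
    export_score_plot,
    feature_matrix,
    generate_training_screen,
    leave_one_out_accuracy,
    nipals_fit,
)

out = Path("example_output")
out.mkdir(exist_ok=True)

config = SyntheticConfig(n_pairs=60, seed=1)
screen = generate_training_screen(config)
X = feature_matrix(screen)
y = screen.experimental_labels()

model = nipals_fit(X, y, n_components=2)
model.save(out / "model.json")

preds = model.predict_matrix(X)
result = evaluate_screen(screen, preds)
loo = leave_one_out_accuracy(X, y)
print(f"training fit: {result.confusion.correct}/{result.n} correct "
      f"({result.accuracy_percent}%)")
print(f"leave-one-out accuracy: {loo:.3f}")

line = decision_boundary_lv(model)
if line.vertical:
    print(f"decision boundary: LV1 = {line.x0:.3f}")
else:
    print(f"decision boundary: LV2 = {line.intercept:.3f} + {line.slope:.3f} * LV1")

export_score_plot(
    [p.scores for p in preds],
    y,
    list(result.per_pair_agreement),
    line,
    out / "score_plot.svg",
)
print(f"score plot written to {out / 'score_plot.svg'}")

# The continuous COAM value is the regression response on the 0/1 class
# coding; pairs at or above 0.5 are called coamorphous. In score space
# the same rule is the dashed line on the plot.
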