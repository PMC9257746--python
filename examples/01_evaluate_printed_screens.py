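"""Evaluate the two packaged bisVCap screening tables.

Loads the seven-system comelt screen (labels only) and the
thirteen-system predictive screen (continuous COAM values), scores the
recorded predictions against the experimental outcomes and prints the
agreement statistics.
"""

from coamscreen import (
    OutcomeLabel,
    evaluate_screen,
    fixture_new_screen,
    fixture_prior_screen,
    predictions_from_printed,
)

for name, screen in (
    ("prior comelt screen", fixture_prior_screen()),
    ("predictive screen", fixture_new_screen()),
):
    preds = predictions_from_printed(screen, threshold=0.5)
    result = evaluate_screen(screen, preds)
    n_coam = sum(p.predicted_class is OutcomeLabel.COAM for p in preds)
    print(f"{name}: n={result.n}")
    print(f"  predicted COAM: {n_coam}")
    print(f"  correct: {result.confusion.correct}/{result.n}"
          f" -> accuracy {result.accuracy_percent}%")
    print(f"  one-sided Fisher p = {result.fisher_p:.4f}")
    print(f"  confusion (tp,fp,fn,tn) = ({result.confusion.tp},{result.confusion.fp},"
          f"{result.confusion.fn},{result.confusion.tn})")

# The accuracy is the fraction of systems whose predicted class matched
# the melt-quench outcome (decomposed systems count as not-COAM); the
# Fisher probability asks how likely an association at least this strong
# is under random label assignment with the same margins.
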