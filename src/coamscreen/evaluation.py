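"""Agreement statistics and score plots for a COAM screen.

A screen is scored by cross-tabulating predicted against experimental
outcomes (predicted COAM is the positive row), reporting the integer
accuracy percentage and a one-sided Fisher exact probability for
positive association.  Systems that decomposed on melting count as
experimentally not-COAM by default (a decomposed melt cannot be a
single-phase amorphous product), or can be excluded instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .errors import ContractError, DimensionalityError, DomainError, EvaluationError
from .plsda import BoundaryLine, LatentScores, PredictionResult, classify
from .records import OutcomeLabel, ScreenTable

#: How decomposed-on-melting outcomes enter the agreement statistics.
DECOMPOSED_AS_NOT_COAM = "as_not_coam"
DECOMPOSED_EXCLUDE = "exclude"


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-tabulation; predicted COAM is the positive row."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DomainError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def correct(self) -> int:
        return self.tp + self.tn


@dataclass(frozen=True)
class ScreenEvaluation:
    """Aggregate agreement statistics for one screen."""

    confusion: ConfusionTable
    n: int
    accuracy_percent: int
    fisher_p: float
    fisher_degenerate: bool
    per_pair_agreement: tuple[bool, ...]
    excluded: tuple[str, ...] = ()


def _effective_label(label: OutcomeLabel, decomposed_policy: str) -> Optional[OutcomeLabel]:
    if label is OutcomeLabel.UNKNOWN:
        raise EvaluationError("pair with UNKNOWN experimental outcome must be excluded upstream")
    if label is OutcomeLabel.DECOMPOSED:
        if decomposed_policy == DECOMPOSED_AS_NOT_COAM:
            return OutcomeLabel.NOT_COAM
        if decomposed_policy == DECOMPOSED_EXCLUDE:
            return None
        raise DomainError(f"unknown decomposed policy '{decomposed_policy}'")
    return label


def agreement_flag(
    predicted: OutcomeLabel,
    experimental: OutcomeLabel,
    decomposed_policy: str = DECOMPOSED_AS_NOT_COAM,
) -> bool:
    """Whether a prediction counts as correct for one pair."""
    eff = _effective_label(experimental, decomposed_policy)
    if eff is None:
        raise EvaluationError("decomposed pair excluded; no agreement flag defined")
    return predicted is eff


def confusion_table(
    predicted: Sequence[OutcomeLabel],
    experimental: Sequence[OutcomeLabel],
    decomposed_policy: str = DECOMPOSED_AS_NOT_COAM,
) -> ConfusionTable:
    """Cross-tabulate predicted vs experimental outcomes.

    DECOMPOSED experimental outcomes map to NOT_COAM under the default
    policy; under the exclude policy those pairs are dropped.
    """
    if len(predicted) != len(experimental):
        raise ContractError(
            f"{len(predicted)} predictions for {len(experimental)} experimental labels"
        )
    tp = fp = fn = tn = 0
    for pred, exp in zip(predicted, experimental):
        eff = _effective_label(exp, decomposed_policy)
        if eff is None:
            continue
        if pred is OutcomeLabel.COAM:
            tp += eff is OutcomeLabel.COAM
            fp += eff is OutcomeLabel.NOT_COAM
        elif pred is OutcomeLabel.NOT_COAM:
            fn += eff is OutcomeLabel.COAM
            tn += eff is OutcomeLabel.NOT_COAM
        else:
            raise EvaluationError(f"predicted label must be COAM or NOT_COAM, got {pred}")
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def accuracy_percent(confusion: ConfusionTable) -> int:
    """Integer accuracy percentage, rounded half away from zero.

    5/7 correct gives 71; 11/13 gives 85.  Computed with exact rational
    arithmetic so ties never depend on binary rounding.
    """
    if confusion.total == 0:
        raise DomainError("accuracy undefined for an empty confusion table")
    pct = Fraction(100 * confusion.correct, confusion.total)
    return int(math.floor(pct + Fraction(1, 2)))


def fisher_one_sided(confusion: ConfusionTable) -> tuple[float, bool]:
    """One-sided Fisher exact probability of positive association.

    The tail sum of hypergeometric probabilities of tables at least as
    extreme as observed, holding both margins fixed.  Degenerate margins
    (an all-zero row or column) return 1 with the degenerate flag set.
    """
    if confusion.total == 0:
        raise DomainError("Fisher probability undefined for an empty table")
    row1 = confusion.tp + confusion.fp
    col1 = confusion.tp + confusion.fn
    degenerate = (
        row1 == 0 or col1 == 0 or row1 == confusion.total or col1 == confusion.total
    )
    if degenerate:
        return 1.0, True
    result = stats.fisher_exact(
        [[confusion.tp, confusion.fp], [confusion.fn, confusion.tn]], alternative="greater"
    )
    return float(result.pvalue), False


def evaluate_screen(
    table: ScreenTable,
    predictions: Sequence[PredictionResult],
    decomposed_policy: str = DECOMPOSED_AS_NOT_COAM,
) -> ScreenEvaluation:
    """Score a screen's predictions against its experimental outcomes.

    Per-pair agreement flags follow the input order; under the exclude
    policy decomposed pairs appear in ``excluded`` and not in the flags.
    """
    if len(predictions) != len(table.pairs):
        raise ContractError(
            f"{len(predictions)} predictions for {len(table.pairs)} pairs"
        )
    predicted, experimental, flags, excluded = [], [], [], []
    for pair, pred in zip(table.pairs, predictions):
        eff = _effective_label(pair.experimental_label, decomposed_policy)
        if eff is None:
            excluded.append(pair.display_label)
            continue
        predicted.append(pred.predicted_class)
        experimental.append(eff)
        flags.append(pred.predicted_class is eff)
    conf = confusion_table(predicted, experimental)
    p, degenerate = fisher_one_sided(conf)
    return ScreenEvaluation(
        confusion=conf,
        n=conf.total,
        accuracy_percent=accuracy_percent(conf),
        fisher_p=p,
        fisher_degenerate=degenerate,
        per_pair_agreement=tuple(flags),
        excluded=tuple(excluded),
    )


def predictions_from_printed(
    table: ScreenTable, threshold: float = 0.5
) -> list[PredictionResult]:
    """Predictions from externally supplied (printed) COAM values/labels.

    Pairs carrying a continuous ``coam_value`` are classified at the
    threshold; label-only pairs use their recorded predicted label.
    """
    preds = []
    for pair in table.pairs:
        if pair.coam_value is not None:
            preds.append(
                PredictionResult(
                    coam_value=pair.coam_value,
                    predicted_class=classify(pair.coam_value, threshold),
                )
            )
        elif pair.predicted_label is not None:
            preds.append(PredictionResult(coam_value=None, predicted_class=pair.predicted_label))
        else:
            raise EvaluationError(
                f"pair {pair.display_label} carries neither a COAM value nor a predicted label"
            )
    return preds


def export_score_plot(
    scores: Sequence[LatentScores],
    labels: Sequence[OutcomeLabel],
    agreement: Sequence[bool],
    boundary: Optional[BoundaryLine],
    path: Union[str, Path],
    annotations: Optional[Sequence[str]] = None,
) -> None:
    """Write the LV1/LV2 score scatter plot to a vector-format file.

    Experimentally COAM systems plot green, not-COAM (incl. decomposed)
    red; incorrectly predicted systems are hollow; the separation line
    is dashed blue.
    """
    if not (len(scores) == len(labels) == len(agreement)):
        raise ContractError("scores, labels and agreement flags must have equal lengths")
    for s in scores:
        if len(s) < 2:
            raise DimensionalityError("score plot needs at least 2 latent variables per point")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    for i, (s, lab, ok) in enumerate(zip(scores, labels, agreement)):
        color = "green" if lab is OutcomeLabel.COAM else "red"
        face = color if ok else "none"
        ax.scatter(s.lv[0], s.lv[1], s=55, facecolors=face, edgecolors=color, zorder=3)
        if annotations is not None:
            ax.annotate(annotations[i], (s.lv[0], s.lv[1]), fontsize=7,
                        xytext=(4, 4), textcoords="offset points")
    if boundary is not None and len(scores) > 0:
        xs = np.array([s.lv[0] for s in scores])
        ys = np.array([s.lv[1] for s in scores])
        x_lo, x_hi = _padded(xs)
        y_lo, y_hi = _padded(ys)
        if boundary.vertical:
            ax.plot([boundary.x0, boundary.x0], [y_lo, y_hi], "b--", zorder=2)
        else:
            grid = np.linspace(x_lo, x_hi, 50)
            ax.plot(grid, boundary.intercept + boundary.slope * grid, "b--", zorder=2)
        ax.set_xlim(x_lo, x_hi)
        ax.set_ylim(y_lo, y_hi)
    ax.set_xlabel("LV1")
    ax.set_ylabel("LV2")
    ax.set_title("PLS-DA score plot")
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)


def _padded(v: np.ndarray, frac: float = 0.15) -> tuple[float, float]:
    lo, hi = float(v.min()), float(v.max())
    pad = (hi - lo) * frac or 1.0
    return lo - pad, hi + pad
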