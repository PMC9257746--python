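"""From-scratch PLS-DA (partial least squares - discriminant analysis).

The classifier regresses a coded class membership (not COAM -> 0,
COAM -> 1) on the autoscaled pair descriptors with NIPALS latent
variables, yielding a continuous "COAM value" that is thresholded
(default 0.5, inclusive) into a class.  Score pairs (LV1, LV2) define
the familiar 2-D score plot, and the locus where the reconstructed
response equals the threshold is the plotted separation line.

Algorithm
---------
X is mean-centred and scaled to unit sample variance (features carry
heterogeneous units); y is mean-centred.  With a univariate response the
NIPALS inner loop collapses to a closed form per latent variable ``a``::

    w_a = E'f / ||E'f||      (unit-norm weight)
    t_a = E w_a              (score)
    p_a = E't_a / t_a't_a    (X loading)
    q_a = f't_a / t_a't_a    (y loading)
    E  <- E - t_a p_a' ;  f <- f - q_a t_a     (deflation)

The regression vector is ``b = W (P'W)^{-1} q`` and a prediction is
``ŷ = ȳ + x_scaled · b``, which equals ``ȳ + Σ_a q_a t_a`` for the
projected scores, so score-space geometry and predictions agree exactly.
Everything is deterministic: no random initialisation exists.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import (
    ContractError,
    ConvergenceError,
    DegenerateFeatureError,
    DegenerateTrainingError,
    DimensionalityError,
    DomainError,
)
from .records import OutcomeLabel

#: Class coding used throughout: the response the model regresses on.
CLASS_CODING = {OutcomeLabel.NOT_COAM: 0.0, OutcomeLabel.COAM: 1.0}

DEFAULT_THRESHOLD = 0.5
SERIALIZATION_SCHEMA = "coamscreen-plsda/1"


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature autoscaling parameters (mean / sample std, n-1)."""

    means: np.ndarray
    scales: np.ndarray
    feature_order: tuple[str, ...]

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.scales


@dataclass(frozen=True)
class LatentScores:
    """Ordered latent-variable scores for one observation."""

    lv: np.ndarray

    def __len__(self) -> int:
        return len(self.lv)


@dataclass(frozen=True)
class PredictionResult:
    """Continuous COAM value, thresholded class and LV scores for one pair."""

    coam_value: Optional[float]
    predicted_class: OutcomeLabel
    scores: Optional[LatentScores] = None


@dataclass(frozen=True)
class BoundaryLine:
    """Decision boundary in the (LV1, LV2) plane.

    Either ``lv2 = intercept + slope * lv1`` or, when the response does
    not depend on LV2, the vertical line ``lv1 = x0``.  ``coam_above``
    tells which side of a non-vertical line predicts COAM (True: points
    with larger LV2 classify COAM); for vertical lines the COAM side is
    ``lv1 >= x0`` iff ``coam_right``.
    """

    vertical: bool
    slope: float = float("nan")
    intercept: float = float("nan")
    x0: float = float("nan")
    coam_above: bool = True
    coam_right: bool = True


@dataclass
class PLSDAModel:
    """A fitted PLS-DA model.

    Attributes mirror the NIPALS decomposition: unit-norm ``weights`` W
    (p x A), ``x_loadings`` P (p x A), scalar ``y_loadings`` q (A,), the
    composite ``regression_vector`` b on the scaled-feature scale, plus
    the scaling, class coding, threshold and provenance metadata.
    """

    n_components: int
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    regression_vector: np.ndarray
    y_mean: float
    scaling: ScalingParams
    threshold: float = DEFAULT_THRESHOLD
    metadata: dict = field(default_factory=dict)
    training_scores: Optional[np.ndarray] = None

    # -- prediction ---------------------------------------------------

    def _check_features(self, feature_order: Optional[Sequence[str]]) -> None:
        if feature_order is not None and tuple(feature_order) != self.scaling.feature_order:
            raise ContractError(
                f"feature order mismatch: model expects {self.scaling.feature_order}, "
                f"got {tuple(feature_order)}"
            )

    def project(
        self, x: np.ndarray, feature_order: Optional[Sequence[str]] = None
    ) -> LatentScores:
        """Latent-variable scores of one observation (row vector)."""
        self._check_features(feature_order)
        e = self.scaling.apply(np.asarray(x, dtype=float).ravel())
        scores = np.empty(self.n_components)
        for a in range(self.n_components):
            t = float(e @ self.weights[:, a])
            scores[a] = t
            e = e - t * self.x_loadings[:, a]
        return LatentScores(lv=scores)

    def predict_value(
        self, x: np.ndarray, feature_order: Optional[Sequence[str]] = None
    ) -> float:
        """Continuous COAM value (class-coding scale, not clamped)."""
        self._check_features(feature_order)
        xs = self.scaling.apply(np.asarray(x, dtype=float).ravel())
        return self.y_mean + float(xs @ self.regression_vector)

    def predict(
        self, x: np.ndarray, feature_order: Optional[Sequence[str]] = None
    ) -> PredictionResult:
        value = self.predict_value(x, feature_order)
        return PredictionResult(
            coam_value=value,
            predicted_class=classify(value, self.threshold),
            scores=self.project(x, feature_order),
        )

    def predict_matrix(self, X, feature_order: Optional[Sequence[str]] = None):
        """Predict a whole feature matrix; returns a list of PredictionResult.

        Accepts an (n, p) array or a pandas DataFrame, whose columns are
        then checked against the model's feature order.
        """
        cols = getattr(X, "columns", None)
        if cols is not None:
            self._check_features(tuple(cols))
            X = X.to_numpy()
        return [self.predict(row, feature_order) for row in np.atleast_2d(np.asarray(X, float))]

    # -- serialization ------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "schema": SERIALIZATION_SCHEMA,
            "n_components": self.n_components,
            "feature_order": list(self.scaling.feature_order),
            "means": self.scaling.means.tolist(),
            "scales": self.scaling.scales.tolist(),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "regression_vector": self.regression_vector.tolist(),
            "y_mean": self.y_mean,
            "threshold": self.threshold,
            "class_coding": {"NOT_COAM": 0, "COAM": 1},
            "metadata": self.metadata,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PLSDAModel":
        doc = json.loads(text)
        if doc.get("schema") != SERIALIZATION_SCHEMA:
            raise ContractError(f"unsupported model schema: {doc.get('schema')!r}")
        scaling = ScalingParams(
            means=np.array(doc["means"], dtype=float),
            scales=np.array(doc["scales"], dtype=float),
            feature_order=tuple(doc["feature_order"]),
        )
        return cls(
            n_components=int(doc["n_components"]),
            weights=np.array(doc["weights"], dtype=float),
            x_loadings=np.array(doc["x_loadings"], dtype=float),
            y_loadings=np.array(doc["y_loadings"], dtype=float),
            regression_vector=np.array(doc["regression_vector"], dtype=float),
            y_mean=float(doc["y_mean"]),
            scaling=scaling,
            threshold=float(doc["threshold"]),
            metadata=doc.get("metadata", {}),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PLSDAModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def autoscale_fit(X: np.ndarray, feature_order: Optional[Sequence[str]] = None) -> ScalingParams:
    """Column means and sample standard deviations (n-1 denominator).

    Raises :class:`DegenerateFeatureError` naming any zero-variance
    feature, since unit-variance scaling is then undefined.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DomainError("autoscale_fit needs a 2-D matrix with at least 2 rows")
    names = tuple(feature_order) if feature_order is not None else tuple(
        f"x{j}" for j in range(X.shape[1])
    )
    if len(names) != X.shape[1]:
        raise ContractError("feature_order length does not match number of columns")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(scales == 0)
    if dead.size:
        raise DegenerateFeatureError(
            f"zero-variance feature(s): {', '.join(names[j] for j in dead)}"
        )
    return ScalingParams(means=means, scales=scales, feature_order=names)


def nipals_fit(
    X,
    y,
    n_components: int = 2,
    tol: float = 1e-10,
    max_iter: int = 500,
    threshold: float = DEFAULT_THRESHOLD,
    feature_order: Optional[Sequence[str]] = None,
    metadata: Optional[dict] = None,
) -> PLSDAModel:
    """Fit a PLS-DA model with NIPALS latent-variable extraction.

    Parameters
    ----------
    X : (n, p) feature matrix or DataFrame (columns become feature_order).
    y : length-n class coding in {0, 1} (or OutcomeLabel sequence).
    n_components : number of latent variables (<= p).
    tol, max_iter : residual-covariance convergence guard; with the
        univariate response each LV is a single closed-form step, so
        these only police degenerate residuals.
    """
    cols = getattr(X, "columns", None)
    if cols is not None and feature_order is None:
        feature_order = tuple(cols)
    X = np.asarray(X, dtype=float)
    y = np.asarray(
        [CLASS_CODING[v] if isinstance(v, OutcomeLabel) else float(v) for v in np.ravel(y)]
    )
    n, p = X.shape
    if len(y) != n:
        raise ContractError(f"X has {n} rows but y has {len(y)} entries")
    if not 1 <= n_components <= p:
        raise DomainError(f"n_components must be in [1, {p}], got {n_components}")
    if np.unique(y).size < 2:
        raise DegenerateTrainingError("training response contains a single class")

    scaling = autoscale_fit(X, feature_order)
    E = scaling.apply(X)
    y_mean = float(y.mean())
    f = y - y_mean

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    T = np.empty((n, n_components))
    for a in range(n_components):
        cov = E.T @ f
        norm = float(np.linalg.norm(cov))
        if norm <= tol:
            raise ConvergenceError(
                f"latent variable {a + 1}: residual X'y covariance is numerically zero"
            )
        w = cov / norm
        t = E @ w
        tt = float(t @ t)
        if tt <= tol:
            raise ConvergenceError(f"latent variable {a + 1}: degenerate score vector")
        p_a = (E.T @ t) / tt
        q_a = float(f @ t) / tt
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
        E = E - np.outer(t, p_a)
        f = f - q_a * t

    b = W @ np.linalg.solve(P.T @ W, q)
    meta = {
        "sign_convention": "API_minus_coformer",
        "class_coding": {"NOT_COAM": 0, "COAM": 1},
        "n_training_pairs": n,
    }
    meta.update(metadata or {})
    return PLSDAModel(
        n_components=n_components,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        regression_vector=b,
        y_mean=y_mean,
        scaling=scaling,
        threshold=threshold,
        metadata=meta,
        training_scores=T,
    )


def classify(coam_value: float, threshold: float = DEFAULT_THRESHOLD) -> OutcomeLabel:
    """COAM iff the continuous value reaches the threshold (inclusive)."""
    if not (math.isfinite(coam_value) and math.isfinite(threshold)):
        raise DomainError("classify requires finite inputs")
    return OutcomeLabel.COAM if coam_value >= threshold else OutcomeLabel.NOT_COAM


def decision_boundary_lv(model: PLSDAModel, eps: float = 1e-12) -> BoundaryLine:
    """Separation line in the (LV1, LV2) score plane.

    In score space the reconstructed response is
    ``ŷ = ȳ + q1·LV1 + q2·LV2``; the boundary is ``ŷ = threshold``.
    Requires at least two latent variables.
    """
    if model.n_components < 2:
        raise DimensionalityError("decision boundary needs a model with >= 2 latent variables")
    q1, q2 = float(model.y_loadings[0]), float(model.y_loadings[1])
    c = model.threshold - model.y_mean
    if abs(q2) <= eps:
        if abs(q1) <= eps:
            raise DomainError("response does not depend on LV1 or LV2; no boundary exists")
        return BoundaryLine(vertical=True, x0=c / q1, coam_right=q1 > 0)
    return BoundaryLine(
        vertical=False, slope=-q1 / q2, intercept=c / q2, coam_above=q2 > 0
    )


def response_from_scores(model: PLSDAModel, lv1, lv2) -> np.ndarray:
    """Reconstructed COAM value at points of the (LV1, LV2) plane."""
    if model.n_components < 2:
        raise DimensionalityError("needs >= 2 latent variables")
    q1, q2 = float(model.y_loadings[0]), float(model.y_loadings[1])
    return model.y_mean + q1 * np.asarray(lv1, float) + q2 * np.asarray(lv2, float)


def leave_one_out_accuracy(X, y, n_components: int = 2, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Leave-one-out classification accuracy of a PLS-DA fit (fraction)."""
    cols = getattr(X, "columns", None)
    order = tuple(cols) if cols is not None else None
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(
        [CLASS_CODING[v] if isinstance(v, OutcomeLabel) else float(v) for v in np.ravel(y)]
    )
    n = Xa.shape[0]
    correct = 0
    for i in range(n):
        mask = np.arange(n) != i
        model = nipals_fit(Xa[mask], ya[mask], n_components=n_components, threshold=threshold,
                           feature_order=order)
        pred = classify(model.predict_value(Xa[i]), threshold)
        truth = OutcomeLabel.COAM if ya[i] == 1.0 else OutcomeLabel.NOT_COAM
        correct += pred is truth
    return correct / n
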