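"""Per-Gα coupling classifiers: L2 logistic regression with [0,1] scaling.

The model is binary logistic regression minimising

    min_{w,c}  (1/2) wᵀw + C Σᵢ log(1 + exp(-yᵢ (xᵢᵀw + c))),   yᵢ ∈ {-1, +1}

with features min-max scaled to [0, 1] and classes re-weighted inversely to
their frequencies.  The inverse regularisation strength C is chosen by grid
search over stratified 5-fold cross-validated ROC AUC; the whole CV is
repeated (default ten times) with different fold seeds and the reported CV
AUC is the mean ± sd over repeats.  Feature relevance is read off the
trained weights, and a label-randomisation test (refit on class-preserving
label permutations) probes over-fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, check_X_y

DEFAULT_C_GRID = tuple(float(c) for c in np.logspace(-3, 3, 10))


def _fit_minmax(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return X.min(axis=0), X.max(axis=0)


def _apply_minmax(X: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                  clip: bool = True) -> np.ndarray:
    span = hi - lo
    out = np.where(span > 0, (X - lo) / np.where(span > 0, span, 1.0), 0.0)
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out


class CouplingClassifier(BaseEstimator, ClassifierMixin):
    """L2 logistic-regression coupling model with built-in scaling and CV.

    Parameters
    ----------
    C_grid : candidate inverse regularisation strengths (ascending; ties in
        CV AUC resolve to the smallest C, i.e. the strongest regularisation).
    n_folds, n_repeats : stratified CV layout; fold seeds derive from
        ``random_state`` by fixed arithmetic, so fits are reproducible.
    class_weight : "balanced" re-weights classes inversely to frequency.
    scaling : "fold" fits the [0,1] scaler inside each training fold
        (leak-free default); "global" scales the whole matrix before CV.
    solver, tol, max_iter : passed to the convex optimiser; the intercept is
        not penalised.

    Fitted attributes: ``coef_``, ``intercept_``, ``C_``, ``scaler_min_``,
    ``scaler_max_``, ``cv_auc_mean_``, ``cv_auc_sd_``, ``cv_auc_grid_``.
    """

    def __init__(
        self,
        C_grid: Sequence[float] = DEFAULT_C_GRID,
        n_folds: int = 5,
        n_repeats: int = 10,
        class_weight: str | dict | None = "balanced",
        scaling: str = "fold",
        solver: str = "lbfgs",
        tol: float = 1e-10,
        max_iter: int = 5000,
        random_state: int = 0,
    ):
        self.C_grid = C_grid
        self.n_folds = n_folds
        self.n_repeats = n_repeats
        self.class_weight = class_weight
        self.scaling = scaling
        self.solver = solver
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _lr(self, C: float) -> LogisticRegression:
        # L2 penalty (the solver default), strength 1/C, intercept unpenalised
        return LogisticRegression(
            C=C, solver=self.solver, tol=self.tol,
            max_iter=self.max_iter, class_weight=self.class_weight,
        )

    def fit(self, X, y) -> "CouplingClassifier":
        X, y = check_X_y(X, np.asarray(y))
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("exactly two classes are required")
        self.classes_ = classes
        y01 = (y == classes[1]).astype(int)
        counts = np.bincount(y01)
        if counts.min() < self.n_folds:
            raise ValueError(
                f"minority class has {counts.min()} samples; "
                f"stratified {self.n_folds}-fold CV needs at least {self.n_folds}"
            )
        grid = np.sort(np.asarray(self.C_grid, dtype=float))
        if grid.size == 0 or np.any(grid <= 0):
            raise ValueError("C grid must be non-empty and positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        fold_seeds = [
            int((self.random_state * 1_000_003 + 7919 * r) % (2**31 - 1))
            for r in range(self.n_repeats)
        ]
        aucs = np.zeros((self.n_repeats, grid.size))
        for r, fs in enumerate(fold_seeds):
            skf = StratifiedKFold(self.n_folds, shuffle=True, random_state=fs)
            folds = list(skf.split(X, y01))
            if self.scaling == "global":
                lo, hi = _fit_minmax(X)
                Xg = _apply_minmax(X, lo, hi)
            for ci, C in enumerate(grid):
                scores = []
                for tr, te in folds:
                    if self.scaling == "fold":
                        lo, hi = _fit_minmax(X[tr])
                        Xtr = _apply_minmax(X[tr], lo, hi)
                        Xte = _apply_minmax(X[te], lo, hi)
                    else:
                        Xtr, Xte = Xg[tr], Xg[te]
                    lr = self._lr(C).fit(Xtr, y01[tr])
                    scores.append(roc_auc_score(y01[te], lr.decision_function(Xte)))
                aucs[r, ci] = float(np.mean(scores))
        mean_by_c = aucs.mean(axis=0)
        best = int(np.argmax(mean_by_c))  # first max => smallest C on ties
        self.C_ = float(grid[best])
        self.cv_auc_grid_ = mean_by_c
        self.cv_auc_mean_ = float(mean_by_c[best])
        self.cv_auc_sd_ = float(aucs[:, best].std())

        self.scaler_min_, self.scaler_max_ = _fit_minmax(X)
        Xs = _apply_minmax(X, self.scaler_min_, self.scaler_max_)
        lr = self._lr(self.C_).fit(Xs, y01)
        self.coef_ = lr.coef_.ravel().copy()
        self.intercept_ = float(lr.intercept_[0])
        self.n_features_in_ = X.shape[1]
        return self

    def _scale(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return _apply_minmax(X, self.scaler_min_, self.scaler_max_)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self._scale(X) @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        """Coupling probability by the logistic of the linear score."""
        z = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p > 0.5).astype(int)]


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def objective(w: np.ndarray, c: float, X: np.ndarray, y_pm: np.ndarray,
              C: float, sample_weight: np.ndarray | None = None) -> float:
    """The penalised logistic cost: (1/2)wᵀw + C Σ log(1 + exp(-y(xᵀw+c)))."""
    margins = -y_pm * (X @ w + c)
    losses = np.logaddexp(0.0, margins)
    if sample_weight is not None:
        losses = losses * sample_weight
    return float(0.5 * w @ w + C * losses.sum())


@dataclass
class TrainingConfig:
    """Reproducible training layout for one Gα model."""

    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    n_folds: int = 5
    n_repeats: int = 10
    class_weighting: str | None = "balanced"
    scaling: str = "fold"
    seed: int = 0


@dataclass
class MetricsReport:
    """Standard binary-classification metrics at a probability threshold."""

    MCC: float
    ACC: float
    PRE: float
    REC: float
    SPE: float
    AUC: float
    F1M: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def compute_metrics(probabilities, labels, threshold: float = 0.5) -> MetricsReport:
    """MCC, accuracy, precision, recall, specificity, rank AUC and macro F1.

    AUC is the rank statistic over all positive/negative pairs with ties
    counted 1/2; with a single class present, AUC and MCC are NaN.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if p.size == 0:
        raise ValueError("empty input")
    pred = p > threshold
    tn = int(np.sum(~y & ~pred))
    fp = int(np.sum(~y & pred))
    one_class = y.all() or not y.any()
    return MetricsReport(
        MCC=float("nan") if one_class else float(matthews_corrcoef(y, pred)),
        ACC=float(accuracy_score(y, pred)),
        PRE=float(precision_score(y, pred, zero_division=0)),
        REC=float(recall_score(y, pred, zero_division=0)),
        SPE=float(tn / (tn + fp)) if (tn + fp) > 0 else float("nan"),
        AUC=float("nan") if one_class else float(roc_auc_score(y, p)),
        F1M=float(f1_score(y, pred, average="macro", zero_division=0)),
    )


def feature_relevance(
    weights: np.ndarray, feature_names: Sequence[str]
) -> list[tuple[str, float]]:
    """Features ranked by |weight| descending (the model's relevance view)."""
    w = np.asarray(weights, dtype=float)
    if len(w) != len(feature_names):
        raise ValueError("weights and feature names differ in length")
    order = np.argsort(-np.abs(w), kind="stable")
    return [(feature_names[i], float(w[i])) for i in order]


def randomization_test(
    X,
    y,
    config: TrainingConfig | None = None,
    n_randomizations: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """CV AUC distribution under class-count-preserving label permutations.

    Each randomisation permutes the labels (exactly preserving the coupled /
    not-coupled counts), reruns the full training procedure and records its
    cross-validated AUC.  Near-chance values indicate the true-label model is
    not an artefact of over-fitting.
    """
    config = config or TrainingConfig()
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    out = np.empty(n_randomizations)
    for k in range(n_randomizations):
        y_perm = y[rng.permutation(len(y))]
        clf = CouplingClassifier(
            C_grid=config.c_grid, n_folds=config.n_folds, n_repeats=config.n_repeats,
            class_weight=config.class_weighting, scaling=config.scaling,
            random_state=int((seed + 1) * 104729 + k) % (2**31 - 1),
        ).fit(X, y_perm)
        out[k] = clf.cv_auc_mean_
    return out


@dataclass
class ModelBundle:
    """Serializable trained model for one Gα: weights + scaler + diagnostics."""

    galpha: str
    weights: np.ndarray
    intercept: float
    C: float
    scaler_min: np.ndarray
    scaler_max: np.ndarray
    cv_auc_mean: float
    cv_auc_sd: float
    feature_names: list[str] = field(default_factory=list)
    schema_ref: str = ""

    @classmethod
    def from_estimator(
        cls, clf: CouplingClassifier, galpha: str,
        feature_names: Sequence[str] = (), schema_ref: str = "",
    ) -> "ModelBundle":
        return cls(
            galpha=galpha,
            weights=clf.coef_.copy(),
            intercept=clf.intercept_,
            C=clf.C_,
            scaler_min=clf.scaler_min_.copy(),
            scaler_max=clf.scaler_max_.copy(),
            cv_auc_mean=clf.cv_auc_mean_,
            cv_auc_sd=clf.cv_auc_sd_,
            feature_names=list(feature_names),
            schema_ref=schema_ref,
        )

    def scale(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return _apply_minmax(x, self.scaler_min, self.scaler_max)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """P(coupled) = (1 + exp(-(wᵀx' + c)))⁻¹ on the scaled features."""
        xs = self.scale(x)
        if xs.shape[1] != len(self.weights):
            raise ValueError("feature vector length does not match the model")
        return sigmoid(xs @ self.weights + self.intercept)

    def contributions(self, x: np.ndarray) -> np.ndarray:
        """Per-feature weight × scaled value; sums to logit(P) - intercept."""
        xs = self.scale(x)
        return xs * self.weights

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "galpha": self.galpha,
            "weights": [float(v) for v in self.weights],
            "intercept": self.intercept,
            "C": self.C,
            "scaler_min": [float(v) for v in self.scaler_min],
            "scaler_max": [float(v) for v in self.scaler_max],
            "cv_auc_mean": self.cv_auc_mean,
            "cv_auc_sd": self.cv_auc_sd,
            "feature_names": self.feature_names,
            "schema_ref": self.schema_ref,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelBundle":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            galpha=d["galpha"],
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            C=float(d["C"]),
            scaler_min=np.asarray(d["scaler_min"], dtype=float),
            scaler_max=np.asarray(d["scaler_max"], dtype=float),
            cv_auc_mean=float(d["cv_auc_mean"]),
            cv_auc_sd=float(d["cv_auc_sd"]),
            feature_names=list(d["feature_names"]),
            schema_ref=d.get("schema_ref", ""),
        )


def train(
    matrix: np.ndarray,
    labels: Sequence[bool],
    config: TrainingConfig | None = None,
    galpha: str = "G",
    feature_names: Sequence[str] = (),
) -> tuple[ModelBundle, CouplingClassifier]:
    """Convenience wrapper: fit a CouplingClassifier and bundle the result."""
    config = config or TrainingConfig()
    clf = CouplingClassifier(
        C_grid=config.c_grid, n_folds=config.n_folds, n_repeats=config.n_repeats,
        class_weight=config.class_weighting, scaling=config.scaling,
        random_state=config.seed,
    ).fit(matrix, np.asarray(labels, dtype=bool))
    return ModelBundle.from_estimator(clf, galpha, feature_names), clf
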