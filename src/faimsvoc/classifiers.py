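"""The three diagnostic classifiers behind one train/predict contract.

All models consume the selected wavelet features (standardized on the
training fold as part of the fitted model) and emit a probability that the
patient has coeliac disease (CD = 1, D-IBS = 0):

* ``sparse_logistic`` — logistic regression with an elastic-net penalty,
  which drives uninformative coefficients to zero; the fitted coefficient
  vector is exposed for sparsity inspection.
* ``random_forest`` — an ensemble of decision trees; probability is the
  fraction of trees voting CD.
* ``svm`` — a kernel support-vector machine; its signed decision margin is
  the ranking score, mapped through a logistic link onto [0, 1] so the
  contract's probability range holds (the mapping is monotone, so ROC
  analysis sees exactly the margin ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

KINDS = ("sparse_logistic", "random_forest", "svm")

_DEFAULTS: dict[str, dict[str, Any]] = {
    # elastic-net mixing 0.5; fixed moderate penalty; set c_grid to a list of
    # C values to tune instead by 5-fold CV inside the training fold
    "sparse_logistic": {"l1_ratio": 0.5, "C": 1.0, "c_grid": None,
                        "max_iter": 5000, "tol": 1e-8},
    "random_forest": {"n_estimators": 500, "max_depth": None},
    "svm": {"kernel": "linear", "C": 1.0},
}


@dataclass
class ClassifierSpec:
    """Classifier kind plus hyperparameters; defaults filled per kind."""

    kind: str = "sparse_logistic"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        merged = dict(_DEFAULTS[self.kind])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    pipeline: Pipeline
    n_features: int

    @property
    def coefficients(self) -> np.ndarray:
        """Non-intercept coefficient vector (sparse_logistic only)."""
        if self.spec.kind != "sparse_logistic":
            raise ValueError("coefficients only exposed for sparse_logistic")
        return self.pipeline[-1].coef_.ravel().copy()


def _build(spec: ClassifierSpec):
    hp = spec.hyperparameters
    if spec.kind == "sparse_logistic":
        if hp.get("c_grid"):
            clf = LogisticRegressionCV(
                Cs=list(hp["c_grid"]), cv=5, solver="saga",
                l1_ratios=[hp["l1_ratio"]], scoring="neg_log_loss",
                max_iter=hp["max_iter"], random_state=spec.seed, tol=1e-4,
            )
        else:
            clf = LogisticRegression(
                solver="saga", C=hp["C"], l1_ratio=hp["l1_ratio"],
                max_iter=hp["max_iter"], random_state=spec.seed, tol=hp["tol"],
            )
    elif spec.kind == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=hp["n_estimators"], max_depth=hp["max_depth"],
            random_state=spec.seed,
        )
    else:
        clf = SVC(kernel=hp["kernel"], C=hp["C"], random_state=spec.seed)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def fit_classifier(spec: ClassifierSpec, features: np.ndarray,
                   labels: Sequence[int]) -> TrainedModel:
    """Fit the requested model on a training matrix (rows = patients).

    Features are standardized with training-fold statistics inside the
    returned model.  Deterministic for a fixed spec (including seed).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or not np.all(np.isfinite(X)):
        raise ValueError("features must be a finite 2-D matrix")
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    pipe = _build(spec)
    pipe.fit(X, y)
    clf = pipe[-1]
    if spec.kind == "sparse_logistic" and np.all(clf.coef_ == 0.0):
        # saga's stopping rule watches only the (penalized) coefficients, so
        # once l1 zeroes them all it may halt with the unpenalized intercept
        # unconverged; with zero coefficients the optimum is closed-form.
        prevalence = float(np.mean(y == clf.classes_[1]))
        clf.intercept_ = np.array([np.log(prevalence / (1.0 - prevalence))])
    return TrainedModel(spec, pipe, X.shape[1])


def predict_probabilities(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Probability of CD for each row of ``features``."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature count {X.shape[1]} != training count {model.n_features}")
    clf = model.pipeline[-1]
    if model.spec.kind == "svm":
        margin = model.pipeline.decision_function(X)
        if clf.classes_[1] != 1:                  # margin is for classes_[1]
            margin = -margin
        return 1.0 / (1.0 + np.exp(-margin))
    proba = model.pipeline.predict_proba(X)
    return proba[:, list(clf.classes_).index(1)]


def predict_probability(model: TrainedModel, features: np.ndarray) -> float:
    """Probability of CD for a single feature vector."""
    return float(predict_probabilities(model, np.atleast_2d(features))[0])
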