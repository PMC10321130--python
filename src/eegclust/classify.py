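"""Registry of the ten benchmark classifiers plus supporting procedures.

The registry wires established scikit-learn estimators to the fixed
hyperparameters used throughout the benchmark: an SGD-trained multilayer
perceptron (32 hidden sigmoid units, learning rate 0.3, momentum 0.5, 800
training cycles), 2-nearest-neighbour with nearest-neighbour tie-breaking,
incremental LDA (authored here; streaming class means and pooled scatter),
Gaussian naive Bayes, three SVMs (linear trained by stochastic gradient
descent, polynomial of order 2, RBF with gamma 2.0), QDA, a decision tree
and a random forest.  Also provided: the training-MSE-versus-iterations
hyperparameter search used to pick those SVM/KNN settings, pairwise
one-against-one voting, and the consecutive-positive-window seizure alarm
rule with median smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSIFIER_KINDS = (
    "ann",
    "knn",
    "ilda",
    "nbc",
    "svm_linear",
    "svm_poly",
    "svm_rbf",
    "qda",
    "dtree",
    "rf",
)


@dataclass(frozen=True)
class ClassifierSpec:
    """A registry entry: classifier kind, overridable params, seed."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise KeyError(
                f"unknown classifier kind {self.kind!r}; expected one of {CLASSIFIER_KINDS}"
            )


def default_specs(seed: int = 0) -> list[ClassifierSpec]:
    """The ten-classifier benchmark roster with default hyperparameters."""
    return [ClassifierSpec(kind, seed=seed) for kind in CLASSIFIER_KINDS]


def build_classifier(spec: ClassifierSpec):
    """Instantiate a fit/predict estimator for a registry spec.

    Gradient-trained models (ANN, SGD linear SVM) are wrapped with a
    feature standardizer so the fixed learning rates are usable regardless
    of feature scale.
    """
    p = dict(spec.params)
    kind, seed = spec.kind, spec.seed
    if kind == "ann":
        clf = MLPClassifier(
            hidden_layer_sizes=p.pop("hidden_layer_sizes", (32,)),
            activation="logistic",
            solver="sgd",
            learning_rate_init=p.pop("learning_rate", 0.3),
            momentum=p.pop("momentum", 0.5),
            max_iter=p.pop("cycles", 800),
            random_state=seed,
            **p,
        )
        return make_pipeline(StandardScaler(), clf)
    if kind == "knn":
        # k=2 with distance weights: the nearer neighbour decides ties
        return KNeighborsClassifier(
            n_neighbors=p.pop("k", 2), weights="distance", metric="euclidean", **p
        )
    if kind == "ilda":
        return IncrementalLDA()
    if kind == "nbc":
        return GaussianNB(**p)
    if kind == "svm_linear":
        clf = SGDClassifier(
            loss="hinge",
            max_iter=p.pop("iterations", 1000),
            tol=None,
            random_state=seed,
            **p,
        )
        return make_pipeline(StandardScaler(), clf)
    if kind == "svm_poly":
        return SVC(kernel="poly", degree=p.pop("order", 2), random_state=seed, **p)
    if kind == "svm_rbf":
        return SVC(kernel="rbf", gamma=p.pop("gamma", 2.0), random_state=seed, **p)
    if kind == "qda":
        # slight covariance shrinkage: sorted-centroid features can be
        # near-collinear, which would make class covariances singular
        return QuadraticDiscriminantAnalysis(reg_param=p.pop("reg_param", 1e-3), **p)
    if kind == "dtree":
        return DecisionTreeClassifier(criterion="entropy", random_state=seed, **p)
    if kind == "rf":
        return RandomForestClassifier(
            n_estimators=p.pop("n_estimators", 100), random_state=seed, **p
        )
    raise KeyError(kind)


# ---------------------------------------------------------------------------
# distances, regularization, pairwise voting


def knn_distance(z1: Sequence[float], z2: Sequence[float]) -> float:
    """Euclidean distance between two feature vectors."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("vectors must have equal length")
    return float(np.linalg.norm(z1 - z2))


def svm_regularization_q(
    train_features: np.ndarray,
    kernel: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> float:
    """Data-driven regularization Q = N / sum_j K(y_j, y_bar).

    The reference point is the training mean; the default kernel is
    1 + <u, v> (a positive linear kernel on standardized data).  Q is
    invariant under duplication of the training set.
    """
    Y = np.atleast_2d(np.asarray(train_features, dtype=float))
    if Y.size == 0:
        raise ValueError("empty training set")
    if kernel is None:
        kernel = lambda u, v: 1.0 + float(u @ v)  # noqa: E731
    center = Y.mean(axis=0)
    total = sum(kernel(y, center) for y in Y)
    if total == 0.0:
        raise ZeroDivisionError("kernel sum is zero; Q undefined")
    return len(Y) / total


def pairwise_vote(decisions: Sequence[float], n_classes: int) -> int:
    """One-against-one vote over n(n-1)/2 signed pair decisions.

    ``decisions`` are ordered as pairs (0,1), (0,2), ..., (n-2, n-1); a
    positive score votes for the first class of the pair, negative for the
    second.  Ties resolve to the lowest class index.
    """
    expected = n_classes * (n_classes - 1) // 2
    if len(decisions) != expected:
        raise ValueError(f"need {expected} pair decisions, got {len(decisions)}")
    votes = np.zeros(n_classes)
    idx = 0
    for a in range(n_classes):
        for b in range(a + 1, n_classes):
            s = np.sign(decisions[idx])
            if s > 0:
                votes[a] += 1
            elif s < 0:
                votes[b] += 1
            idx += 1
    return int(np.argmax(votes))  # argmax resolves ties to the lowest index


# ---------------------------------------------------------------------------
# incremental LDA


class IncrementalLDA:
    """Streaming two-class LDA: class means and pooled scatter kept online.

    ``partial_fit`` folds in new observations without revisiting old ones;
    after any sample order over the same set, predictions coincide with
    batch LDA.  Prediction before both classes have been observed raises.
    """

    def __init__(self) -> None:
        self.classes_: np.ndarray | None = None
        self._counts: dict = {}
        self._means: dict = {}
        self._scatter: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "IncrementalLDA":
        self.__init__()
        return self.partial_fit(X, y)

    def partial_fit(self, X: np.ndarray, y: np.ndarray) -> "IncrementalLDA":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if X.shape[0] == 0:
            return self
        if self._scatter is None:
            self._scatter = np.zeros((X.shape[1], X.shape[1]))
        for xi, yi in zip(X, y):
            n = self._counts.get(yi, 0)
            mean = self._means.get(yi, np.zeros(X.shape[1]))
            delta = xi - mean
            new_mean = mean + delta / (n + 1)
            # rank-1 update of the within-class scatter (Welford)
            self._scatter += np.outer(delta, xi - new_mean)
            self._counts[yi] = n + 1
            self._means[yi] = new_mean
        self.classes_ = np.asarray(sorted(self._counts))
        return self

    def _check_ready(self) -> None:
        if self.classes_ is None or len(self.classes_) < 2:
            raise RuntimeError(
                "incremental LDA needs observations from both classes before predicting"
            )

    @property
    def coef_(self) -> np.ndarray:
        """Discriminant direction Sigma^-1 (mu_1 - mu_0)."""
        self._check_ready()
        c0, c1 = self.classes_[:2]
        n = sum(self._counts.values())
        cov = self._scatter / max(n - len(self.classes_), 1)
        cov = cov + 1e-12 * np.eye(cov.shape[0])
        return np.linalg.solve(cov, self._means[c1] - self._means[c0])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        self._check_ready()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        c0, c1 = self.classes_[:2]
        w = self.coef_
        m = 0.5 * (self._means[c0] + self._means[c1])
        n0, n1 = self._counts[c0], self._counts[c1]
        bias = float(np.log(n1 / n0))
        return (X - m) @ w + bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        score = self.decision_function(X)
        c0, c1 = self.classes_[:2]
        return np.where(score > 0, c1, c0)


def ilda_partial_fit(
    model: IncrementalLDA, new_features: np.ndarray, new_labels: np.ndarray
) -> IncrementalLDA:
    """Functional wrapper over :meth:`IncrementalLDA.partial_fit`."""
    return model.partial_fit(new_features, new_labels)


# ---------------------------------------------------------------------------
# MSE-vs-iterations hyperparameter search (grid tables)

DEFAULT_ITERATION_SCHEDULE = (
    50, 100, 150, 200, 225, 250, 300, 350, 375, 400, 500, 600, 800, 1000, 1200, 1400,
)


def _spec_with(spec: ClassifierSpec, param_name: str | None, value, iterations: int) -> ClassifierSpec:
    params = dict(spec.params)
    if param_name is not None:
        params[param_name] = value
    if spec.kind == "ann":
        params["cycles"] = iterations
    elif spec.kind == "svm_linear":
        params["iterations"] = iterations
    elif spec.kind in ("svm_poly", "svm_rbf"):
        params["max_iter"] = iterations
    # instance-based / closed-form learners have no iteration axis; their
    # MSE column is constant across the schedule
    return ClassifierSpec(spec.kind, params, spec.seed)


def mse_hyperparam_search(
    spec_template: ClassifierSpec,
    grid: Sequence,
    train_X: np.ndarray,
    train_y: np.ndarray,
    param_name: str | None = None,
    iteration_schedule: Sequence[int] = DEFAULT_ITERATION_SCHEDULE,
    seed: int = 0,
) -> tuple[pd.DataFrame, object]:
    """Training-MSE grid over (hyperparameter value, iteration cap).

    For each grid value and iteration cap the classifier is trained and
    the training MSE of predicted-versus-true binary labels recorded; the
    table has one row per schedule step and one column per grid value.  A
    grid value qualifies when its last three scheduled MSEs are
    non-increasing (converged, not trapped or flat-lined); among
    qualifiers the one with the lowest final MSE wins (all grid values
    compete on final MSE if none qualifies).
    """
    if len(grid) == 0 or len(iteration_schedule) == 0:
        raise ValueError("grid and iteration schedule must be nonempty")
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    y_num = (train_y == np.unique(train_y)[-1]).astype(float)
    table = pd.DataFrame(
        index=pd.Index(list(iteration_schedule), name="iterations"),
        columns=list(grid),
        dtype=float,
    )
    for value in grid:
        for iters in iteration_schedule:
            spec = _spec_with(spec_template, param_name, value, int(iters))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf = build_classifier(spec)
                    clf.fit(train_X, train_y)
                    pred = clf.predict(train_X)
            except Exception:
                continue  # recorded as missing
            p_num = (np.asarray(pred) == np.unique(train_y)[-1]).astype(float)
            table.loc[iters, value] = float(np.mean((p_num - y_num) ** 2))
    finals = table.iloc[-1]
    tail = table.iloc[-3:] if len(table) >= 3 else table
    qualifies = [
        v
        for v in grid
        if table[v].notna().all() and np.all(np.diff(tail[v].to_numpy()) <= 0)
    ]
    candidates = qualifies if qualifies else [v for v in grid if not np.isnan(finals[v])]
    if not candidates:
        raise RuntimeError("every grid cell failed to train")
    chosen = min(candidates, key=lambda v: (finals[v], list(grid).index(v)))
    return table, chosen


# ---------------------------------------------------------------------------
# seizure alarm rule


@dataclass(frozen=True)
class AlarmConfig:
    """Alarm threshold (consecutive positives) and median smoothing width."""

    alarm_threshold: int = 3
    median_width: int = 1
    window_step: float = 1.0

    def __post_init__(self) -> None:
        if self.alarm_threshold < 1:
            raise ValueError("alarm_threshold must be >= 1")
        if self.median_width < 1 or self.median_width % 2 == 0:
            raise ValueError("median_width must be odd and >= 1")


def median_smooth(stream: np.ndarray, width: int) -> np.ndarray:
    """Median filter with replicated edges; width 1 is the identity."""
    x = np.asarray(stream)
    if width == 1:
        return x.copy()
    half = width // 2
    padded = np.pad(x, half, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, width)
    return np.median(windows, axis=1).astype(x.dtype)


def seizure_alarm(binary_stream: Sequence[int], cfg: AlarmConfig = AlarmConfig()) -> list[int]:
    """Indices where a run of ``alarm_threshold`` consecutive 1s completes.

    The stream is median-smoothed first; each completed run raises one
    alarm and resets the run counter.
    """
    stream = np.asarray(binary_stream, dtype=int)
    if not np.all(np.isin(stream, (0, 1))):
        raise ValueError("stream must be binary 0/1")
    smoothed = median_smooth(stream, cfg.median_width)
    alarms: list[int] = []
    run = 0
    for i, v in enumerate(smoothed):
        run = run + 1 if v == 1 else 0
        if run == cfg.alarm_threshold:
            alarms.append(i)
            run = 0
    return alarms
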