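"""The four classification algorithms under one train/predict/score contract.

LDA and the Gaussian naive Bayes classifier are generative models
implemented from their closed forms; KNN is implemented directly
(brute-force neighbor search); the RBF-kernel SVM delegates to
scikit-learn's SVC behind the same contract.

Scores returned by :func:`predict_scores` are posterior probabilities for
LDA/NBC, neighbor-vote fractions for KNN (rows sum to 1 in all three
cases), and one-vs-rest decision values mapped monotonically to [0, 1] for
the SVM.
"""

from __future__ import annotations

import base64
import pickle
import time
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.special import logsumexp
from sklearn.svm import SVC

from .errors import InvalidArgumentError, NumericalError

__all__ = [
    "ALGORITHMS",
    "ScoreMatrix",
    "LDAClassifier",
    "GaussianNBClassifier",
    "KNNClassifier",
    "RBFSVMClassifier",
    "fit",
    "predict",
    "predict_scores",
    "model_to_dict",
    "model_from_dict",
]

ALGORITHMS = ("lda", "nbc", "svm", "knn")

SERIALIZATION_VERSION = 1


@dataclass
class ScoreMatrix:
    """Per-sample, per-class scores; higher means more likely."""

    values: np.ndarray  # (n_samples, n_classes)
    classes: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.classes):
            raise InvalidArgumentError("scores must be (n_samples, n_classes)")

    def argmax_labels(self) -> np.ndarray:
        idx = np.argmax(self.values, axis=1)
        return np.asarray(self.classes, dtype=object)[idx]


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidArgumentError("X must be a 2-D (n_samples, n_features) array")
    return X


def _validate_training(X: np.ndarray, y: np.ndarray, check_finite: bool = True):
    if X.shape[0] != len(y):
        raise InvalidArgumentError("X and y have different lengths")
    if X.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 training samples")
    if check_finite and not np.isfinite(X).all():
        raise InvalidArgumentError("X contains non-finite features")
    classes = np.unique(y)
    if len(classes) < 2:
        raise InvalidArgumentError(
            f"need at least 2 classes in y; got only {classes[0]!r}"
        )
    return classes


class _BaseModel:
    """Uniform contract: fit(X, y) -> self; predict; predict_scores."""

    algorithm: str = ""
    classes_: np.ndarray
    n_features_: int

    def _check_X(self, X) -> np.ndarray:
        X = _as_matrix(X)
        if X.shape[1] != self.n_features_:
            raise InvalidArgumentError(
                f"X has {X.shape[1]} features; model was fit with "
                f"{self.n_features_}"
            )
        return X

    def predict(self, X) -> np.ndarray:
        return self.predict_scores(X).argmax_labels()

    def predict_scores(self, X) -> ScoreMatrix:  # pragma: no cover - abstract
        raise NotImplementedError


class LDAClassifier(_BaseModel):
    """Linear discriminant analysis via the pooled-covariance closed form.

    Per-class means mu_k, empirical priors pi_k, and a pooled within-class
    covariance Sigma with a small ridge ``lambda * trace(Sigma)/p * I``.
    The discriminant is delta_k(x) = x' Sigma^-1 mu_k - mu_k' Sigma^-1 mu_k / 2
    + log pi_k; scores are the softmax posteriors (the shared quadratic term
    cancels).
    """

    algorithm = "lda"

    def __init__(self, ridge: float = 1e-6):
        if ridge < 0:
            raise InvalidArgumentError("ridge must be >= 0")
        self.ridge = float(ridge)

    def fit(self, X, y) -> "LDAClassifier":
        X = _as_matrix(X)
        y = np.asarray(y)
        classes = _validate_training(X, y)
        n, p = X.shape
        k = len(classes)
        means = np.empty((k, p))
        priors = np.empty(k)
        scatter = np.zeros((p, p))
        for i, c in enumerate(classes):
            block = X[y == c]
            means[i] = block.mean(axis=0)
            priors[i] = block.shape[0] / n
            centered = block - means[i]
            scatter += centered.T @ centered
        dof = max(n - k, 1)
        cov = scatter / dof
        tr = np.trace(cov)
        lam = self.ridge * (tr / p if tr > 0 else 1.0)
        cov[np.diag_indices_from(cov)] += lam
        try:
            cho = scipy.linalg.cho_factor(cov, check_finite=False)
        except scipy.linalg.LinAlgError as exc:
            raise NumericalError(
                "pooled covariance is singular despite ridge regularization; "
                "raise `ridge` or reduce the feature set"
            ) from exc
        self.classes_ = classes
        self.n_features_ = p
        self.means_ = means
        self.priors_ = priors
        self.covariance_ = cov
        # linear form: delta(x) = x @ coef_ + intercept_
        self.coef_ = scipy.linalg.cho_solve(cho, means.T, check_finite=False)
        self.intercept_ = (
            -0.5 * np.einsum("kp,pk->k", means, self.coef_) + np.log(priors)
        )
        return self

    def decision_values(self, X) -> np.ndarray:
        X = self._check_X(X)
        return X @ self.coef_ + self.intercept_

    def predict_scores(self, X) -> ScoreMatrix:
        d = self.decision_values(X)
        log_post = d - logsumexp(d, axis=1, keepdims=True)
        return ScoreMatrix(np.exp(log_post), tuple(self.classes_))


class GaussianNBClassifier(_BaseModel):
    """Gaussian naive Bayes from the closed-form estimators.

    Per-class, per-feature means and (population) variances with a variance
    floor of ``floor_ratio * max(variance)``; likelihoods are computed in
    log space to avoid underflow.
    """

    algorithm = "nbc"

    def __init__(self, floor_ratio: float = 1e-9):
        if floor_ratio < 0:
            raise InvalidArgumentError("floor_ratio must be >= 0")
        self.floor_ratio = float(floor_ratio)

    def fit(self, X, y) -> "GaussianNBClassifier":
        X = _as_matrix(X)
        y = np.asarray(y)
        classes = _validate_training(X, y)
        k, p = len(classes), X.shape[1]
        means = np.empty((k, p))
        variances = np.empty((k, p))
        priors = np.empty(k)
        for i, c in enumerate(classes):
            block = X[y == c]
            means[i] = block.mean(axis=0)
            variances[i] = block.var(axis=0)
            priors[i] = block.shape[0] / X.shape[0]
        vmax = variances.max()
        floor = self.floor_ratio * vmax if vmax > 0 else 1e-12
        variances = np.maximum(variances, max(floor, 1e-300))
        self.classes_ = classes
        self.n_features_ = p
        self.means_ = means
        self.variances_ = variances
        self.priors_ = priors
        return self

    def _log_joint(self, X) -> np.ndarray:
        X = self._check_X(X)
        out = np.empty((X.shape[0], len(self.classes_)))
        for i in range(len(self.classes_)):
            var = self.variances_[i]
            diff = X - self.means_[i]
            out[:, i] = (
                -0.5 * np.sum(np.log(2.0 * np.pi * var) + diff**2 / var, axis=1)
                + np.log(self.priors_[i])
            )
        return out

    def predict_scores(self, X) -> ScoreMatrix:
        lj = self._log_joint(X)
        log_post = lj - logsumexp(lj, axis=1, keepdims=True)
        return ScoreMatrix(np.exp(log_post), tuple(self.classes_))


class KNNClassifier(_BaseModel):
    """k-nearest neighbors with uniform vote weighting.

    Training stores references only — no statistics, no validation scan,
    not even class enumeration — so training cost is O(1) regardless of
    dataset size; all computation happens at prediction time.  Vote ties
    are broken by smaller summed neighbor distance, then by class order.
    """

    algorithm = "knn"

    def __init__(self, k: int = 5, metric: str = "euclidean"):
        if k < 1:
            raise InvalidArgumentError("k must be >= 1")
        if metric != "euclidean":
            raise InvalidArgumentError("only the euclidean metric is supported")
        self.k = int(k)
        self.metric = metric

    def fit(self, X, y) -> "KNNClassifier":
        # deliberately O(1): store references, defer everything else
        self._X = X
        self._y = y
        self._prepared = False
        return self

    def _prepare(self):
        if self._prepared:
            return
        X = _as_matrix(self._X)
        y = np.asarray(self._y)
        classes = _validate_training(X, y, check_finite=True)
        if self.k > X.shape[0]:
            raise InvalidArgumentError(
                f"k={self.k} exceeds the {X.shape[0]} stored training samples"
            )
        self._Xt = X
        self.classes_ = classes
        self.n_features_ = X.shape[1]
        self._y_idx = np.searchsorted(classes, y)
        self._train_sq = np.einsum("ij,ij->i", X, X)
        self._prepared = True

    def _neighbors(self, X, chunk: int = 512):
        """Yield (neighbor index, squared distance) blocks for test chunks."""
        self._prepare()
        X = self._check_X(X)
        for a in range(0, X.shape[0], chunk):
            block = X[a : a + chunk]
            d2 = (
                np.einsum("ij,ij->i", block, block)[:, None]
                - 2.0 * block @ self._Xt.T
                + self._train_sq[None, :]
            )
            np.maximum(d2, 0.0, out=d2)
            if self.k < d2.shape[1]:
                idx = np.argpartition(d2, self.k - 1, axis=1)[:, : self.k]
            else:
                idx = np.tile(np.arange(d2.shape[1]), (d2.shape[0], 1))
            yield a, idx, np.take_along_axis(d2, idx, axis=1)

    def predict_scores(self, X) -> ScoreMatrix:
        self._prepare()
        n = _as_matrix(X).shape[0]
        k_classes = len(self.classes_)
        votes = np.zeros((n, k_classes))
        for a, idx, _d2 in self._neighbors(X):
            labels = self._y_idx[idx]
            for ci in range(k_classes):
                votes[a : a + idx.shape[0], ci] = (labels == ci).sum(axis=1)
        return ScoreMatrix(votes / self.k, tuple(self.classes_))

    def predict(self, X) -> np.ndarray:
        self._prepare()
        n = _as_matrix(X).shape[0]
        k_classes = len(self.classes_)
        out_idx = np.empty(n, dtype=int)
        for a, idx, d2 in self._neighbors(X):
            labels = self._y_idx[idx]
            votes = np.zeros((idx.shape[0], k_classes))
            dist_sum = np.zeros((idx.shape[0], k_classes))
            d = np.sqrt(d2)
            for ci in range(k_classes):
                mask = labels == ci
                votes[:, ci] = mask.sum(axis=1)
                dist_sum[:, ci] = np.where(mask, d, 0.0).sum(axis=1)
            top = votes.max(axis=1, keepdims=True)
            tied = votes == top
            # ties: smaller summed neighbor distance, then class order
            key = np.where(tied, dist_sum, np.inf)
            out_idx[a : a + idx.shape[0]] = np.argmin(key, axis=1)
        return self.classes_[out_idx]


class RBFSVMClassifier(_BaseModel):
    """RBF-kernel SVM delegated to scikit-learn's SVC (C=1, gamma='scale' =
    1/(p * var(X)) by default), with one-vs-rest decision values mapped
    monotonically to [0, 1] as scores.

    Prediction defers to the delegate, so ties between the score argmax and
    the delegated prediction resolve in the delegate's favor.
    """

    algorithm = "svm"

    def __init__(self, C: float = 1.0, gamma="scale"):
        if C <= 0:
            raise InvalidArgumentError("C must be > 0")
        self.C = C
        self.gamma = gamma

    def fit(self, X, y) -> "RBFSVMClassifier":
        X = _as_matrix(X)
        y = np.asarray(y)
        _validate_training(X, y)
        self._svc = SVC(
            C=self.C,
            gamma=self.gamma,
            kernel="rbf",
            decision_function_shape="ovr",
        ).fit(X, y)
        self.classes_ = self._svc.classes_
        self.n_features_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        return self._svc.predict(self._check_X(X))

    def predict_scores(self, X) -> ScoreMatrix:
        d = self._svc.decision_function(self._check_X(X))
        if d.ndim == 1:  # binary: single margin for classes_[1]
            d = np.column_stack([-d, d])
        scores = 1.0 / (1.0 + np.exp(-d))
        return ScoreMatrix(scores, tuple(self.classes_))


_MODEL_TYPES = {
    "lda": LDAClassifier,
    "nbc": GaussianNBClassifier,
    "knn": KNNClassifier,
    "svm": RBFSVMClassifier,
}


def fit(algorithm: str, X, y, **hyperparams) -> _BaseModel:
    """Train one of the four algorithms; returns the fitted model.

    X may be an array or the feature block of a feature table.  KNN defers
    validation to prediction time (its training is storage only); the other
    algorithms validate eagerly.
    """
    if algorithm not in _MODEL_TYPES:
        raise InvalidArgumentError(
            f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}"
        )
    model = _MODEL_TYPES[algorithm](**hyperparams)
    return model.fit(X, y)


def predict(model: _BaseModel, X) -> np.ndarray:
    return model.predict(X)


def predict_scores(model: _BaseModel, X) -> ScoreMatrix:
    return model.predict_scores(X)


def timed_fit(algorithm: str, X, y, **hyperparams) -> tuple[_BaseModel, float]:
    """Fit and return (model, wall-clock seconds)."""
    t0 = time.perf_counter()
    model = fit(algorithm, X, y, **hyperparams)
    return model, time.perf_counter() - t0


# ---------------------------------------------------------------------------
# Serialization (versioned JSON-compatible dictionaries)
# ---------------------------------------------------------------------------


def model_to_dict(model: _BaseModel) -> dict:
    """Serialize a fitted model to a JSON-compatible dictionary."""
    d: dict = {
        "schema_version": SERIALIZATION_VERSION,
        "algorithm": model.algorithm,
    }
    if isinstance(model, LDAClassifier):
        d.update(
            ridge=model.ridge,
            classes=model.classes_.tolist(),
            means=model.means_.tolist(),
            priors=model.priors_.tolist(),
            covariance=model.covariance_.tolist(),
        )
    elif isinstance(model, GaussianNBClassifier):
        d.update(
            floor_ratio=model.floor_ratio,
            classes=model.classes_.tolist(),
            means=model.means_.tolist(),
            variances=model.variances_.tolist(),
            priors=model.priors_.tolist(),
        )
    elif isinstance(model, KNNClassifier):
        model._prepare()
        d.update(
            k=model.k,
            metric=model.metric,
            X=model._Xt.tolist(),
            y=np.asarray(model._y).tolist(),
        )
    elif isinstance(model, RBFSVMClassifier):
        d.update(
            C=model.C,
            gamma=model.gamma if isinstance(model.gamma, str) else float(model.gamma),
            delegate=base64.b64encode(pickle.dumps(model._svc)).decode("ascii"),
        )
    else:  # pragma: no cover
        raise InvalidArgumentError(f"cannot serialize {type(model).__name__}")
    return d


def model_from_dict(d: dict) -> _BaseModel:
    """Rebuild a model serialized by :func:`model_to_dict`."""
    version = d.get("schema_version")
    if version != SERIALIZATION_VERSION:
        raise InvalidArgumentError(
            f"unsupported model schema version {version!r}"
        )
    algo = d["algorithm"]
    if algo == "lda":
        m = LDAClassifier(ridge=d["ridge"])
        m.classes_ = np.asarray(d["classes"])
        m.means_ = np.asarray(d["means"], dtype=float)
        m.priors_ = np.asarray(d["priors"], dtype=float)
        m.covariance_ = np.asarray(d["covariance"], dtype=float)
        m.n_features_ = m.means_.shape[1]
        cho = scipy.linalg.cho_factor(m.covariance_, check_finite=False)
        m.coef_ = scipy.linalg.cho_solve(cho, m.means_.T, check_finite=False)
        m.intercept_ = (
            -0.5 * np.einsum("kp,pk->k", m.means_, m.coef_) + np.log(m.priors_)
        )
        return m
    if algo == "nbc":
        m = GaussianNBClassifier(floor_ratio=d["floor_ratio"])
        m.classes_ = np.asarray(d["classes"])
        m.means_ = np.asarray(d["means"], dtype=float)
        m.variances_ = np.asarray(d["variances"], dtype=float)
        m.priors_ = np.asarray(d["priors"], dtype=float)
        m.n_features_ = m.means_.shape[1]
        return m
    if algo == "knn":
        m = KNNClassifier(k=d["k"], metric=d["metric"])
        return m.fit(np.asarray(d["X"], dtype=float), np.asarray(d["y"]))
    if algo == "svm":
        m = RBFSVMClassifier(C=d["C"], gamma=d["gamma"])
        m._svc = pickle.loads(base64.b64decode(d["delegate"]))
        m.classes_ = m._svc.classes_
        m.n_features_ = m._svc.n_features_in_
        return m
    raise InvalidArgumentError(f"unknown algorithm {algo!r} in serialized model")
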