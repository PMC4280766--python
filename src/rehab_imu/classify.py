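"""Train-fold-only standardization + PCA, logistic regression, and the
one-vs-all classifier bank.

To avoid over-fitting the high-dimensional feature vector, features are
z-scored with training-fold statistics and reduced by PCA, retaining the
smallest number of leading components whose cumulative explained
variance reaches 99%.  Both the standardization statistics and the
loadings are estimated on the training fold only; held-out data is
projected with those frozen coefficients.

Binary decisions use a single ridge-stabilised logistic regression.
Error identification uses a bank of one-vs-all logistic models, one per
class; the predicted class is the one with the highest positive-class
probability, with exact ties resolved in favour of the class most
frequent in the training fold (then lexicographically).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

DEFAULT_VARIANCE_THRESHOLD = 0.99
DEFAULT_RIDGE = 1e-4


@dataclasses.dataclass
class ProjectionModel:
    """Frozen training-fold standardization + PCA loadings."""

    feature_mean: np.ndarray
    feature_scale: np.ndarray
    center: np.ndarray              # mean of the standardized training data
    components: np.ndarray          # (k, d), orthonormal rows
    explained_variance: np.ndarray  # (k,), of the retained components
    explained_variance_ratio: np.ndarray  # full spectrum
    k: int

    @property
    def n_features(self) -> int:
        return int(self.feature_mean.size)


def fit_projection(
    training_features: np.ndarray,
    var_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> ProjectionModel:
    """Standardize with training statistics and fit PCA, retaining the
    smallest k with cumulative explained variance >= *var_threshold*.

    Zero-variance features are kept with their scale treated as 1.
    """
    X = np.asarray(training_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need a 2-D matrix with >= 2 trials and >= 1 feature")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / scale
    pca = PCA(svd_solver="full").fit(Z)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    k = int(np.argmax(cum >= var_threshold - 1e-12)) + 1
    return ProjectionModel(
        feature_mean=mean,
        feature_scale=scale,
        center=pca.mean_,
        components=pca.components_[:k].copy(),
        explained_variance=pca.explained_variance_[:k].copy(),
        explained_variance_ratio=ratios.copy(),
        k=k,
    )


def project(model: ProjectionModel, features: np.ndarray) -> np.ndarray:
    """Apply the frozen standardization and loadings; never re-fits."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model "
            f"({model.n_features})"
        )
    Z = (X - model.feature_mean) / model.feature_scale
    return (Z - model.center) @ model.components.T


def reconstruct(model: ProjectionModel, scores: np.ndarray) -> np.ndarray:
    """Map component scores back to the original feature space."""
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    Z = S @ model.components + model.center
    return Z * model.feature_scale + model.feature_mean


@dataclasses.dataclass
class LogisticModel:
    """Binary logistic regression: P(positive | x) = sigmoid(w.x + b)."""

    weights: np.ndarray
    intercept: float
    lam: float
    positive_class: object
    negative_class: object


def _fit_logistic_core(
    X: np.ndarray, t: np.ndarray, lam: float
) -> tuple[np.ndarray, float]:
    """Penalized ML fit: maximize sum log-lik - (lam/2)||w||^2 (intercept
    unpenalized)."""
    if lam < 0:
        raise ValueError("regularization strength must be >= 0")
    if lam == 0:
        clf = LogisticRegression(penalty=None, solver="lbfgs",
                                 tol=1e-10, max_iter=2000)
    else:
        clf = LogisticRegression(C=1.0 / lam, solver="lbfgs",
                                 tol=1e-10, max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, t)
    # sklearn orders classes_ ascending; align sign with t == 1 positive
    w = clf.coef_[0]
    b = float(clf.intercept_[0])
    if clf.classes_[1] != 1:  # pragma: no cover - t is always 0/1
        w, b = -w, -b
    return w, b


def fit_logistic(
    X: np.ndarray,
    y: Sequence,
    lam: float = DEFAULT_RIDGE,
    positive_class: object | None = None,
) -> LogisticModel:
    """Fit a binary logistic regression with ridge penalty ``lam``.

    ``y`` may be boolean, 0/1, or two arbitrary labels with
    ``positive_class`` naming the positive one.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    classes = sorted(set(y.tolist()), key=repr)
    if len(classes) != 2:
        raise ValueError(
            f"logistic regression needs exactly 2 classes, got {classes}; "
            "curation should remove degenerate folds"
        )
    if positive_class is None:
        if set(classes) == {0, 1}:
            positive_class = 1
        elif set(classes) == {False, True}:
            positive_class = True
        else:
            raise ValueError("positive_class is required for non-binary labels")
    if positive_class not in classes:
        raise ValueError(f"positive_class {positive_class!r} absent from y")
    negative_class = next(c for c in classes if c != positive_class)
    t = (y == positive_class).astype(int)
    w, b = _fit_logistic_core(X, t, lam)
    return LogisticModel(
        weights=w, intercept=b, lam=lam,
        positive_class=positive_class, negative_class=negative_class,
    )


def decision_values(model: LogisticModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.weights.size:
        raise ValueError(
            f"dimension mismatch: x has {X.shape[1]} features, "
            f"model expects {model.weights.size}"
        )
    return X @ model.weights + model.intercept


def predict_proba(model: LogisticModel, X: np.ndarray) -> np.ndarray:
    """P(positive class) for each row of X."""
    return expit(decision_values(model, X))


def predict_binary(model: LogisticModel, x: np.ndarray) -> tuple[object, float]:
    """Label and positive-class probability for one feature vector;
    the positive class is chosen iff its probability is >= 0.5."""
    p = float(predict_proba(model, np.atleast_2d(x))[0])
    label = model.positive_class if p >= 0.5 else model.negative_class
    return label, p


@dataclasses.dataclass
class ClassifierBank:
    """One-vs-all logistic models plus training-fold class counts."""

    models: dict[object, LogisticModel]
    training_prevalence: dict[object, int]

    def classes(self) -> tuple:
        return tuple(self.models.keys())


def fit_bank(
    X: np.ndarray, labels: Sequence, lam: float = DEFAULT_RIDGE
) -> ClassifierBank:
    """Fit one logistic model per class (that class positive, the rest
    negative)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 distinct labels")
    counts = {c: int(np.sum(labels == c)) for c in classes}
    rare = [c for c, n in counts.items() if n < 2]
    if rare:
        raise ValueError(
            f"classes with fewer than 2 examples: {rare}; curation should "
            "have removed them"
        )
    models = {}
    for c in classes:
        t = labels == c
        w, b = _fit_logistic_core(X, t.astype(int), lam)
        models[c] = LogisticModel(
            weights=w, intercept=b, lam=lam,
            positive_class=c, negative_class=f"not:{c}",
        )
    return ClassifierBank(models=models, training_prevalence=counts)


def bank_probabilities(bank: ClassifierBank, X: np.ndarray) -> dict[object, np.ndarray]:
    return {c: predict_proba(m, X) for c, m in bank.models.items()}


def predict_multiclass(bank: ClassifierBank, x: np.ndarray) -> object:
    """Argmax of per-class positive probabilities.

    On an exact probability tie the class with the larger training
    prevalence wins; if prevalences also tie, the lexicographically first
    class (a documented, deterministic convention).
    """
    if not bank.models:
        raise ValueError("empty classifier bank")
    probs = {c: float(predict_proba(m, np.atleast_2d(x))[0])
             for c, m in bank.models.items()}
    best = max(probs.values())
    candidates = [c for c, p in probs.items() if p == best]
    candidates.sort(key=lambda c: (-bank.training_prevalence[c], str(c)))
    return candidates[0]


# ---------------------------------------------------------------------------
# JSON model bundles (inspectable, exact reload)
# ---------------------------------------------------------------------------


def _logistic_to_dict(m: LogisticModel) -> dict:
    return {
        "weights": m.weights.tolist(),
        "intercept": m.intercept,
        "lam": m.lam,
        "positive_class": m.positive_class,
        "negative_class": m.negative_class,
    }


def _logistic_from_dict(d: Mapping) -> LogisticModel:
    return LogisticModel(
        weights=np.asarray(d["weights"], dtype=float),
        intercept=float(d["intercept"]),
        lam=float(d["lam"]),
        positive_class=d["positive_class"],
        negative_class=d["negative_class"],
    )


def save_bundle(
    path: str | Path,
    projection: ProjectionModel,
    models: LogisticModel | ClassifierBank,
) -> None:
    """Serialize a projection + classifier(s) as a JSON bundle."""
    proj = {
        "feature_mean": projection.feature_mean.tolist(),
        "feature_scale": projection.feature_scale.tolist(),
        "center": projection.center.tolist(),
        "components": projection.components.tolist(),
        "explained_variance": projection.explained_variance.tolist(),
        "explained_variance_ratio": projection.explained_variance_ratio.tolist(),
        "k": projection.k,
    }
    if isinstance(models, ClassifierBank):
        clf = {
            "kind": "bank",
            "models": {str(c): _logistic_to_dict(m)
                       for c, m in models.models.items()},
            "training_prevalence": {str(c): n for c, n in
                                    models.training_prevalence.items()},
        }
    else:
        clf = {"kind": "binary", "model": _logistic_to_dict(models)}
    Path(path).write_text(
        json.dumps({"projection": proj, "classifier": clf}, indent=1)
    )


def load_bundle(path: str | Path) -> tuple[ProjectionModel, LogisticModel | ClassifierBank]:
    d = json.loads(Path(path).read_text())
    p = d["projection"]
    projection = ProjectionModel(
        feature_mean=np.asarray(p["feature_mean"], dtype=float),
        feature_scale=np.asarray(p["feature_scale"], dtype=float),
        center=np.asarray(p["center"], dtype=float),
        components=np.asarray(p["components"], dtype=float),
        explained_variance=np.asarray(p["explained_variance"], dtype=float),
        explained_variance_ratio=np.asarray(
            p["explained_variance_ratio"], dtype=float
        ),
        k=int(p["k"]),
    )
    c = d["classifier"]
    if c["kind"] == "bank":
        bank = ClassifierBank(
            models={k: _logistic_from_dict(v) for k, v in c["models"].items()},
            training_prevalence={k: int(v) for k, v in
                                 c["training_prevalence"].items()},
        )
        return projection, bank
    return projection, _logistic_from_dict(c["model"])
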