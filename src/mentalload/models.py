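"""Sixteen classifier presets behind one train/predict/score contract.

Six families — decision trees, discriminant analysis, logistic regression,
SVM, k-nearest-neighbour and ensembles — each in the preset variants of a
point-and-click classification environment:

===================  =========================================================
family               presets
===================  =========================================================
decision_tree        simple / medium / complex   (max 4 / 20 / 100 splits)
discriminant         linear / quadratic
logistic_regression  default                      (2-class tasks only)
svm                  linear / quadratic / cubic   (box constraint 1)
knn                  coarse / medium / fine       (100 / 10 / 1 neighbours)
ensemble             bagged_trees / subspace_discriminant / subspace_knn /
                     rusboost                     (30 learners each)
===================  =========================================================

Scale-sensitive families (SVM, kNN, discriminant, logistic) z-score
standardise features inside the fit, on training rows only; tree ensembles
are left unscaled. Multiclass SVM uses one-vs-one voting with per-class
vote-margin scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = ["ModelSpec", "TrainedModel", "PRESETS", "iter_specs",
           "make_model", "fit", "predict_scores"]

#: family -> tuple of preset names
PRESETS: dict[str, tuple[str, ...]] = {
    "decision_tree": ("simple", "medium", "complex"),
    "discriminant": ("linear", "quadratic"),
    "logistic_regression": ("default",),
    "svm": ("linear", "quadratic", "cubic"),
    "knn": ("coarse", "medium", "fine"),
    "ensemble": ("bagged_trees", "subspace_discriminant", "subspace_knn",
                 "rusboost"),
}

_SCALED_FAMILIES = {"discriminant", "logistic_regression", "svm", "knn"}
_N_ENSEMBLE = 30


@dataclass(frozen=True)
class ModelSpec:
    """A (family, preset) pair plus the seed driving any internal randomness."""

    family: str
    preset: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in PRESETS:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {sorted(PRESETS)}")
        if self.preset not in PRESETS[self.family]:
            raise ValueError(
                f"unknown preset {self.preset!r} for {self.family}; "
                f"valid presets: {list(PRESETS[self.family])}")

    @property
    def name(self) -> str:
        return f"{self.family}/{self.preset}"


def iter_specs(seed: int = 0, n_classes: int = 2) -> list[ModelSpec]:
    """All sixteen presets (fifteen for multiclass tasks, where logistic
    regression does not apply)."""
    specs = []
    for family, presets in PRESETS.items():
        if family == "logistic_regression" and n_classes > 2:
            continue
        specs.extend(ModelSpec(family, preset, seed) for preset in presets)
    return specs


class PseudoQuadraticDiscriminant(BaseEstimator, ClassifierMixin):
    """Quadratic discriminant analysis with pseudo-inverse class covariances.

    Class-conditional Gaussians with per-class covariance, inverted by
    eigendecomposition with small eigenvalues discarded (pseudo-determinant
    likewise), so tables wider than the per-class sample count still fit.
    """

    _EIG_RCOND = 1e-10

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.means_, self.pinvs_, self.logpdets_, self.priors_ = [], [], [], []
        for cls in self.classes_:
            sub = X[y == cls]
            mu = sub.mean(axis=0)
            cov = np.cov(sub, rowvar=False, ddof=1)
            cov = np.atleast_2d(cov)
            evals, evecs = np.linalg.eigh(cov)
            keep = evals > max(evals.max(), 0) * self._EIG_RCOND
            if not keep.any():  # degenerate class: identity fallback
                evals = np.ones_like(evals)
                keep = np.ones_like(keep)
            inv = (evecs[:, keep] / evals[keep]) @ evecs[:, keep].T
            self.means_.append(mu)
            self.pinvs_.append(inv)
            self.logpdets_.append(float(np.log(evals[keep]).sum()))
            self.priors_.append(sub.shape[0] / X.shape[0])
        return self

    def _discriminants(self, X):
        X = np.asarray(X, dtype=float)
        g = np.empty((X.shape[0], self.classes_.size))
        for j in range(self.classes_.size):
            d = X - self.means_[j]
            maha = np.einsum("ij,jk,ik->i", d, self.pinvs_[j], d)
            g[:, j] = (-0.5 * maha - 0.5 * self.logpdets_[j]
                       + np.log(self.priors_[j]))
        return g

    def decision_function(self, X):
        g = self._discriminants(X)
        return g[:, 1] - g[:, 0] if self.classes_.size == 2 else g

    def predict_proba(self, X):
        g = self._discriminants(X)
        g = g - g.max(axis=1, keepdims=True)
        p = np.exp(g)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self._discriminants(X), axis=1)]


class RandomUnderSamplingBoost(BaseEstimator, ClassifierMixin):
    """Boosted trees fitted after random under-sampling to the minority
    class count (seeded). On balanced tables the resampling is a no-op and
    the estimator reduces to boosted shallow trees."""

    def __init__(self, n_estimators: int = _N_ENSEMBLE, random_state: int = 0):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        classes, counts = np.unique(y, return_counts=True)
        n_min = counts.min()
        keep = []
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            if idx.size > n_min:
                idx = rng.choice(idx, size=n_min, replace=False)
            keep.append(idx)
        keep = np.sort(np.concatenate(keep))
        self.booster_ = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=3,
                                             random_state=self.random_state),
            n_estimators=self.n_estimators,
            random_state=self.random_state,
        )
        self.booster_.fit(X[keep], y[keep])
        self.classes_ = self.booster_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "booster_")
        return self.booster_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "booster_")
        return self.booster_.predict_proba(X)


def _subspace_dim(n_features: int) -> int:
    return max(1, n_features // 2)


def make_model(spec: ModelSpec, n_classes: int = 2):
    """Configured, untrained scikit-learn estimator for a preset."""
    if spec.family == "logistic_regression" and n_classes > 2:
        raise ValueError("logistic regression applies to 2-class tasks only")
    fam, preset, seed = spec.family, spec.preset, spec.seed
    if fam == "decision_tree":
        max_splits = {"simple": 4, "medium": 20, "complex": 100}[preset]
        est = DecisionTreeClassifier(max_leaf_nodes=max_splits + 1,
                                     random_state=seed)
    elif fam == "discriminant":
        est = (LinearDiscriminantAnalysis() if preset == "linear"
               else PseudoQuadraticDiscriminant())
    elif fam == "logistic_regression":
        est = LogisticRegression(max_iter=1000, random_state=seed)
    elif fam == "svm":
        degree = {"linear": 1, "quadratic": 2, "cubic": 3}[preset]
        if degree == 1:
            est = SVC(kernel="linear", C=1.0, random_state=seed)
        else:
            est = SVC(kernel="poly", degree=degree, coef0=1.0, C=1.0,
                      gamma="scale", random_state=seed)
    elif fam == "knn":
        k = {"coarse": 100, "medium": 10, "fine": 1}[preset]
        est = KNeighborsClassifier(n_neighbors=k)
    else:  # ensemble
        if preset == "bagged_trees":
            est = BaggingClassifier(
                estimator=DecisionTreeClassifier(random_state=seed),
                n_estimators=_N_ENSEMBLE, random_state=seed)
        elif preset == "subspace_discriminant":
            est = BaggingClassifier(
                estimator=LinearDiscriminantAnalysis(),
                n_estimators=_N_ENSEMBLE, bootstrap=False, max_features=0.5,
                random_state=seed)
        elif preset == "subspace_knn":
            est = BaggingClassifier(
                estimator=KNeighborsClassifier(n_neighbors=10),
                n_estimators=_N_ENSEMBLE, bootstrap=False, max_features=0.5,
                random_state=seed)
        else:  # rusboost
            est = RandomUnderSamplingBoost(n_estimators=_N_ENSEMBLE,
                                           random_state=seed)
    if fam in _SCALED_FAMILIES:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass
class TrainedModel:
    """A fitted preset plus the metadata needed for safe prediction."""

    spec: ModelSpec
    estimator: object
    classes: np.ndarray
    feature_names: list[str]


def _design(rows: pd.DataFrame, feature_names: list[str]) -> np.ndarray:
    missing = [c for c in feature_names if c not in rows.columns]
    if missing:
        raise ValueError(f"rows lack feature columns {missing}")
    return rows[feature_names].to_numpy(dtype=float)


def fit(spec: ModelSpec, table: pd.DataFrame,
        feature_names: "list[str] | None" = None) -> TrainedModel:
    """Fit one preset on a labelled feature table.

    ``table`` must carry a ``label`` column and the feature columns; any
    z-score standardisation happens inside the estimator pipeline on the
    training rows only.
    """
    from .features import ID_COLUMNS

    if feature_names is None:
        feature_names = [c for c in table.columns if c not in ID_COLUMNS]
    y = table["label"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training rows contain a single class")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 training rows")
    X = _design(table, feature_names)
    est = make_model(spec, n_classes=classes.size)
    if isinstance(est, Pipeline):
        inner = est.named_steps["clf"]
        if isinstance(inner, KNeighborsClassifier):
            inner.set_params(n_neighbors=min(inner.n_neighbors, len(X)))
    est.fit(X, y)
    fitted_classes = getattr(est, "classes_", classes)
    return TrainedModel(spec=spec, estimator=est,
                        classes=np.asarray(fitted_classes),
                        feature_names=list(feature_names))


def predict_scores(model: TrainedModel, rows: pd.DataFrame
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-class scores (higher = more likely) and argmax labels.

    Ties break deterministically toward the lowest class index.
    """
    X = _design(rows, model.feature_names)
    est = model.estimator
    if hasattr(est, "predict_proba"):
        scores = np.asarray(est.predict_proba(X))
    else:
        raw = np.asarray(est.decision_function(X))
        if raw.ndim == 1:  # binary margin -> two-column score
            scores = np.column_stack([-raw, raw])
        else:
            scores = raw
    # argmax with lowest-index tie-break (np.argmax already breaks ties low)
    labels = model.classes[np.argmax(scores, axis=1)]
    return scores, labels
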