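"""Cross-validated stacked ensemble with non-negative least-squares weights.

A registry of base classifiers is fit with V-fold cross-validation; the
out-of-fold probability matrix ``Z`` is combined by solving
``min ||y - Z a||^2, a >= 0`` and normalising ``a`` to sum to one.  Base
learners that fail on any fold are dropped with a warning instead of aborting
the run — the subsampling engine performs thousands of small fits and must
degrade gracefully.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.dummy import DummyClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "LearnerSpec",
    "SLFit",
    "DEFAULT_LIBRARY",
    "FAST_LIBRARY",
    "build_learner",
    "make_folds",
    "cv_predictions",
    "nnls_weights",
    "fit_superlearner",
    "predict",
    "classify",
]


@dataclass(frozen=True)
class LearnerSpec:
    """A named base classifier plus hyperparameter overrides."""

    name: str
    params: dict = field(default_factory=dict)


def _glm(seed, **p):
    return LogisticRegression(C=np.inf, max_iter=p.pop("max_iter", 500), **p)


def _ridge(seed, **p):
    return LogisticRegression(C=p.pop("C", 1.0), max_iter=p.pop("max_iter", 500), **p)


def _lasso(seed, **p):
    return LogisticRegression(l1_ratio=1.0, C=p.pop("C", 1.0), solver="liblinear",
                              random_state=seed, max_iter=p.pop("max_iter", 500), **p)


def _rf(seed, **p):
    return RandomForestClassifier(n_estimators=p.pop("n_estimators", 100),
                                  random_state=seed, **p)


def _knn(seed, **p):
    return KNeighborsClassifier(n_neighbors=p.pop("n_neighbors", 5), **p)


def _constant(seed, **p):
    return DummyClassifier(strategy="prior", **p)


_REGISTRY = {
    "glm": _glm,
    "ridge": _ridge,
    "lasso": _lasso,
    "rf": _rf,
    "knn": _knn,
    "constant": _constant,
}

#: full minimum library
DEFAULT_LIBRARY = ("glm", "ridge", "lasso", "rf", "knn", "constant")
#: cheap library suited to thousands of subsample fits
FAST_LIBRARY = ("glm", "knn", "constant")


def register_learner(name: str, factory) -> None:
    """Extend the registry: ``factory(seed, **params) -> sklearn estimator``."""
    _REGISTRY[name] = factory


def available_learners() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def _as_spec(learner) -> LearnerSpec:
    return learner if isinstance(learner, LearnerSpec) else LearnerSpec(str(learner))


def build_learner(spec, seed: int = 0, n_train: int | None = None):
    """Instantiate a registered learner; seeds make the build deterministic."""
    spec = _as_spec(spec)
    if spec.name not in _REGISTRY:
        raise KeyError(
            f"unknown learner {spec.name!r}; registered: {available_learners()}"
        )
    params = dict(spec.params)
    if spec.name == "knn" and n_train is not None:
        params.setdefault("n_neighbors", max(1, min(5, n_train)))
    return _REGISTRY[spec.name](seed, **params)


def _proba_one(model, X) -> np.ndarray:
    """P(y = 1) per row, clipped to [0, 1]."""
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    if 1 in classes:
        p = proba[:, classes.index(1)]
    else:  # trained on a single-class fold
        p = np.zeros(len(X))
    return np.clip(p, 0.0, 1.0)


def make_folds(
    n: int,
    V: int,
    seed: int = 0,
    groups=None,
    strata=None,
) -> np.ndarray:
    """Outcome-stratified fold assignment.

    Without ``groups``: indices are dealt round-robin within a continuous
    per-class sequence, so overall fold sizes differ by at most one and each
    class is spread evenly.  With ``groups`` every row of a group lands in
    one fold (groups are dealt, largest first, to the currently smallest
    fold of their class sequence); exact size balance is then best-effort.
    """
    if V < 2:
        raise ValueError("V must be >= 2")
    if V > n:
        raise ValueError(f"V={V} exceeds n={n}")
    rng = np.random.default_rng(seed)
    strata = np.zeros(n, dtype=int) if strata is None else np.asarray(strata)
    folds = np.empty(n, dtype=int)

    if groups is None:
        pos = 0
        offset = int(rng.integers(V))
        for cls in np.unique(strata):
            idx = np.flatnonzero(strata == cls)
            rng.shuffle(idx)
            for i in idx:
                folds[i] = (pos + offset) % V
                pos += 1
        return folds

    groups = np.asarray(groups)
    sizes = np.zeros(V, dtype=float)
    for cls in np.unique(strata):
        cls_groups = np.unique(groups[strata == cls])
        rng.shuffle(cls_groups)
        cls_groups = sorted(
            cls_groups, key=lambda g: -int((groups == g).sum())
        )
        for g in cls_groups:
            rows = np.flatnonzero(groups == g)
            f = int(np.argmin(sizes))
            folds[rows] = f
            sizes[f] += len(rows)
    return folds


def cv_predictions(
    X: np.ndarray,
    y: np.ndarray,
    library,
    folds: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, list[LearnerSpec]]:
    """Out-of-fold probability matrix ``Z`` (rows x surviving learners).

    ``Z[i, l]`` comes from learner ``l`` trained without row ``i``'s fold.
    A learner raising on any fold loses its whole column (with a warning).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    specs = [_as_spec(l) for l in library]
    if not specs:
        raise ValueError("empty learner library")
    fold_ids = np.unique(folds)
    columns, kept = [], []
    for li, spec in enumerate(specs):
        col = np.empty(len(y), dtype=float)
        try:
            for f in fold_ids:
                test = folds == f
                train = ~test
                model = build_learner(spec, seed=seed + 1000 * li + int(f),
                                      n_train=int(train.sum()))
                with warnings.catch_warnings():
                    # non-convergence on tiny/separable folds is routine noise
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    model.fit(X[train], y[train])
                col[test] = _proba_one(model, X[test])
        except Exception as exc:  # noqa: BLE001 — degrade, don't abort
            warnings.warn(f"learner {spec.name!r} failed during CV and was dropped: {exc}")
            continue
        columns.append(col)
        kept.append(spec)
    if not columns:
        raise RuntimeError("all learners failed during cross-validation")
    return np.column_stack(columns), kept


def nnls_weights(Z: np.ndarray, y: np.ndarray, cv_risk=None) -> np.ndarray:
    """Convex meta-weights: NNLS solution normalised to sum to one.

    If the solver returns all zeros (possible when every column overshoots),
    unit weight goes to the learner with the lowest CV risk.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 1:
        raise ValueError("Z must be a nonempty 2D matrix")
    w, _ = nnls(Z, y)
    if w.sum() <= 0:
        risk = np.mean((Z - y[:, None]) ** 2, axis=0) if cv_risk is None else np.asarray(cv_risk)
        w = np.zeros(Z.shape[1])
        w[int(np.argmin(risk))] = 1.0
    return w / w.sum()


@dataclass
class SLFit:
    """A fitted stacked ensemble."""

    learners: list[LearnerSpec]
    V: int
    folds: np.ndarray
    cv_risk: np.ndarray
    weights: np.ndarray
    models: list
    oof_pred: np.ndarray
    cv_accuracy: float
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.weights < -1e-12) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be a convex combination")
        if not np.isfinite(self.cv_risk).all():
            raise ValueError("cv_risk must be finite")


def fit_superlearner(
    X: np.ndarray,
    y: np.ndarray,
    library=DEFAULT_LIBRARY,
    V: int = 10,
    seed: int = 0,
    groups=None,
) -> SLFit:
    """Fit the cross-validated NNLS-stacked ensemble.

    ``V`` is reduced automatically when a class has fewer members than folds,
    keeping every training fold two-class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    V_eff = int(max(2, min(V, counts.min())))
    folds = make_folds(len(y), V_eff, seed=seed, groups=groups, strata=y)
    Z, kept = cv_predictions(X, y, library, folds, seed=seed)
    cv_risk = np.mean((Z - y[:, None]) ** 2, axis=0)
    weights = nnls_weights(Z, y, cv_risk=cv_risk)
    oof = np.clip(Z @ weights, 0.0, 1.0)
    cv_accuracy = float(np.mean((oof >= 0.5).astype(int) == y))

    models, final_specs, final_w = [], [], []
    for spec, w in zip(kept, weights):
        try:
            model = build_learner(spec, seed=seed + 7, n_train=len(y))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(X, y)
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"learner {spec.name!r} failed on the full data: {exc}")
            continue
        models.append(model)
        final_specs.append(spec)
        final_w.append(w)
    if not models:
        raise RuntimeError("all learners failed on the full data")
    final_w = np.asarray(final_w, dtype=float)
    if final_w.sum() <= 0:
        final_w = np.ones(len(final_w))
    final_w = final_w / final_w.sum()
    kept_idx = [kept.index(s) for s in final_specs]

    return SLFit(
        learners=final_specs,
        V=V_eff,
        folds=folds,
        cv_risk=cv_risk[kept_idx],
        weights=final_w,
        models=models,
        oof_pred=oof,
        cv_accuracy=cv_accuracy,
        seed=seed,
    )


def predict(fit: SLFit, X: np.ndarray) -> np.ndarray:
    """Ensemble probability: weighted combination of full-data refits."""
    X = np.asarray(X, dtype=float)
    p = np.zeros(len(X))
    for w, model in zip(fit.weights, fit.models):
        if w > 0:
            p += w * _proba_one(model, X)
    return np.clip(p, 0.0, 1.0)


def classify(fit: SLFit, X: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    return (predict(fit, X) >= cutoff).astype(int)
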