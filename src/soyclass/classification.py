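"""Multinomial classifiers on markers -> yield classes with repeated CV.

Two model families are supported: a multinomial elastic-net logistic
regression (lasso + ridge penalties, features standardised internally) and a
random forest with class probabilities taken from tree vote fractions.

The evaluation protocol mirrors repeated hold-out with nested tuning: in
each outer repetition the data are split into stratified 80/20 training and
testing subsets; hyperparameters are chosen on the 80% alone by inner
stratified k-fold cross-validation (5-fold x 5 repeats by default); the
tuned model is refit on the full training subset and the held-out 20% is
predicted.  Out-of-fold predictions are pooled across repetitions.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score, make_scorer
from sklearn.model_selection import (GridSearchCV, RepeatedStratifiedKFold,
                                     train_test_split)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .markers import MarkerMatrix
from .selection_index import CLASS_ORDER

logger = logging.getLogger(__name__)

PROBA_COLUMNS = {"low": "p_low", "moderate": "p_moderate", "high": "p_high"}


@dataclasses.dataclass
class CVProtocol:
    """Repeated stratified 80/20 evaluation with nested tuning."""

    outer_reps: int = 10
    outer_test_fraction: float = 0.20
    inner_folds: int = 5
    inner_repeats: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.outer_test_fraction < 1:
            raise ValueError("outer_test_fraction must be in (0, 1)")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")


@dataclasses.dataclass
class ModelSpec:
    """A model family with its tuning grid.

    ``tuning_grid`` of ``None`` selects the documented defaults: for the
    elastic net, mixing parameter in {0.1, 0.55, 1.0} crossed with 10 penalty
    values log-spaced down from the data-derived maximum; for the random
    forest, 500 trees with candidate features per split in
    {sqrt(m)/2, sqrt(m), 2 sqrt(m)}.
    """

    family: str = "elastic_net_multinomial"
    tuning_grid: list | dict | None = None
    final_metric: str = "accuracy"

    def __post_init__(self) -> None:
        if self.family not in ("elastic_net_multinomial", "random_forest"):
            raise ValueError(f"unknown model family {self.family!r}")
        if isinstance(self.tuning_grid, (list, dict)) and not self.tuning_grid:
            raise ValueError("tuning grid must be non-empty")


def build_estimator(spec: ModelSpec):
    if spec.family == "elastic_net_multinomial":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(
                solver="saga", l1_ratio=0.5, max_iter=5000, tol=1e-4)),
        ])
    return RandomForestClassifier(n_estimators=500, n_jobs=1)


def elastic_net_default_grid(X: np.ndarray, y: np.ndarray,
                             l1_ratios=(0.1, 0.55, 1.0),
                             n_lambda: int = 10, eps: float = 1e-3) -> list[dict]:
    """Penalty path from the data-derived maximum, glmnet style.

    lambda_max is the smallest penalty that zeroes all coefficients under the
    pure lasso; for mixing parameter a it scales as lambda_max / a, and the
    path descends log-linearly to ``eps * lambda_max`` over ``n_lambda``
    points.  sklearn's C is 1 / (n * lambda).
    """
    n = len(y)
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    classes = np.unique(y)
    Y = np.array([(y == c).astype(float) for c in classes]).T
    R = Y - Y.mean(axis=0)
    lam_max_l1 = np.abs(Xs.T @ R).max() / n
    grid = []
    for a in l1_ratios:
        lam_max = lam_max_l1 / max(a, 1e-3)
        lams = lam_max * np.logspace(0.0, np.log10(eps), n_lambda)
        grid.append({
            "clf__l1_ratio": [a],
            "clf__C": sorted(1.0 / (n * lams)),
        })
    return grid


def rf_default_grid(n_markers: int) -> dict:
    root = np.sqrt(n_markers)
    feats = sorted({max(1, int(round(root / 2))), max(1, int(round(root))),
                    max(1, int(round(2 * root)))})
    return {"max_features": feats}


def _resolve_grid(spec: ModelSpec, X, y):
    if spec.tuning_grid is not None:
        return spec.tuning_grid
    if spec.family == "elastic_net_multinomial":
        return elastic_net_default_grid(X, y)
    return rf_default_grid(X.shape[1])


def _scorer(metric: str):
    if metric == "accuracy":
        return "accuracy"
    if metric == "kappa":
        return make_scorer(cohen_kappa_score)
    raise ValueError(f"unknown tuning metric {metric!r}")


def _align_classes(markers: MarkerMatrix, classes) -> np.ndarray:
    """Map marker genotypes to class labels; classes may be the MSI table."""
    if isinstance(classes, pd.DataFrame):
        series = classes.set_index("genotype")["yield_class"]
    else:
        series = pd.Series(classes)
    y = series.reindex(markers.genotype_ids)
    if y.isna().any():
        miss = list(markers.genotype_ids[y.isna().to_numpy()])[:5]
        raise ValueError(f"no class label for genotypes: {miss}")
    bad = set(y.unique()) - set(CLASS_ORDER)
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    return y.to_numpy(object)


def _ordered_proba(model, X) -> np.ndarray:
    raw = model.predict_proba(X)
    cls = list(model.classes_)
    cols = []
    for c in CLASS_ORDER:
        cols.append(raw[:, cls.index(c)] if c in cls else np.zeros(len(X)))
    return np.column_stack(cols)


def _fit_tuned(spec: ModelSpec, protocol: CVProtocol, X, y, random_state: int):
    est = build_estimator(spec)
    grid = _resolve_grid(spec, X, y)
    inner = RepeatedStratifiedKFold(
        n_splits=protocol.inner_folds, n_repeats=protocol.inner_repeats,
        random_state=random_state)
    gs = GridSearchCV(est, grid, scoring=_scorer(spec.final_metric),
                      cv=inner, n_jobs=1, refit=True)
    # seed the estimator itself where applicable
    params = est.get_params()
    for key in ("random_state", "clf__random_state"):
        if key in params:
            gs.estimator = clone(est).set_params(**{key: random_state})
            break
    gs.fit(X, y)
    return gs


def run_repeated_cv(
    markers: MarkerMatrix,
    classes,
    spec: ModelSpec,
    protocol: CVProtocol | None = None,
) -> pd.DataFrame:
    """Pooled out-of-fold class predictions and probabilities.

    Returns one record per (genotype, repetition) in the test splits with
    columns genotype_id, repetition, true_class, predicted_class, p_low,
    p_moderate, p_high.  Ties in predicted probability break deterministically
    in the fixed class order low < moderate < high.
    """
    protocol = protocol or CVProtocol()
    if not markers.is_complete:
        raise ValueError("classification requires a complete (imputed) marker matrix")
    y = _align_classes(markers, classes)
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise ValueError(f"each class needs >= 2 observations, got {counts.to_dict()}")
    X = markers.codes
    idx = np.arange(len(y))

    records = []
    for rep in range(protocol.outer_reps):
        train_idx = test_idx = None
        for attempt in range(20):
            rs = (protocol.seed + 7919 * rep + attempt) % (2**31 - 1)
            tr, te = train_test_split(
                idx, test_size=protocol.outer_test_fraction, random_state=rs,
                stratify=y if protocol.stratified else None)
            if set(y[tr]) == set(np.unique(y)):
                train_idx, test_idx = tr, te
                break
            logger.warning("repetition %d attempt %d lacked a class in training; resampling",
                           rep, attempt)
        if train_idx is None:
            raise RuntimeError(f"could not build a training split covering all classes (rep {rep})")
        gs = _fit_tuned(spec, protocol, X[train_idx], y[train_idx], random_state=rs + 1)
        proba = _ordered_proba(gs.best_estimator_, X[test_idx])
        pred = np.asarray(CLASS_ORDER, dtype=object)[np.argmax(proba, axis=1)]
        for k, i in enumerate(test_idx):
            records.append((markers.genotype_ids[i], rep, y[i], pred[k],
                            proba[k, 0], proba[k, 1], proba[k, 2]))
    out = pd.DataFrame(records, columns=[
        "genotype_id", "repetition", "true_class", "predicted_class",
        "p_low", "p_moderate", "p_high"])
    psum = out[["p_low", "p_moderate", "p_high"]].sum(axis=1)
    if not np.allclose(psum, 1.0, atol=1e-8):
        raise AssertionError("class probabilities do not sum to 1")
    return out


@dataclasses.dataclass
class FinalModel:
    """A tuned classifier fitted on all data, for screening new genotypes."""

    spec: ModelSpec
    protocol: CVProtocol
    marker_ids: np.ndarray
    model: object
    chosen_params: dict
    cv_score: float

    def predict_proba(self, markers: MarkerMatrix) -> pd.DataFrame:
        if list(markers.marker_ids) != list(self.marker_ids):
            extra = sorted(set(markers.marker_ids) - set(self.marker_ids))[:5]
            missing = sorted(set(self.marker_ids) - set(markers.marker_ids))[:5]
            raise ValueError(
                f"marker set mismatch: unexpected {extra}, missing {missing}")
        if not markers.is_complete:
            raise ValueError("prediction requires complete marker rows")
        proba = _ordered_proba(self.model, markers.codes)
        return pd.DataFrame(
            {"genotype_id": markers.genotype_ids,
             "p_low": proba[:, 0], "p_moderate": proba[:, 1], "p_high": proba[:, 2]})

    def predict_class(self, markers: MarkerMatrix) -> pd.Series:
        proba = self.predict_proba(markers)[["p_low", "p_moderate", "p_high"]].to_numpy()
        return pd.Series(np.asarray(CLASS_ORDER, dtype=object)[np.argmax(proba, axis=1)],
                         index=markers.genotype_ids)

    def model_card(self) -> dict:
        return {
            "family": self.spec.family,
            "final_metric": self.spec.final_metric,
            "chosen_hyperparameters": {k: (v.item() if hasattr(v, "item") else v)
                                       for k, v in self.chosen_params.items()},
            "inner_cv_score": float(self.cv_score),
            "seed": self.protocol.seed,
            "inner_folds": self.protocol.inner_folds,
            "inner_repeats": self.protocol.inner_repeats,
        }


def train_final_model(
    markers: MarkerMatrix,
    classes,
    spec: ModelSpec,
    protocol: CVProtocol | None = None,
) -> FinalModel:
    """Tune on all data by inner CV, refit, and wrap for deployment."""
    protocol = protocol or CVProtocol()
    if not markers.is_complete:
        raise ValueError("classification requires a complete (imputed) marker matrix")
    y = _align_classes(markers, classes)
    gs = _fit_tuned(spec, protocol, markers.codes, y,
                    random_state=protocol.seed % (2**31 - 1))
    return FinalModel(
        spec=spec, protocol=protocol, marker_ids=markers.marker_ids.copy(),
        model=gs.best_estimator_, chosen_params=dict(gs.best_params_),
        cv_score=float(gs.best_score_))
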