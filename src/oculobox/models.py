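"""Classifier construction: best-subset and L1-penalized logistic models,
random forests, and repeated stratified cross-validation.

All fits are reproducible under a fixed seed.  Best-subset search is an
exhaustive AIC-scored scan of logistic models up to ``max_subset_size``
predictors; the LASSO penalty is chosen by internal cross-validated
deviance; random forests report the out-of-bag misclassification rate.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .evaluate import roc_auc

_NEAR_ML_C = 1e6  # weak ridge: effectively maximum likelihood, finite under separation
SEPARATION_COEF_LIMIT = 50.0


@dataclass
class ClassifierSpec:
    """Configuration of one classifier build."""

    method: str
    candidate_metrics: list[str]
    max_subset_size: int = 5
    n_trees: int = 500
    threshold: float = 0.5
    missing_policy: str = "drop_rows"       # or "drop_columns"
    lasso_penalty_rule: str = "min_deviance"  # or "1se"

    def __post_init__(self) -> None:
        if self.method not in ("best_subset", "lasso", "random_forest"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.max_subset_size < 1:
            raise ValueError("max_subset_size must be >= 1")
        if self.missing_policy not in ("drop_rows", "drop_columns"):
            raise ValueError("missing_policy must be drop_rows or drop_columns")


@dataclass
class FittedModel:
    """A fitted classifier with enough state to score new subjects."""

    method: str
    selected_metrics: list[str]
    intercept: float = 0.0
    coefficients: dict[str, float] = field(default_factory=dict)
    scaler_mean: dict[str, float] = field(default_factory=dict)
    scaler_scale: dict[str, float] = field(default_factory=dict)
    threshold: float = 0.5
    seed: int | None = None
    apparent_auc: float | None = None
    apparent_misclassification: float | None = None
    oob_error: float | None = None
    forest: RandomForestClassifier | None = None

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Case probability per row of a metric table."""
        X = table[self.selected_metrics].to_numpy(float)
        if self.method == "random_forest":
            if self.forest is None:
                raise ValueError("random forest model has no fitted forest")
            return self.forest.predict_proba(X)[:, 1]
        if self.scaler_mean:
            mu = np.array([self.scaler_mean[m] for m in self.selected_metrics])
            sc = np.array([self.scaler_scale[m] for m in self.selected_metrics])
            X = (X - mu) / sc
        eta = self.intercept + X @ np.array(
            [self.coefficients[m] for m in self.selected_metrics])
        return 1.0 / (1.0 + np.exp(-eta))

    def predict_class(self, table: pd.DataFrame) -> np.ndarray:
        if self.method == "random_forest":
            X = table[self.selected_metrics].to_numpy(float)
            return self.forest.predict(X).astype(bool)
        return self.predict_proba(table) >= self.threshold

    def to_json(self, path=None) -> str:
        if self.method == "random_forest":
            payload = {"method": self.method,
                       "selected_metrics": self.selected_metrics,
                       "oob_error": self.oob_error, "seed": self.seed,
                       "note": "forest state not serialized; refit from data"}
        else:
            payload = {"method": self.method,
                       "selected_metrics": self.selected_metrics,
                       "intercept": self.intercept,
                       "coefficients": self.coefficients,
                       "scaler_mean": self.scaler_mean,
                       "scaler_scale": self.scaler_scale,
                       "threshold": self.threshold, "seed": self.seed,
                       "apparent_auc": self.apparent_auc,
                       "apparent_misclassification": self.apparent_misclassification}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload["method"] == "random_forest":
            raise ValueError("random forest models cannot be restored from JSON")
        return cls(method=payload["method"],
                   selected_metrics=payload["selected_metrics"],
                   intercept=payload["intercept"],
                   coefficients=payload["coefficients"],
                   scaler_mean=payload.get("scaler_mean", {}),
                   scaler_scale=payload.get("scaler_scale", {}),
                   threshold=payload.get("threshold", 0.5),
                   seed=payload.get("seed"),
                   apparent_auc=payload.get("apparent_auc"),
                   apparent_misclassification=payload.get("apparent_misclassification"))


@dataclass
class CVResult:
    mean_auc: float
    mean_misclassification: float  # percent
    n_folds: int
    n_repeats: int
    seed: int
    auc_per_repeat: np.ndarray = field(repr=False, default=None)
    misclassification_per_repeat: np.ndarray = field(repr=False, default=None)


def prepare_training_data(table: pd.DataFrame, labels,
                          spec: ClassifierSpec) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Apply the missing-data policy and return (X, y, usable candidates).

    ``drop_rows`` removes subjects with any missing candidate value
    (complete-case analysis); ``drop_columns`` removes candidates with any
    missing value and keeps all subjects.
    """
    labels = np.asarray(labels, dtype=bool)
    cols = [c for c in spec.candidate_metrics if c in table.columns]
    if len(cols) < len(spec.candidate_metrics):
        missing = set(spec.candidate_metrics) - set(cols)
        raise ValueError(f"candidate metrics absent from table: {sorted(missing)}")
    X = table[cols]
    if spec.missing_policy == "drop_columns":
        cols = [c for c in cols if np.isfinite(X[c].to_numpy(float)).all()]
        X = X[cols]
        keep = np.ones(len(X), dtype=bool)
    else:
        keep = np.isfinite(X.to_numpy(float)).all(axis=1)
        X = X.loc[keep]
    # constant predictors carry no information and break standardization
    usable = []
    for c in cols:
        if np.ptp(X[c].to_numpy(float)) == 0:
            warnings.warn(f"dropping constant predictor {c}")
        else:
            usable.append(c)
    return X[usable], labels[keep], usable


def _log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Near-ML logistic fit; returns (intercept, coefs, log-likelihood)."""
    if X.shape[1] == 0:
        p = y.mean()
        b0 = math.log(p / (1 - p)) if 0 < p < 1 else (20.0 if p == 1 else -20.0)
        return b0, np.zeros(0), _log_likelihood(y, np.full(len(y), y.mean()))
    lr = LogisticRegression(C=_NEAR_ML_C, solver="lbfgs", max_iter=2000)
    lr.fit(X, y)
    prob = lr.predict_proba(X)[:, 1]
    if np.abs(lr.coef_).max() > SEPARATION_COEF_LIMIT:
        warnings.warn("possible separation: coefficients capped by weak penalty")
    return float(lr.intercept_[0]), lr.coef_[0].copy(), _log_likelihood(y, prob)


def _apparent_performance(model: FittedModel, X: pd.DataFrame,
                          y: np.ndarray) -> None:
    scores = model.predict_proba(X)
    _, model.apparent_auc = roc_auc(scores, y)
    pred = scores >= model.threshold
    model.apparent_misclassification = 100.0 * float(np.mean(pred != y))


def fit_best_subset(table: pd.DataFrame, labels, spec: ClassifierSpec,
                    ) -> FittedModel:
    """Exhaustive search over predictor subsets; winner by smallest AIC.

    The intercept-only model is included as the null baseline, so with
    uninformative candidates the search returns no predictors.
    """
    X, y, cols = prepare_training_data(table, labels, spec)
    if not cols:
        raise ValueError("no usable candidate metrics")
    Xv = X.to_numpy(float)
    best = (math.inf, ())
    fits: dict[tuple, tuple] = {}
    for k in range(0, min(spec.max_subset_size, len(cols)) + 1):
        for subset in combinations(range(len(cols)), k):
            b0, coefs, ll = _fit_logistic(Xv[:, list(subset)], y)
            aic = 2 * (k + 1) - 2 * ll
            fits[subset] = (b0, coefs)
            if aic < best[0] - 1e-10:
                best = (aic, subset)
    subset = best[1]
    b0, coefs = fits[subset]
    selected = [cols[i] for i in subset]
    model = FittedModel(method="best_subset", selected_metrics=selected,
                        intercept=b0,
                        coefficients=dict(zip(selected, coefs.tolist())),
                        threshold=spec.threshold)
    _apparent_performance(model, X, y)
    return model


def fit_lasso(table: pd.DataFrame, labels, spec: ClassifierSpec, seed: int = 0,
              penalty: float | None = None) -> FittedModel:
    """L1-penalized logistic fit on internally standardized predictors.

    The penalty is chosen by 4-fold cross-validated deviance under ``seed``
    (``1se`` rule optional); passing ``penalty`` (an inverse-regularization
    C) bypasses the internal selection.
    """
    X, y, cols = prepare_training_data(table, labels, spec)
    if not cols:
        raise ValueError("no usable candidate metrics")
    Xv = X.to_numpy(float)
    mu = Xv.mean(axis=0)
    sc = Xv.std(axis=0, ddof=0)
    Z = (Xv - mu) / sc

    if penalty is not None:
        lr = LogisticRegression(penalty="l1", C=penalty, solver="liblinear",
                                max_iter=5000, random_state=seed)
        lr.fit(Z, y)
        b0, coefs = float(lr.intercept_[0]), lr.coef_[0]
    else:
        cv = StratifiedKFold(4, shuffle=True, random_state=seed)
        lr = LogisticRegressionCV(Cs=np.logspace(-3, 3, 25), penalty="l1",
                                  solver="liblinear", cv=cv,
                                  scoring="neg_log_loss", max_iter=5000,
                                  random_state=seed)
        lr.fit(Z, y)
        if spec.lasso_penalty_rule == "1se":
            scores = lr.scores_[True].mean(axis=0)
            se = lr.scores_[True].std(axis=0, ddof=1) / math.sqrt(cv.get_n_splits())
            best_i = int(np.argmax(scores))
            ok = scores >= scores[best_i] - se[best_i]
            c_1se = lr.Cs_[np.flatnonzero(ok)[0]]  # smallest C within 1 SE
            lr = LogisticRegression(penalty="l1", C=c_1se, solver="liblinear",
                                    max_iter=5000, random_state=seed)
            lr.fit(Z, y)
        b0, coefs = float(lr.intercept_[0]), lr.coef_[0]

    nz = np.flatnonzero(coefs != 0)
    selected = [cols[i] for i in nz]
    model = FittedModel(
        method="lasso", selected_metrics=selected, intercept=b0,
        coefficients={cols[i]: float(coefs[i]) for i in nz},
        scaler_mean={cols[i]: float(mu[i]) for i in nz},
        scaler_scale={cols[i]: float(sc[i]) for i in nz},
        threshold=spec.threshold, seed=seed)
    _apparent_performance(model, X, y)
    return model


def fit_random_forest(table: pd.DataFrame, labels, spec: ClassifierSpec,
                      seed: int = 0) -> FittedModel:
    """Bootstrap tree ensemble; reports OOB misclassification (percent)."""
    X, y, cols = prepare_training_data(table, labels, spec)
    if len(np.unique(y)) < 2:
        raise ValueError("random forest needs both classes present")
    rf = RandomForestClassifier(n_estimators=spec.n_trees, oob_score=True,
                                random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # OOB warning on tiny forests
        rf.fit(X.to_numpy(float), y)
    model = FittedModel(method="random_forest", selected_metrics=list(cols),
                        threshold=spec.threshold, seed=seed, forest=rf,
                        oob_error=100.0 * (1.0 - float(rf.oob_score_)))
    _apparent_performance(model, X, y)
    return model


def fit_model(table: pd.DataFrame, labels, spec: ClassifierSpec,
              seed: int = 0) -> FittedModel:
    if spec.method == "best_subset":
        return fit_best_subset(table, labels, spec)
    if spec.method == "lasso":
        return fit_lasso(table, labels, spec, seed=seed)
    return fit_random_forest(table, labels, spec, seed=seed)


def repeated_cv(table: pd.DataFrame, labels, spec: ClassifierSpec,
                n_folds: int = 4, n_repeats: int = 1000, seed: int = 0,
                _leak_selection: bool = False) -> CVResult:
    """Repeated stratified k-fold CV with model selection inside each fold.

    Out-of-fold case probabilities are pooled within each repeat into one
    AUC and one misclassification rate; means over repeats are reported.
    ``_leak_selection`` (tests only) performs selection once on the full
    data and only refits coefficients per fold — the anti-pattern whose
    optimism the honest mode avoids.
    """
    X, y, cols = prepare_training_data(table, labels, spec)
    spec = ClassifierSpec(**{**spec.__dict__, "candidate_metrics": cols})
    if y.sum() < n_folds or (~y).sum() < n_folds:
        raise ValueError("each class needs at least n_folds members")

    leak_metrics = None
    if _leak_selection:
        leak_metrics = fit_model(X, y, spec, seed=seed).selected_metrics

    rng = np.random.default_rng(seed)
    aucs = np.empty(n_repeats)
    errs = np.empty(n_repeats)
    for r in range(n_repeats):
        skf = StratifiedKFold(n_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        scores = np.empty(len(y))
        for train_idx, test_idx in skf.split(X, y):
            Xtr, ytr = X.iloc[train_idx], y[train_idx]
            if leak_metrics is not None:
                sub = ClassifierSpec(**{**spec.__dict__,
                                        "candidate_metrics": leak_metrics,
                                        "max_subset_size": max(1, len(leak_metrics))})
                b0, coefs, _ = _fit_logistic(
                    Xtr[leak_metrics].to_numpy(float), ytr)
                fold_model = FittedModel(
                    method="best_subset", selected_metrics=leak_metrics,
                    intercept=b0,
                    coefficients=dict(zip(leak_metrics, coefs.tolist())),
                    threshold=spec.threshold)
            else:
                fold_model = fit_model(Xtr, ytr, spec,
                                       seed=int(rng.integers(2 ** 31)))
            scores[test_idx] = fold_model.predict_proba(X.iloc[test_idx])
        _, aucs[r] = roc_auc(scores, y)
        errs[r] = 100.0 * float(np.mean((scores >= spec.threshold) != y))
    return CVResult(mean_auc=float(aucs.mean()),
                    mean_misclassification=float(errs.mean()),
                    n_folds=n_folds, n_repeats=n_repeats, seed=seed,
                    auc_per_repeat=aucs, misclassification_per_repeat=errs)
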