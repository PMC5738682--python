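"""Logistic-regression panels and likelihood-ratio model ranking.

Panels are fitted by plain maximum likelihood (Newton/IRLS on the score
equations, no penalty by default, matching the analysis being reproduced);
an optional ridge term is available for separated data. The deviance
reported is -2 * maximized log-likelihood, the scale on which candidate
panels are ranked; the null-relative likelihood-ratio statistic is exposed
alongside because near-separating panels drive the raw deviance toward 0.

Near-complete separation is common here -- tumor-specific CpGs at high
purity split cases from controls almost perfectly -- so the fitter flags
``separation_detected`` whenever any coefficient exceeds a documented bound
(default 15 on the logit scale) and uses step-halving to keep IRLS stable
as the likelihood surface flattens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LogisticModel",
    "fit_logistic",
    "likelihood_ratio_test",
    "predict_prob",
    "rank_models",
    "PanelLogisticClassifier",
    "SEPARATION_BOUND",
]

#: |coefficient| beyond which the fit is flagged as (quasi-)separated.
SEPARATION_BOUND = 15.0

_EPS = 1e-12


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class LogisticModel:
    feature_names: tuple[str, ...]
    intercept: float
    coef: np.ndarray
    deviance: float          # -2 * maximized log-likelihood
    null_deviance: float     # deviance of the intercept-only model
    converged: bool
    separation_detected: bool
    n_iter: int
    n_samples: int

    @property
    def lr_statistic(self) -> float:
        """Null-relative likelihood-ratio statistic, df = n features."""
        return max(self.null_deviance - self.deviance, 0.0)


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _irls(X: np.ndarray, y: np.ndarray, max_iter: int, tol: float, ridge: float):
    """Newton/IRLS with step-halving; converged when max|score| < tol.

    The ridge penalty (when > 0) is applied to all coefficients including
    the intercept column's weight only for slope terms.
    """
    n, k = X.shape
    beta = np.zeros(k)
    pen = np.full(k, ridge)
    pen[0] = 0.0  # never penalize the intercept
    dev = _deviance(y, np.full(n, 0.5)) + 2 * 0  # starting point beta=0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = _sigmoid(eta)
        score = X.T @ (y - p) - pen * beta
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = np.clip(p * (1.0 - p), _EPS, None)
        H = (X * w[:, None]).T @ X + np.diag(pen)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        # step-halving on penalized deviance increase
        cur = _deviance(y, p) + float(pen @ (beta**2))
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            cand_dev = _deviance(y, _sigmoid(X @ cand)) + float(
                pen @ (cand**2)
            )
            if cand_dev <= cur + 1e-10:
                break
            scale *= 0.5
        beta = beta + scale * step
    p = _sigmoid(X @ beta)
    return beta, _deviance(y, p), converged, it


def _null_deviance(y: np.ndarray) -> float:
    ybar = float(np.mean(y))
    p = np.clip(ybar, _EPS, 1 - _EPS)
    n1 = float(np.sum(y))
    n0 = float(len(y) - n1)
    return -2.0 * (n1 * np.log(p) + n0 * np.log(1 - p))


def fit_logistic(
    features,
    labels,
    max_iter: int = 100,
    tol: float = 1e-8,
    ridge: float = 0.0,
    separation_bound: float = SEPARATION_BOUND,
) -> LogisticModel:
    """Maximum-likelihood logistic fit of ``labels`` (0/1) on ``features``.

    ``features`` is samples x features (DataFrame or array; an empty
    feature set fits the intercept-only model). Raises on missing values
    or single-class labels.
    """
    if isinstance(features, pd.DataFrame):
        names = tuple(map(str, features.columns))
        Xf = features.to_numpy(dtype=float)
    else:
        Xf = np.asarray(features, dtype=float)
        if Xf.ndim == 1:
            Xf = Xf[:, None]
        names = tuple(f"x{i}" for i in range(Xf.shape[1]))
    y = np.asarray(labels, dtype=float)
    if Xf.shape[0] != y.shape[0]:
        raise ValueError("features and labels must align")
    if np.isnan(Xf).any():
        raise ValueError("missing feature values; impute upstream")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("labels must be 0/1")
    if classes.size < 2:
        raise ValueError("need both classes present")

    X = np.column_stack([np.ones(Xf.shape[0]), Xf])
    beta, dev, converged, n_iter = _irls(X, y, max_iter=max_iter, tol=tol, ridge=ridge)
    coef = beta[1:]
    return LogisticModel(
        feature_names=names,
        intercept=float(beta[0]),
        coef=coef,
        deviance=dev,
        null_deviance=_null_deviance(y),
        converged=converged,
        separation_detected=bool(np.any(np.abs(coef) > separation_bound)),
        n_iter=n_iter,
        n_samples=int(y.shape[0]),
    )


def likelihood_ratio_test(full: LogisticModel, reduced: LogisticModel) -> float:
    """Upper-tail chi-square p for nested models; df = feature difference."""
    if not set(reduced.feature_names) <= set(full.feature_names):
        raise ValueError("models are not nested")
    if reduced.n_samples != full.n_samples:
        raise ValueError("models were fitted on different samples")
    df = len(full.feature_names) - len(reduced.feature_names)
    statistic = max(reduced.deviance - full.deviance, 0.0)
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(statistic, df))


def predict_prob(model: LogisticModel, features) -> np.ndarray:
    """Predicted P(case) per sample; DataFrame columns aligned by name."""
    if isinstance(features, pd.DataFrame):
        missing = set(model.feature_names) - set(map(str, features.columns))
        if missing:
            raise KeyError(f"missing feature columns: {sorted(missing)}")
        Xf = features.loc[:, list(model.feature_names)].to_numpy(dtype=float)
    else:
        Xf = np.asarray(features, dtype=float)
        if Xf.ndim == 1:
            Xf = Xf[:, None]
        if Xf.shape[1] != len(model.feature_names):
            raise ValueError("feature count mismatch")
    eta = model.intercept + Xf @ model.coef
    return _sigmoid(eta)


def rank_models(
    candidates,
    train_features: pd.DataFrame,
    train_labels,
    top: int = 3,
    **fit_kwargs,
) -> list[tuple[object, LogisticModel]]:
    """Fit every candidate feature set and rank by model evidence.

    Ordering: ascending deviance, ties broken by fewer features then
    lexicographic roster. Non-converged fits are excluded; if every fit
    fails to converge an error is raised. Returns the ``top`` best
    (candidate, model) pairs.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate")
    fitted = []
    for cand in candidates:
        probes = list(getattr(cand, "probes", cand))
        model = fit_logistic(train_features.loc[:, probes], train_labels, **fit_kwargs)
        if model.converged:
            fitted.append((cand, model))
    if not fitted:
        raise RuntimeError("all candidate fits failed to converge")
    fitted.sort(key=lambda cm: (cm[1].deviance, len(cm[1].feature_names), cm[1].feature_names))
    return fitted[:top]


class PanelLogisticClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style wrapper around the IRLS fitter.

    Fitted attributes: ``intercept_``, ``coef_``, ``deviance_``,
    ``null_deviance_``, ``converged_``, ``separation_detected_``,
    ``classes_``, ``model_`` (the underlying :class:`LogisticModel`).
    """

    def __init__(
        self,
        max_iter: int = 100,
        tol: float = 1e-8,
        ridge: float = 0.0,
        separation_bound: float = SEPARATION_BOUND,
        threshold: float = 0.5,
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.ridge = ridge
        self.separation_bound = separation_bound
        self.threshold = threshold

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("binary classification requires exactly 2 classes")
        y01 = (y == self.classes_[1]).astype(float)
        self.model_ = fit_logistic(
            X,
            y01,
            max_iter=self.max_iter,
            tol=self.tol,
            ridge=self.ridge,
            separation_bound=self.separation_bound,
        )
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.intercept_ = self.model_.intercept
        self.coef_ = self.model_.coef.copy()
        self.deviance_ = self.model_.deviance
        self.null_deviance_ = self.model_.null_deviance
        self.converged_ = self.model_.converged
        self.separation_detected_ = self.model_.separation_detected
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        p1 = predict_prob(self.model_, pd.DataFrame(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return np.where(p >= self.threshold, self.classes_[1], self.classes_[0])

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        X = pd.DataFrame(X)
        Xf = X.loc[:, list(self.model_.feature_names)].to_numpy(dtype=float)
        return self.intercept_ + Xf @ self.coef_
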