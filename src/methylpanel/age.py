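"""Age-correlation screening of candidate CpGs.

Methylation at some CpGs drifts with age in normal tissue; left in a
tumor-specific panel they would encode patient age rather than disease.
Probes whose methylation in normal tissue shows a significant *positive*
Spearman correlation with age are removed. The default p cutoff, 1.1E-05,
numerically equals 0.05/4726 to two significant figures (a Bonferroni
correction over a differential-probe set of that size), but it is exposed
as a plain configurable cutoff.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "spearman_rho",
    "spearman_p",
    "remove_age_related",
    "AgeCorrelationFilter",
    "EXACT_P_MAX_N",
]

#: Below this n the permutation null of Spearman's rho is enumerated exactly.
EXACT_P_MAX_N = 10


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks. Returns NaN when either vector is constant
    (correlation undefined). Missing values are removed pairwise.
    """
    x, y = _pairwise_complete(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


_PERM_CACHE: dict[int, np.ndarray] = {}


def _exact_rho_distribution(n: int) -> np.ndarray:
    """All n! Spearman rho values of rank permutations against 1..n."""
    if n in _PERM_CACHE:
        return _PERM_CACHE[n]
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(base)))
    # rho = 1 - 6*sum(d^2)/(n(n^2-1)) holds exactly for tie-free ranks
    d2 = ((perms - base) ** 2).sum(axis=1)
    rhos = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    _PERM_CACHE[n] = rhos
    return rhos


def spearman_p(rho: float, n: int) -> float:
    """Two-sided p for Spearman's rho.

    For n < 10 the permutation null is enumerated exactly (tie-free
    assumption); for n >= 10 the t-approximation
    t = rho * sqrt((n-2)/(1-rho^2)) with n-2 df is used. At |rho| = 1 the
    approximation underflows to 0, which is documented behaviour.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if math.isnan(rho):
        return float("nan")
    if not -1.0 <= rho <= 1.0 + 1e-12:
        raise ValueError("rho outside [-1, 1]")
    if n < EXACT_P_MAX_N:
        rhos = _exact_rho_distribution(n)
        return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def remove_age_related(
    dmr_probes,
    beta_normal: pd.DataFrame,
    ages,
    p_cutoff: float = 1.1e-5,
    positive_only: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """Split probes into age-clean and age-correlated sets.

    Parameters
    ----------
    dmr_probes
        Probe ids to screen (typically the differential probes); input
        order is preserved in the kept list.
    beta_normal
        Probes x samples beta matrix restricted to normal-tissue samples.
    ages
        Age in years per normal sample (aligned with the matrix columns).
    p_cutoff
        Removal requires rho > 0 (when ``positive_only``) and p < cutoff.

    Returns (kept probe ids, correlation table for all screened probes with
    a ``removed`` flag).
    """
    if not 0.0 < p_cutoff < 1.0:
        raise ValueError("p_cutoff must lie in (0, 1)")
    ages = np.asarray(ages, dtype=float)
    if np.isnan(ages).any():
        raise ValueError("ages must be available for all normal samples")
    if ages.shape[0] != beta_normal.shape[1]:
        raise ValueError("ages must align with beta_normal columns")

    rows = []
    for probe in dmr_probes:
        if probe not in beta_normal.index:
            raise KeyError(f"probe {probe!r} absent from beta matrix")
        vals = beta_normal.loc[probe].to_numpy(dtype=float)
        x, y = _pairwise_complete(ages, vals)
        rho = spearman_rho(x, y) if x.size >= 3 else float("nan")
        p = spearman_p(rho, x.size) if x.size >= 3 else float("nan")
        removed = bool(not math.isnan(p) and p < p_cutoff and (rho > 0 or not positive_only))
        rows.append(dict(probe_id=probe, rho=rho, p_value=p, n=int(x.size), removed=removed))
    table = pd.DataFrame(rows).set_index("probe_id")
    kept = [p for p in dmr_probes if not table.loc[p, "removed"]]
    return kept, table


class AgeCorrelationFilter(TransformerMixin, BaseEstimator):
    """Feature filter dropping age-correlated probes (samples x probes).

    ``fit(X, y)`` takes normal-tissue beta values as ``X`` and ages as
    ``y``. Fitted attributes: ``correlations_`` (per-probe rho/p table) and
    ``support_`` (True where kept).
    """

    def __init__(self, p_cutoff: float = 1.1e-5, positive_only: bool = True):
        self.p_cutoff = p_cutoff
        self.positive_only = positive_only

    def fit(self, X, y):
        X = pd.DataFrame(X)
        self.n_features_in_ = X.shape[1]
        kept, table = remove_age_related(
            list(X.columns), X.T, y, p_cutoff=self.p_cutoff, positive_only=self.positive_only
        )
        self.correlations_ = table
        self.support_ = ~table["removed"].to_numpy()
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        return pd.DataFrame(X).loc[:, self.support_]
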