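"""Beta-value computation, assay QC against methylation standards, probe
filtering and dichotomization.

A beta value is the methylated-allele signal fraction M / (M + U + offset);
the assay's background signal keeps truly unmethylated CpGs in roughly the
0-0.3 band, which motivates the 0.3 dichotomization threshold used
downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "compute_beta",
    "qc_control_curve",
    "filter_probes",
    "dichotomize",
    "Dichotomizer",
    "MissingFractionFilter",
]


def compute_beta(methylated_intensity, unmethylated_intensity, offset: float = 0.0):
    """Beta = M / (M + U + offset); NaN where the denominator is zero.

    The default offset is 0 (a plain intensity ratio); pass e.g. 100 for the
    Illumina-style stabilising offset.
    """
    m = np.asarray(methylated_intensity, dtype=float)
    u = np.asarray(unmethylated_intensity, dtype=float)
    if np.any(m < 0) or np.any(u < 0) or offset < 0:
        raise ValueError("intensities and offset must be non-negative")
    denom = m + u + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0), np.nan)
    return float(beta) if beta.ndim == 0 else beta


def qc_control_curve(observed: dict[float, "list[float]"], tolerance: float = 0.05) -> pd.DataFrame:
    """Compare measured beta of methylation standards with their nominal level.

    ``observed`` maps an expected level (e.g. 0, 0.33, 0.66, 1.0) to the
    measured beta values of the corresponding control DNA mix. A level is
    flagged ``inflated`` when mean(observed) - expected exceeds
    ``tolerance``; negative bias never flags.
    """
    if not observed:
        raise ValueError("at least one standard level required")
    rows = []
    for level in sorted(observed):
        vals = np.asarray(observed[level], dtype=float)
        if vals.size == 0:
            raise ValueError(f"no observations for standard level {level}")
        bias = float(np.mean(vals)) - float(level)
        rows.append(
            dict(
                expected=float(level),
                observed_mean=float(np.mean(vals)),
                bias=bias,
                inflated=bias > tolerance,
                n=int(vals.size),
            )
        )
    return pd.DataFrame(rows)


def filter_probes(
    beta: pd.DataFrame, max_missing_fraction: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Drop probes whose missing fraction exceeds the cutoff.

    Returns the filtered matrix (input probe order preserved) and the
    removed probe ids in input order.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    missing_frac = beta.isna().mean(axis=1)
    drop = missing_frac > max_missing_fraction
    removed = list(beta.index[drop])
    return beta.loc[~drop], removed


def dichotomize(beta: pd.DataFrame, threshold: float = 0.3) -> pd.DataFrame:
    """Binary methylation call: 1 iff beta > threshold (strict), NaN kept.

    The strict inequality at the boundary is a documented convention: a
    probe sitting exactly at the background ceiling is called unmethylated.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    arr = beta.to_numpy(dtype=float) if isinstance(beta, pd.DataFrame) else np.asarray(beta, float)
    out = np.where(np.isnan(arr), np.nan, (arr > threshold).astype(float))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    return out


class Dichotomizer(TransformerMixin, BaseEstimator):
    """Stateless transformer wrapping :func:`dichotomize` (samples x probes)."""

    def __init__(self, threshold: float = 0.3):
        self.threshold = threshold

    def fit(self, X, y=None):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        X = pd.DataFrame(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        if isinstance(X, pd.DataFrame):
            return dichotomize(X, self.threshold)
        arr = np.asarray(X, dtype=float)
        return np.where(np.isnan(arr), np.nan, (arr > self.threshold).astype(float))


class MissingFractionFilter(TransformerMixin, BaseEstimator):
    """Feature filter wrapping :func:`filter_probes` (samples x probes)."""

    def __init__(self, max_missing_fraction: float = 0.05):
        self.max_missing_fraction = max_missing_fraction

    def fit(self, X, y=None):
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must lie in [0, 1]")
        X = pd.DataFrame(X)
        self.n_features_in_ = X.shape[1]
        self.support_ = (X.isna().mean(axis=0) <= self.max_missing_fraction).to_numpy()
        self.removed_ = list(X.columns[~self.support_])
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = pd.DataFrame(X)
        return X.loc[:, self.support_]
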