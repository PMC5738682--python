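"""Tumor-hypermethylated CpG detection with family-wise error control.

Each probe's dichotomized calls are tallied into a 2x2 contingency table
(tumor/normal x methylated/unmethylated) and tested with Pearson's
chi-square (no continuity correction) or, when any expected cell count
falls below 5 (Cochran's rule), Fisher's exact test. Significance is
Bonferroni-controlled: the per-test threshold is family_alpha divided by
the number of probes tested, and a probe passes when p <= threshold *and*
the tumor group is the more methylated one (the hypermethylation direction
filter, on by default).
"""

from __future__ import annotations

from functools import lru_cache
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ContingencyTable2x2",
    "contingency_from_groups",
    "chi_square_test",
    "fisher_exact_test",
    "expected_counts",
    "needs_exact_test",
    "bonferroni_threshold",
    "detect_dmrs",
    "DMRDetector",
]


class ContingencyTable2x2(NamedTuple):
    """Counts: rows tumor/normal, columns methylated/unmethylated."""

    a: int  # tumor, methylated
    b: int  # tumor, unmethylated
    c: int  # normal, methylated
    d: int  # normal, unmethylated


def contingency_from_groups(binary_row, labels) -> ContingencyTable2x2:
    """Tally one probe's 0/1 calls into a 2x2 table, dropping missing values.

    ``labels`` is boolean-like, True for tumor samples.
    """
    vals = np.asarray(binary_row, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if vals.shape != lab.shape:
        raise ValueError("binary_row and labels must align")
    keep = ~np.isnan(vals)
    if not keep.any():
        raise ValueError("all entries missing")
    vals, lab = vals[keep], lab[keep]
    meth = vals > 0.5
    return ContingencyTable2x2(
        a=int((lab & meth).sum()),
        b=int((lab & ~meth).sum()),
        c=int((~lab & meth).sum()),
        d=int((~lab & ~meth).sum()),
    )


def expected_counts(table: ContingencyTable2x2) -> np.ndarray:
    a, b, c, d = table
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    rows = np.array([a + b, c + d], dtype=float)
    cols = np.array([a + c, b + d], dtype=float)
    return np.outer(rows, cols) / n


def needs_exact_test(table: ContingencyTable2x2) -> bool:
    """Cochran's rule: route to Fisher when any expected count < 5."""
    return bool((expected_counts(table) < 5).any())


@lru_cache(maxsize=200_000)
def _chi_square_p(a: int, b: int, c: int, d: int) -> float:
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(p)


@lru_cache(maxsize=200_000)
def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def chi_square_test(table: ContingencyTable2x2) -> float:
    """Pearson chi-square p (1 df, no continuity correction).

    Caller is responsible for the expected-count precondition; degenerate
    margins raise.
    """
    a, b, c, d = (int(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    return _chi_square_p(a, b, c, d)


def fisher_exact_test(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    margin-preserving tables no more probable than the observed one."""
    a, b, c, d = (int(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    return _fisher_p(a, b, c, d)


def bonferroni_threshold(family_alpha: float, n_tests: int) -> float:
    """Per-test p cutoff controlling FWER at family_alpha over n_tests."""
    if not 0.0 < family_alpha < 1.0:
        raise ValueError("family_alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    return family_alpha / n_tests


def detect_dmrs(
    binary: pd.DataFrame,
    labels,
    family_alpha: float = 0.05,
    direction_filter: str = "hyper",
) -> pd.DataFrame:
    """Per-probe contingency tests over a dichotomized probes x samples matrix.

    Parameters
    ----------
    binary
        Probes x samples matrix of 0/1/NaN methylation calls.
    labels
        Per-sample group, True/1/"tumor" for the tumor group.
    family_alpha
        Family-wise error budget; the per-test threshold is
        family_alpha / n_probes_tested.
    direction_filter
        "hyper" (default) passes only probes more methylated in tumors;
        "both" ignores direction.

    Returns a DataFrame with one row per probe: counts a..d, method,
    p_value, direction and passes flag. Probes with every call missing are
    reported with NaN p and never pass.
    """
    if direction_filter not in ("hyper", "both"):
        raise ValueError("direction_filter must be 'hyper' or 'both'")
    lab = np.asarray(labels)
    if lab.dtype.kind in "US":
        lab = np.char.lower(lab.astype(str)) == "tumor"
    lab = lab.astype(bool)
    if lab.shape[0] != binary.shape[1]:
        raise ValueError("labels must align with samples (columns)")
    if lab.sum() < 2 or (~lab).sum() < 2:
        raise ValueError("need at least 2 samples per group")

    vals = binary.to_numpy(dtype=float)
    present = ~np.isnan(vals)
    meth = np.where(present, vals > 0.5, False)

    a = (meth[:, lab]).sum(axis=1).astype(int)
    b = (present[:, lab] & ~meth[:, lab]).sum(axis=1).astype(int)
    c = (meth[:, ~lab]).sum(axis=1).astype(int)
    d = (present[:, ~lab] & ~meth[:, ~lab]).sum(axis=1).astype(int)

    n_tested = int(((a + b + c + d) > 0).sum())
    threshold = bonferroni_threshold(family_alpha, max(n_tested, 1))

    p = np.full(binary.shape[0], np.nan)
    method = np.empty(binary.shape[0], dtype=object)
    for i in range(binary.shape[0]):
        tbl = ContingencyTable2x2(int(a[i]), int(b[i]), int(c[i]), int(d[i]))
        total = sum(tbl)
        if total == 0:
            method[i] = "none"
            continue
        if needs_exact_test(tbl):
            method[i] = "fisher_exact"
            p[i] = fisher_exact_test(tbl)
        else:
            method[i] = "chi_square"
            p[i] = chi_square_test(tbl)

    with np.errstate(invalid="ignore", divide="ignore"):
        prop_t = np.where(a + b > 0, a / np.maximum(a + b, 1), np.nan)
        prop_n = np.where(c + d > 0, c / np.maximum(c + d, 1), np.nan)
    direction = np.where(prop_t > prop_n, "hyper", "hypo")

    passes = (p <= threshold) & ~np.isnan(p)
    if direction_filter == "hyper":
        passes &= direction == "hyper"

    return pd.DataFrame(
        {
            "probe_id": binary.index,
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "method": method,
            "p_value": p,
            "direction": direction,
            "passes": passes,
            "per_test_threshold": threshold,
        }
    ).set_index("probe_id")


class DMRDetector(TransformerMixin, BaseEstimator):
    """Feature selector keeping tumor-hypermethylated probes.

    Operates on samples x probes input (sklearn orientation): ``X`` is the
    dichotomized 0/1/NaN call matrix, ``y`` the tumor/normal labels. Fitted
    attributes: ``results_`` (per-probe test table), ``support_`` (boolean
    pass mask), ``per_test_threshold_``.
    """

    def __init__(self, family_alpha: float = 0.05, direction_filter: str = "hyper"):
        self.family_alpha = family_alpha
        self.direction_filter = direction_filter

    def fit(self, X, y):
        X = pd.DataFrame(X)
        self.n_features_in_ = X.shape[1]
        self.results_ = detect_dmrs(
            X.T, y, family_alpha=self.family_alpha, direction_filter=self.direction_filter
        )
        self.support_ = self.results_["passes"].to_numpy()
        self.per_test_threshold_ = float(self.results_["per_test_threshold"].iloc[0])
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        return pd.DataFrame(X).loc[:, self.support_]
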