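"""Classifier performance metrics and surrogate-specimen concordance tests.

AUC is computed as Mann-Whitney concordance (the probability a random case
outscores a random control, ties counted 0.5), which equals the area under
the empirical ROC curve without interpolation. Specimen-type comparisons
use the Wilcoxon rank-sum test for independent groups and the Wilcoxon
signed-rank test for patient-paired groups, with exact small-sample null
distributions where attainable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import REGION_CLASSES

__all__ = [
    "roc_auc",
    "sens_spec_at_threshold",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "compare_sample_types",
    "region_profile",
]


def roc_auc(scores, labels) -> float:
    """AUC as Mann-Whitney concordance over all case/control score pairs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    # midrank formulation: AUC = (R1 - n1(n1+1)/2) / (n1*n0), ties -> 0.5
    ranks = stats.rankdata(s)
    r1 = float(ranks[y].sum())
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def sens_spec_at_threshold(scores, labels, threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) calling positive when score >= threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not y.any() or y.all():
        raise ValueError("both classes must be present")
    pos = s >= threshold
    sens = float((pos & y).sum() / y.sum())
    spec = float((~pos & ~y).sum() / (~y).sum())
    return sens, spec


#: Largest min(n, m) for which the rank-sum null is enumerated exactly.
RANK_SUM_EXACT_MAX_N = 10
#: Largest n for which the signed-rank null is enumerated exactly.
SIGNED_RANK_EXACT_MAX_N = 20


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p.

    Exact null when min(n) <= 10 and the pooled data are tie-free;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 values")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if min(x.size, y.size) <= RANK_SUM_EXACT_MAX_N and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def wilcoxon_signed_rank(differences) -> float:
    """Two-sided Wilcoxon signed-rank p on paired differences.

    Zero differences are dropped (Wilcoxon's original treatment); at least
    3 nonzero differences are required, all-zero input raises. Exact
    enumeration of the 2^n sign assignments when n <= 20 and the absolute
    differences are tie-free; normal approximation with continuity
    correction otherwise.
    """
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    if d.size < 3:
        raise ValueError("need at least 3 nonzero differences")
    tie_free = np.unique(np.abs(d)).size == d.size
    method = "exact" if (d.size <= SIGNED_RANK_EXACT_MAX_N and tie_free) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(
            d, zero_method="wilcox", alternative="two-sided", correction=True, method=method
        )
    return float(res.pvalue)


def compare_sample_types(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    probes,
    pairs_spec,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[tuple[str, str], bool]]:
    """Per-probe Wilcoxon comparisons between specimen types.

    Parameters
    ----------
    beta
        Probes x samples matrix.
    samples
        Sample sheet with sample_id, patient_id, specimen_type.
    probes
        Panel probe ids to compare.
    pairs_spec
        Iterable of (type_a, type_b, paired) triples. Unpaired comparisons
        use the rank-sum test on all samples of each type; paired ones use
        the signed-rank test on patient-matched differences (type_a minus
        type_b). A probe whose paired differences are all zero is reported
        with p = 1.0 (no evidence of a difference).

    Returns the per-probe comparison table and a per-pair concordance flag:
    True when every probe's p > alpha (the types are statistically
    indistinguishable on the panel).
    """
    sheet = samples.set_index("sample_id")
    rows = []
    concordant: dict[tuple[str, str], bool] = {}
    for type_a, type_b, paired in pairs_spec:
        ids_a = sheet.index[sheet["specimen_type"] == type_a]
        ids_b = sheet.index[sheet["specimen_type"] == type_b]
        if len(ids_a) == 0 or len(ids_b) == 0:
            raise ValueError(f"specimen type missing from cohort: {type_a} vs {type_b}")
        if paired:
            pa = sheet.loc[ids_a, "patient_id"]
            pb = sheet.loc[ids_b, "patient_id"]
            shared = sorted(set(pa) & set(pb))
            if not shared:
                raise ValueError(f"no shared patients for paired {type_a} vs {type_b}")
            map_a = {p: s for s, p in pa.items()}
            map_b = {p: s for s, p in pb.items()}
            cols_a = [map_a[p] for p in shared]
            cols_b = [map_b[p] for p in shared]
        ps = []
        for probe in probes:
            if paired:
                diffs = (
                    beta.loc[probe, cols_a].to_numpy(dtype=float)
                    - beta.loc[probe, cols_b].to_numpy(dtype=float)
                )
                med = float(np.median(diffs))
                if np.all(diffs[~np.isnan(diffs)] == 0.0):
                    p = 1.0
                else:
                    p = wilcoxon_signed_rank(diffs)
                test = "signed_rank"
            else:
                xa = beta.loc[probe, ids_a].to_numpy(dtype=float)
                xb = beta.loc[probe, ids_b].to_numpy(dtype=float)
                med = float(np.nanmedian(xa) - np.nanmedian(xb))
                p = wilcoxon_rank_sum(xa, xb)
                test = "rank_sum"
            ps.append(p)
            rows.append(
                dict(
                    probe_id=probe,
                    type_a=type_a,
                    type_b=type_b,
                    test=test,
                    p_value=p,
                    median_difference=med,
                )
            )
        concordant[(type_a, type_b)] = bool(all(p > alpha for p in ps))
    return pd.DataFrame(rows), concordant


def region_profile(
    gene: str,
    annotation: pd.DataFrame,
    beta: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Mean beta per (region class x specimen type) for one gene's probes.

    Region classes are ordered promoter-to-body (TSS1500, TSS200, 5UTR,
    1stExon, Body); specimen types absent from the cohort are omitted.
    Means are missing-aware.
    """
    probes = annotation.loc[annotation["gene"] == gene]
    if probes.empty:
        raise KeyError(f"unknown gene {gene!r}")
    sheet = samples.set_index("sample_id")
    out: dict[str, dict[str, float]] = {}
    for stype, ids in sheet.groupby("specimen_type").groups.items():
        cols = [s for s in ids if s in beta.columns]
        if not cols:
            continue
        col_means: dict[str, float] = {}
        for region, grp in probes.groupby("region_class"):
            pids = [p for p in grp["probe_id"] if p in beta.index]
            if pids:
                col_means[region] = float(np.nanmean(beta.loc[pids, cols].to_numpy()))
        out[stype] = col_means
    table = pd.DataFrame(out)
    order = [r for r in REGION_CLASSES if r in table.index]
    extra = [r for r in table.index if r not in order]
    return table.loc[order + extra]
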