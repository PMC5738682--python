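"""ROC/AUC, threshold metrics, Wilcoxon tests, surrogate comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylpanel.evaluate import (
    compare_sample_types,
    region_profile,
    roc_auc,
    sens_spec_at_threshold,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


def pairwise_auc_oracle(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    total = hits = 0
    for a in s[y]:
        for b in s[~y]:
            total += 1
            hits += 1.0 if a > b else (0.5 if a == b else 0.0)
    return hits / total


class TestAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_exhaustive_pair_count(self):
        assert roc_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_matches_pairwise_oracle_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            n = int(rng.integers(6, 25))
            scores = np.round(rng.uniform(size=n), 2)  # rounding induces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            ours = roc_auc(scores, labels)
            assert ours == pytest.approx(pairwise_auc_oracle(scores, labels), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_matches_mann_whitney_u(self, rng):
        from scipy import stats

        scores = rng.uniform(size=30)
        labels = np.array([1] * 12 + [0] * 18)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert roc_auc(scores, labels) == pytest.approx(u / (12 * 18), abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(
        # a coarse grid keeps the transform strictly increasing in floating
        # point (distinct inputs stay distinct after exp)
        scores=st.lists(
            st.integers(-500, 500).map(lambda v: v / 100.0), min_size=4, max_size=15
        ),
        split=st.integers(1, 3),
    )
    def test_invariant_under_increasing_transform(self, scores, split):
        labels = [1] * split + [0] * (len(scores) - split)
        a1 = roc_auc(scores, labels)
        a2 = roc_auc(np.exp(np.asarray(scores) / 5.0), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestSensSpec:
    def test_perfect_classifier(self):
        assert sens_spec_at_threshold([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5) == (1.0, 1.0)

    def test_zero_threshold_boundary(self):
        sens, spec = sens_spec_at_threshold([0.4, 0.6, 0.2], [1, 0, 0], 0.0)
        assert sens == 1.0 and spec == 0.0

    def test_confusion_matrix_count(self):
        sens, spec = sens_spec_at_threshold([0.9, 0.3, 0.6, 0.1], [1, 1, 0, 0], 0.5)
        assert (sens, spec) == (0.5, 0.5)


def rank_sum_enumeration_oracle(x, y):
    """Two-sided p by enumerating all C(n+m, n) assignments of the pooled
    tie-free values to the first group."""
    pooled = sorted(x) + sorted(y)
    n = len(x)
    obs = sum(sorted(pooled).index(v) + 1 for v in x)
    stats_ = []
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    for combo in itertools.combinations(pooled, n):
        stats_.append(sum(ranks[v] for v in combo))
    stats_ = np.asarray(stats_, float)
    mean = stats_.mean()
    return float(np.mean(np.abs(stats_ - mean) >= abs(obs - mean) - 1e-9))


class TestRankSum:
    def test_disjoint_groups_exact(self):
        # only 2 of the C(6,3)=20 splits are as extreme
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_near_one(self):
        p = wilcoxon_rank_sum([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.9

    def test_matches_enumeration_small_samples(self, rng):
        for _ in range(10):
            x = rng.uniform(size=4)
            y = rng.uniform(size=5)
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                rank_sum_enumeration_oracle(list(x), list(y)), abs=1e-9
            )

    def test_power_under_one_sd_shift(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 40)
            y = rng.normal(1, 1, 40)
            hits += wilcoxon_rank_sum(x, y) < 0.01
        assert hits >= 19  # >=95% of seeds

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1, 2], [3, 4, 5])


def signed_rank_enumeration_oracle(diffs):
    """Two-sided p over all 2^n sign assignments of tie-free |differences|."""
    d = np.asarray(diffs, float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = float(ranks[d > 0].sum())
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(float(ranks[np.asarray(signs, bool)].sum()))
    ws = np.asarray(ws)
    mean = ws.mean()
    return float(np.mean(np.abs(ws - mean) >= abs(w_obs - mean) - 1e-9))


class TestSignedRank:
    def test_all_positive_eight_pairs(self):
        # the most extreme of 2^8 = 256 sign patterns, doubled
        assert wilcoxon_signed_rank([1, 2, 3, 4, 5, 6, 7, 8]) == pytest.approx(
            2 / 256
        )

    def test_three_pairs_never_significant(self):
        assert wilcoxon_signed_rank([1, 2, 3]) == pytest.approx(0.25)

    def test_symmetric_differences(self):
        assert wilcoxon_signed_rank([1.5, -1.5, 2.5, -2.5]) == pytest.approx(1.0)

    def test_matches_enumeration(self, rng):
        for _ in range(10):
            d = rng.normal(0.3, 1.0, size=7)
            assert wilcoxon_signed_rank(d) == pytest.approx(
                signed_rank_enumeration_oracle(d), abs=1e-9
            )

    def test_zero_handling(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0, 1.0])  # <3 nonzero


class TestCompareSampleTypes:
    def _cohort_frames(self, values_a, values_b):
        probes = [f"p{i}" for i in range(values_a.shape[0])]
        ids_a = [f"A{i}" for i in range(values_a.shape[1])]
        ids_b = [f"B{i}" for i in range(values_b.shape[1])]
        beta = pd.DataFrame(
            np.hstack([values_a, values_b]), index=probes, columns=ids_a + ids_b
        )
        samples = pd.DataFrame(
            dict(
                sample_id=ids_a + ids_b,
                patient_id=[f"P{i}" for i in range(len(ids_a))] * 2,
                specimen_type=["biopsy"] * len(ids_a) + ["washing"] * len(ids_b),
                disease_label="cancer",
            )
        )
        return beta, samples, probes

    def test_identical_groups_all_p_one(self, rng):
        vals = rng.uniform(0.2, 0.8, size=(4, 8))
        beta, samples, probes = self._cohort_frames(vals, vals)
        table, concordant = compare_sample_types(
            beta, samples, probes,
            [("biopsy", "washing", False), ("biopsy", "washing", True)],
        )
        paired = table[table["test"] == "signed_rank"]
        assert (paired["p_value"] == 1.0).all()  # all-zero differences
        unpaired = table[table["test"] == "rank_sum"]
        assert (unpaired["p_value"] > 0.9).all()
        assert concordant[("biopsy", "washing")]

    def test_shifted_paired_groups_discordant(self, rng):
        a = rng.uniform(0.5, 0.7, size=(3, 8))
        # variable per-pair gaps keep the |differences| tie-free, so the
        # exact 2^8 branch applies
        b = a - rng.uniform(0.2, 0.4, size=a.shape)
        beta, samples, probes = self._cohort_frames(a, b)
        table, concordant = compare_sample_types(
            beta, samples, probes, [("biopsy", "washing", True)]
        )
        assert np.allclose(table["p_value"], 2 / 256)
        assert (table["median_difference"] > 0).all()
        assert not concordant[("biopsy", "washing")]

    def test_missing_type_rejected(self, rng):
        vals = rng.uniform(size=(2, 6))
        beta, samples, probes = self._cohort_frames(vals, vals)
        with pytest.raises(ValueError):
            compare_sample_types(beta, samples, probes, [("biopsy", "sputum", False)])


class TestRegionProfile:
    def _frames(self):
        ann = pd.DataFrame(
            dict(
                probe_id=["p1", "p2", "p3"],
                gene=["G", "G", "G"],
                region_class=["Body", "TSS200", "TSS1500"],
            )
        )
        beta = pd.DataFrame(
            0.5, index=["p1", "p2", "p3"], columns=["s1", "s2", "s3"]
        )
        samples = pd.DataFrame(
            dict(
                sample_id=["s1", "s2", "s3"],
                patient_id=["a", "b", "c"],
                specimen_type=["tumor_tissue", "tumor_tissue", "normal_tissue"],
                disease_label="cancer",
            )
        )
        return ann, beta, samples

    def test_constant_input_constant_cells(self):
        ann, beta, samples = self._frames()
        table = region_profile("G", ann, beta, samples)
        assert (table.to_numpy() == 0.5).all()
        # promoter-to-body row order
        assert list(table.index) == ["TSS1500", "TSS200", "Body"]

    def test_absent_type_omitted(self):
        ann, beta, samples = self._frames()
        table = region_profile("G", ann, beta, samples)
        assert "sputum" not in table.columns

    def test_unknown_gene_rejected(self):
        ann, beta, samples = self._frames()
        with pytest.raises(KeyError):
            region_profile("NOPE", ann, beta, samples)

    def test_promoter_exceeds_body_in_tumor(self, default_cohort):
        """Planted promoter bias: promoter-class planted probes are more
        methylated than body probes in tumor specimens."""
        cohort = default_cohort
        sheet = cohort.samples.set_index("sample_id")
        tumor = sheet.index[sheet["specimen_type"] == "tumor_tissue"]
        ann = cohort.annotation.set_index("probe_id")
        planted = sorted(cohort.truth.diff_probe_ids)
        body = [p for p in cohort.beta.index if ann.loc[p, "region_class"] == "Body"]
        planted_mean = float(cohort.beta.loc[planted, tumor].mean().mean())
        body_mean = float(cohort.beta.loc[body, tumor].mean().mean())
        assert planted_mean > body_mean + 0.2
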