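"""End-to-end panel discovery and per-specimen evaluation.

``run_discovery`` chains the full training-side procedure on a cohort:
probe filtering -> dichotomization -> tumor/normal differential testing
(Bonferroni FWER) -> age-correlation screen in normal tissue -> gene-set
enrichment -> panel assembly with within-term correlation pruning ->
candidate-set enumeration -> logistic fitting and likelihood-ratio ranking.
``evaluate_specimen_types`` then scores held-aside specimen types with the
top model and reports AUC / sensitivity / specificity per type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .age import remove_age_related
from .dmr import detect_dmrs
from .evaluate import compare_sample_types, roc_auc, sens_spec_at_threshold
from .features import CandidateFeatureSet, PanelSelector
from .logistic import LogisticModel, predict_prob, rank_models
from .preprocess import dichotomize, filter_probes

__all__ = ["DiscoveryResult", "run_discovery", "evaluate_specimen_types", "CONTROL_TYPE_FOR"]

#: Which zero-purity group serves as the control arm when scoring a
#: case specimen type: tissue-derived cases against matched normal tissue,
#: airway-derived cases against control bronchial washings.
CONTROL_TYPE_FOR = {
    "tumor_tissue": "normal_tissue",
    "bronchial_biopsy": "normal_tissue",
    "bronchial_washing": "control_washing",
    "sputum": "control_washing",
}


@dataclass
class DiscoveryResult:
    dmr_results: pd.DataFrame
    dmr_probes: list[str]
    age_table: pd.DataFrame
    kept_probes: list[str]
    enrichment: pd.DataFrame
    selected_terms: list[str]
    panel: list[str]
    term_probes: dict[str, list[str]]
    correlated_pairs: dict[str, list[tuple[str, str]]]
    candidate_sets: list[CandidateFeatureSet]
    ranked_models: list[tuple[CandidateFeatureSet, LogisticModel]]
    removed_probes: list[str] = field(default_factory=list)

    @property
    def top_model(self) -> LogisticModel:
        return self.ranked_models[0][1]


def run_discovery(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    annotation: pd.DataFrame,
    gene_sets: dict[str, tuple[str, frozenset[str]]],
    *,
    max_missing_fraction: float = 0.05,
    beta_threshold: float = 0.3,
    family_alpha: float = 0.05,
    age_cutoff: float = 1.1e-5,
    go_cutoff: float = 1e-5,
    corr_alpha: float = 0.05,
    n_terms_select: int = 3,
    panel_size: int = 10,
    max_probes_per_term: int = 4,
    max_sets: int = 50,
    top_models: int = 3,
) -> DiscoveryResult:
    """Derive a tumor-specific CpG panel from tumor/matched-normal tissue.

    ``beta`` is probes x samples; ``samples`` must contain tumor_tissue and
    normal_tissue specimens with ages. Defaults mirror the printed analysis
    constants: dichotomization at beta > 0.3, family alpha 0.05 (per-test
    threshold alpha / n probes), age screen at P < 1.1E-05 for positive
    correlations, gene-set Bonferroni cutoff 1.0E-05, within-term Spearman
    alpha 0.05, three terms and a 10-CpG panel.
    """
    sheet = samples.set_index("sample_id")
    tissue_ids = [
        s for s in beta.columns if sheet.loc[s, "specimen_type"] in ("tumor_tissue", "normal_tissue")
    ]
    if not tissue_ids:
        raise ValueError("cohort contains no tumor/normal tissue samples")
    tumor_mask = np.array(
        [sheet.loc[s, "specimen_type"] == "tumor_tissue" for s in tissue_ids], dtype=bool
    )

    filtered, removed = filter_probes(beta, max_missing_fraction)
    binary = dichotomize(filtered[tissue_ids], beta_threshold)
    dmr_results = detect_dmrs(binary, tumor_mask, family_alpha=family_alpha)
    dmr_probes = list(dmr_results.index[dmr_results["passes"]])
    if not dmr_probes:
        raise ValueError("no differentially methylated probes at the family alpha")

    normal_ids = [s for s in tissue_ids if sheet.loc[s, "specimen_type"] == "normal_tissue"]
    ages = sheet.loc[normal_ids, "age"].to_numpy(dtype=float)
    kept, age_table = remove_age_related(
        dmr_probes, filtered[normal_ids], ages, p_cutoff=age_cutoff
    )
    if not kept:
        raise ValueError("age filter removed every differential probe")

    probe_gene = dict(zip(annotation["probe_id"], annotation["gene"]))
    tumor_ids = [s for s in tissue_ids if tumor_mask[tissue_ids.index(s)]]
    selector = PanelSelector(
        gene_sets=gene_sets,
        probe_gene=probe_gene,
        bonferroni_cutoff=go_cutoff,
        corr_alpha=corr_alpha,
        n_select=n_terms_select,
        panel_size=panel_size,
        max_probes_per_term=max_probes_per_term,
        max_sets=max_sets,
    )
    pvals = dmr_results["p_value"].to_dict()
    selector.fit(filtered.loc[kept, tumor_ids].T, probe_pvalues=pvals)

    labels = tumor_mask.astype(int)
    train = filtered.loc[selector.panel_, tissue_ids].T
    ranked = rank_models(selector.candidate_sets_, train, labels, top=top_models)

    return DiscoveryResult(
        dmr_results=dmr_results,
        dmr_probes=dmr_probes,
        age_table=age_table,
        kept_probes=kept,
        enrichment=selector.enrichment_,
        selected_terms=selector.selected_terms_,
        panel=selector.panel_,
        term_probes=selector.term_probes_,
        correlated_pairs=selector.correlated_pairs_,
        candidate_sets=selector.candidate_sets_,
        ranked_models=ranked,
        removed_probes=removed,
    )


def evaluate_specimen_types(
    result: DiscoveryResult,
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    case_types=("tumor_tissue", "bronchial_biopsy", "bronchial_washing"),
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score each case specimen type with the top model against its
    zero-purity control arm; returns AUC / sens / spec per type."""
    model = result.top_model
    sheet = samples.set_index("sample_id")
    rows = []
    for stype in case_types:
        ctrl_type = CONTROL_TYPE_FOR[stype]
        case_ids = [s for s in beta.columns if sheet.loc[s, "specimen_type"] == stype]
        ctrl_ids = [s for s in beta.columns if sheet.loc[s, "specimen_type"] == ctrl_type]
        if not case_ids or not ctrl_ids:
            continue
        feats = beta.loc[list(model.feature_names), case_ids + ctrl_ids].T
        scores = predict_prob(model, feats)
        labels = np.array([1] * len(case_ids) + [0] * len(ctrl_ids))
        sens, spec = sens_spec_at_threshold(scores, labels, threshold)
        rows.append(
            dict(
                specimen_type=stype,
                control_type=ctrl_type,
                auc=roc_auc(scores, labels),
                sensitivity=sens,
                specificity=spec,
                n_cases=len(case_ids),
                n_controls=len(ctrl_ids),
            )
        )
    return pd.DataFrame(rows).set_index("specimen_type")


def surrogate_comparisons(
    result: DiscoveryResult,
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
):
    """The two headline surrogate contrasts on the discovered panel:
    biopsy vs tumor tissue (unpaired rank-sum) and biopsy vs washing
    (patient-paired signed-rank)."""
    pairs = [
        ("bronchial_biopsy", "tumor_tissue", False),
        ("bronchial_biopsy", "bronchial_washing", True),
    ]
    return compare_sample_types(beta, samples, result.panel, pairs, alpha=alpha)
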