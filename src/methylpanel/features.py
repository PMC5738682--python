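"""GO-constrained panel construction.

The panel is built term-first rather than gene-first: differential genes
are tested for over-representation in each gene set (one-sided
hypergeometric test, Bonferroni over the terms tested), enriched terms
supply candidate probes, and probes within the same term whose methylation
levels are significantly correlated in tumor samples are treated as
redundant -- a candidate model never contains both members of a correlated
pair. Candidate feature sets are the cross-term unions of maximal
independent sets of each term's correlation-conflict graph.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .age import spearman_p, spearman_rho

__all__ = [
    "EnrichmentResult",
    "CandidateFeatureSet",
    "go_enrichment",
    "within_term_correlations",
    "maximal_independent_sets",
    "enumerate_candidate_sets",
    "best_probe_per_gene",
    "PanelSelector",
    "EXACT_MIS_MAX_VERTICES",
]

#: Above this many vertices per term the exact maximal-independent-set
#: enumeration is replaced by a single greedy solution.
EXACT_MIS_MAX_VERTICES = 20


@dataclass(frozen=True)
class CandidateFeatureSet:
    """A correlation-consistent probe roster with per-probe term provenance."""

    probes: tuple[str, ...]
    provenance: tuple[tuple[str, str], ...]  # (probe_id, term_id), probe order

    @property
    def size(self) -> int:
        return len(self.probes)


#: Alias kept for symmetry with the enrichment table rows.
EnrichmentResult = pd.Series


def go_enrichment(
    query_genes,
    collection: dict[str, tuple[str, frozenset[str]]],
    background_genes,
    bonferroni_cutoff: float = 1e-5,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    For a term containing K of the N background genes, with n query genes of
    which k fall in the term, p_raw = P(X >= k) for X hypergeometric(N, K, n);
    p_bonferroni = min(1, p_raw * n_terms). ``selected`` flags
    p_bonferroni < cutoff.
    """
    query = frozenset(query_genes)
    background = frozenset(background_genes)
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    n_terms = len(collection)
    if n_terms == 0:
        raise ValueError("empty gene-set collection")
    N, n = len(background), len(query)
    rows = []
    for term_id, (label, genes) in collection.items():
        members = genes & background
        K = len(members)
        k = len(query & members)
        p_raw = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        p_bonf = min(1.0, p_raw * n_terms)
        rows.append(
            dict(
                term_id=term_id,
                label=label,
                k=k,
                K=K,
                n=n,
                N=N,
                p_raw=p_raw,
                p_bonferroni=p_bonf,
                selected=p_bonf < bonferroni_cutoff,
            )
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["p_raw", "term_id"], kind="stable")
        .set_index("term_id")
    )


def within_term_correlations(
    beta_tumor: pd.DataFrame,
    term_probes: dict[str, "list[str]"],
    alpha: float = 0.05,
) -> dict[str, list[tuple[str, str]]]:
    """Spearman-correlated probe pairs within each term (tumor samples).

    ``beta_tumor`` is probes x tumor samples. A pair is flagged when the
    two-sided Spearman p < alpha. Probes with constant methylation are
    skipped with a warning (correlation undefined). Pairs across different
    terms are never tested.
    """
    if beta_tumor.shape[1] < 3:
        raise ValueError("need at least 3 tumor samples")
    flagged: dict[str, list[tuple[str, str]]] = {}
    for term_id, probes in term_probes.items():
        pairs = []
        for p1, p2 in itertools.combinations(sorted(probes), 2):
            x = beta_tumor.loc[p1].to_numpy(dtype=float)
            y = beta_tumor.loc[p2].to_numpy(dtype=float)
            rho = spearman_rho(x, y)
            if np.isnan(rho):
                warnings.warn(f"constant probe in pair ({p1}, {p2}); pair skipped")
                continue
            n = int((~(np.isnan(x) | np.isnan(y))).sum())
            if spearman_p(rho, n) < alpha:
                pairs.append((p1, p2))
        flagged[term_id] = pairs
    return flagged


def maximal_independent_sets(vertices, edges) -> list[tuple[str, ...]]:
    """All maximal independent sets of a small conflict graph, sorted
    lexicographically; greedy single solution beyond the exact-size cap.

    Maximal independent sets are the maximal cliques of the complement
    graph. The greedy fallback adds vertices in the given order, skipping
    conflicts, and returns one set.
    """
    vertices = list(vertices)
    g = nx.Graph()
    g.add_nodes_from(vertices)
    g.add_edges_from(edges)
    if len(vertices) <= EXACT_MIS_MAX_VERTICES:
        comp = nx.complement(g)
        if comp.number_of_nodes() == 0:
            return []
        sets = [tuple(sorted(cl)) for cl in nx.find_cliques(comp)]
        return sorted(sets)
    kept: list[str] = []
    for v in vertices:
        if all(not g.has_edge(v, u) for u in kept):
            kept.append(v)
    return [tuple(sorted(kept))]


def enumerate_candidate_sets(
    selected_terms,
    term_probes: dict[str, "list[str]"],
    correlated_pairs: dict[str, "list[tuple[str, str]]"],
    max_sets: int = 50,
    max_probes_per_term: int | None = None,
) -> list[CandidateFeatureSet]:
    """Cross-term unions of per-term maximal independent sets.

    Per term, the conflict graph has the term's probes as vertices and its
    flagged correlated pairs as edges; its maximal independent sets are the
    admissible per-term rosters. Candidates are all cross-term combinations,
    each term contributing one roster truncated to ``max_probes_per_term``
    probes (in the order given by ``term_probes``, i.e. the caller's
    ranking). Output is deterministic: lexicographic by the combined probe
    roster, capped at ``max_sets``.
    """
    if max_sets < 1:
        raise ValueError("max_sets must be >= 1")
    selected_terms = list(selected_terms)
    if not selected_terms:
        raise ValueError("need at least one selected term")

    per_term: list[list[tuple[str, ...]]] = []
    for term in selected_terms:
        probes = list(term_probes.get(term, []))
        if not probes:
            continue
        rank = {p: i for i, p in enumerate(probes)}
        sets = maximal_independent_sets(probes, correlated_pairs.get(term, []))
        trimmed = set()
        for s in sets:
            ordered = sorted(s, key=rank.__getitem__)
            if max_probes_per_term is not None:
                ordered = ordered[:max_probes_per_term]
            trimmed.add(tuple(sorted(ordered)))
        per_term.append(sorted((term, s) for s in trimmed))
    if not per_term:
        raise ValueError("no probes in any selected term")

    candidates = []
    for combo in itertools.product(*per_term):
        prov = sorted((p, term) for term, roster in combo for p in roster)
        candidates.append(
            CandidateFeatureSet(
                probes=tuple(p for p, _ in prov), provenance=tuple(prov)
            )
        )
    candidates.sort(key=lambda cs: cs.probes)
    return candidates[:max_sets]


def best_probe_per_gene(probes, probe_gene: dict[str, str], probe_pvalues: dict[str, float]):
    """Keep one probe per gene: the smallest-p probe, ties lexicographic."""
    best: dict[str, str] = {}
    for p in probes:
        g = probe_gene[p]
        if g not in best:
            best[g] = p
        else:
            q = best[g]
            if (probe_pvalues.get(p, 1.0), p) < (probe_pvalues.get(q, 1.0), q):
                best[g] = p
    keep = set(best.values())
    return [p for p in probes if p in keep]


class PanelSelector(BaseEstimator):
    """End-to-end panel construction from differential probes.

    ``fit(X, y=None, probe_pvalues=...)`` takes tumor-sample beta values
    (samples x probes, columns restricted to the age-filtered differential
    probes) plus each probe's differential p-value, runs enrichment over
    ``gene_sets``, keeps the ``n_select`` most enriched selected terms,
    assembles each term's probes (one per gene, best differential p first),
    caps the panel at ``panel_size`` probes round-robin across terms, tests
    within-term correlations and enumerates candidate feature sets.

    Fitted attributes: ``enrichment_``, ``selected_terms_``,
    ``term_probes_``, ``correlated_pairs_``, ``panel_``,
    ``candidate_sets_``.
    """

    def __init__(
        self,
        gene_sets: dict[str, tuple[str, frozenset[str]]] = None,
        probe_gene: dict[str, str] = None,
        background_genes=None,
        bonferroni_cutoff: float = 1e-5,
        corr_alpha: float = 0.05,
        n_select: int = 3,
        panel_size: int = 10,
        max_probes_per_term: int = 4,
        max_sets: int = 50,
    ):
        self.gene_sets = gene_sets
        self.probe_gene = probe_gene
        self.background_genes = background_genes
        self.bonferroni_cutoff = bonferroni_cutoff
        self.corr_alpha = corr_alpha
        self.n_select = n_select
        self.panel_size = panel_size
        self.max_probes_per_term = max_probes_per_term
        self.max_sets = max_sets

    def fit(self, X, y=None, probe_pvalues: dict[str, float] | None = None):
        if self.gene_sets is None or self.probe_gene is None:
            raise ValueError("gene_sets and probe_gene are required")
        X = pd.DataFrame(X)
        probes = list(X.columns)
        pvals = probe_pvalues or {}
        genes = {self.probe_gene[p] for p in probes}
        background = (
            frozenset(self.background_genes)
            if self.background_genes is not None
            else frozenset(self.probe_gene.values())
        )
        self.enrichment_ = go_enrichment(
            genes, self.gene_sets, background, bonferroni_cutoff=self.bonferroni_cutoff
        )
        selected = self.enrichment_[self.enrichment_["selected"]]
        self.selected_terms_ = list(selected.index[: self.n_select])
        if not self.selected_terms_:
            raise ValueError("no gene set passed the enrichment cutoff")

        # Per-term probe rosters: query probes whose gene is in the term,
        # one probe per gene, ordered by differential p-value.
        deduped = best_probe_per_gene(probes, self.probe_gene, pvals)
        term_probes: dict[str, list[str]] = {}
        for term in self.selected_terms_:
            members = self.gene_sets[term][1]
            tp = [p for p in deduped if self.probe_gene[p] in members]
            tp.sort(key=lambda p: (pvals.get(p, 1.0), p))
            term_probes[term] = tp

        # Panel: round-robin across terms by rank until panel_size reached.
        panel: list[str] = []
        for rank in range(max((len(v) for v in term_probes.values()), default=0)):
            for term in self.selected_terms_:
                tp = term_probes[term]
                if rank < len(tp) and len(panel) < self.panel_size:
                    panel.append(tp[rank])
        self.panel_ = panel
        panel_set = set(panel)
        self.term_probes_ = {
            t: [p for p in tp if p in panel_set] for t, tp in term_probes.items()
        }

        self.correlated_pairs_ = within_term_correlations(
            X.T.loc[list(panel)], self.term_probes_, alpha=self.corr_alpha
        )
        self.candidate_sets_ = enumerate_candidate_sets(
            self.selected_terms_,
            self.term_probes_,
            self.correlated_pairs_,
            max_sets=self.max_sets,
            max_probes_per_term=self.max_probes_per_term,
        )
        return self
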