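# Methods

## Statistical model and procedure

The pipeline treats a 450K-style β value as a methylated-allele fraction,
β = M/(M+U+offset) ∈ [0, 1], measured on a mixed cell population. The
working model for any specimen is a two-compartment mixture

    β_obs = clip( π·β_tumor + (1 − π)·β_bg + ε, 0, 1 ),  ε ~ N(0, σ²),

where π is the specimen's tumor-cell fraction. Tumor-specific
hypermethylation is therefore attenuated linearly in π, which is the
mechanism the surrogate-specimen analysis probes: resected tumor tissue and
forceps biopsies carry high π, bronchial washing and sputum are dominated
by exfoliated normal epithelium (π near 0), and matched normal tissue and
washings from cancer-free controls carry π = 0.

Discovery proceeds on tumor/matched-normal tissue pairs:

1. probes with too many missing values are dropped (missing-fraction
   cutoff, default 0.05);
2. β is dichotomized at β > 0.3 — strictly above, because the array's
   background signal in unmethylated DNA occupies roughly the 0–0.3 band;
3. each probe's 2×2 table (tumor/normal × methylated/unmethylated) is
   tested with Pearson's χ² (1 df, no continuity correction) or, when any
   expected cell count is below 5 (Cochran's rule), with the two-sided
   Fisher exact test (sum of hypergeometric probabilities of all
   margin-preserving tables no more probable than the observed one);
4. the family-wise error rate is Bonferroni-controlled: a probe passes at
   p ≤ α/N for N probes tested (0.05/480,912 rounds to 1.0E-07), and only
   tumor-hypermethylated probes pass the default direction filter;
5. probes whose methylation in normal tissue rises with age (Spearman
   ρ > 0, P below the screen cutoff, default 1.1E-05) are removed. The
   cutoff numerically equals 0.05/4,726 at two significant figures — a
   Bonferroni correction over a differential set of that size — but it is
   exposed as a plain constant, since that inference is not certain;
6. the genes of the surviving probes are tested for over-representation in
   each gene set by the one-sided hypergeometric (Fisher) test with
   Bonferroni correction over terms (cutoff 1.0E-05); the most enriched
   selected terms (default 3) structure the panel;
7. within each term, CpG pairs whose tumor-sample methylation levels are
   Spearman-correlated at P < 0.05 are declared redundant. Candidate
   panels are maximal independent sets of the per-term conflict graph
   (exact enumeration via complement-graph cliques up to 20 vertices per
   term, greedy beyond), combined across terms, each term truncated to its
   best probes by differential p-value;
8. each candidate is fitted by unpenalized maximum-likelihood logistic
   regression and candidates are ranked by deviance (−2 log L), ties broken
   by fewer features then lexicographic roster. Both raw deviance and the
   null-relative likelihood-ratio statistic are reported, because
   near-separating panels push raw deviance toward 0 and deviances of that
   magnitude are only interpretable alongside the null value.

Evaluation uses AUC in its Mann–Whitney concordance form (probability a
random case outscores a random control, ties 0.5 — identical to the
empirical ROC area, no interpolation needed), sensitivity/specificity with
positives called at predicted probability ≥ 0.5 (inclusive), and Wilcoxon
tests for specimen-type concordance: rank-sum for independent groups,
signed-rank on patient-paired differences.

## Exact small-sample branches

Statistical routines switch to exact null distributions where they are
attainable, since the surrogate comparisons involve as few as 8 biopsies:

- Fisher's exact test: always exact (scipy), verified in the test suite
  against integer-arithmetic enumeration of every 2×2 table with total ≤ 40;
- rank-sum: exact when min(n) ≤ 10 and the pooled data are tie-free,
  otherwise normal approximation with tie and continuity correction;
- signed-rank: zeros dropped (Wilcoxon's original treatment; the Pratt
  variant is intentionally not default), exact over the 2ⁿ sign patterns
  for n ≤ 20 tie-free differences, normal approximation otherwise. Eight
  uniformly shifted pairs therefore bottom out at p = 2/2⁸ = 0.0078125;
- Spearman p: exact permutation null for n < 10, t-approximation
  t = ρ√((n−2)/(1−ρ²)) with n−2 df for n ≥ 10 (underflows to 0 at |ρ| = 1,
  documented); mid-ranks for ties throughout.

Logistic fits use Newton/IRLS on the score equations with step-halving,
convergence when the max absolute score falls below 1e-8 (max 100
iterations), and an optional ridge penalty (off by default). Complete or
quasi-complete separation — the expected regime for high-purity tumor
panels — is flagged when any |coefficient| exceeds 15 on the logit scale;
separated but converged fits are retained and flagged rather than
discarded, since panel ranking by deviance remains well-defined. The
fitter is cross-checked against statsmodels and scikit-learn in the tests.

## The synthetic cohort generator

`generate_cohort` emulates the data layout of a surgery-plus-bronchoscopy
methylation study: 42 tumor/normal tissue pairs (shared patient id and
age), 76 cancer and 60 control bronchial washings, 8 biopsies and 12 sputa
patient-paired with washings. Defaults, with rationale:

| parameter | default | meaning / why |
|---|---|---|
| `n_probes` | 5,000 | array scaled ~100× down from 485k; keeps every Monte-Carlo suite in seconds while leaving the Bonferroni threshold meaningfully small (1e-5) |
| `n_diff_probes` | 50 | planted tumor-hypermethylated CpGs |
| `n_age_probes` | 5 | planted age-correlated CpGs (also tumor-hypermethylated: in the emulated analysis the age CpGs were removed *from* the differential set, so they must be detectable as differential first) |
| `background_shape` | Beta(2, 18) | non-tumor compartment: mean 0.10, 99% of mass below the 0.3 threshold — the assay's background band |
| `tumor_shape` | Beta(6.5, 3.5) | planted probes in tumor cells: mean 0.65, left-skewed, matching the negative skew of tumor β distributions |
| `purity_by_type` | tumor 0.70, biopsy 0.70, washing 0.10, sputum 0.05, normal/control 0 | see below |
| `age_slope` | 0.010 /year | drift of age probes in the normal-cell compartment of normal tissue, anchored at the cohort mean age; calibrated so 42 normals yield ρ ≈ 0.7–0.8, the magnitude that survives a P < 1.1E-05 screen (an observed age CpG in this regime has ρ ≈ 0.64). Slopes near 0.004 give ρ ≈ 0.5, which that screen cannot detect at n = 42 |
| `noise_sd` | 0.03 | technical replicate-scale noise on the β scale, added after mixing, then clipped |
| `age_range` | 40–75 y | uniform patient ages |
| `n_terms`, `genes_per_term` | 30, 40 | gene-set scaffold; planted differential genes are partitioned round-robin across the first three terms (transcription regulation, cell–cell signaling, cell–cell adhesion), padded with unplanted genes; background terms contain unplanted genes only |

Biopsy purity defaults to tumor purity (0.70). The empirical claim being
emulated is that biopsy methylation is statistically indistinguishable
from resected tumor; at 8 biopsies vs 42 tumors the rank-sum test has
~25–30% power against even a 0.5-sd shift, so a visibly lower biopsy
purity (0.60, or the literature's 33.4% mean tumor area in a biopsy)
produces detectable discordance and contradicts that claim. Both lower
values ship as presets (`BIOPSY_PURITY_PRESETS`), and purity is an
explicit knob because the mechanism reconciling low measured tumor area
with tissue-like methylation is unresolved.

Non-differential probes share one methylation state between the two
compartments, so their distribution is identical in every specimen type —
the global null is exactly null. One RNG stream keyed by `seed` drives all
draws; a fixed seed reproduces the matrix bit for bit.

**What the generator does not emulate:** Infinium type-I/II probe
chemistry and its bias (and hence dasen-style normalization), detection
p-values and bead counts, SNP-overlapping or cross-reactive probes,
per-patient purity variation, co-methylation blocks and genomic
autocorrelation, inflammatory-cell admixture in sputum, and histology
effects. Passing recovery tests therefore demonstrate the pipeline's
statistical machinery under the purity-mixture model, not robustness to
array artifacts — on real data the preprocessing choices upstream of this
package (normalization, probe masking) carry that burden.

## Numerical conventions and edge cases

- Dichotomization uses strict inequality (β = 0.30 → unmethylated);
  configurable.
- β offset defaults to 0 (plain intensity ratio); an Illumina-style
  offset can be passed.
- Missing values: excluded pairwise everywhere (contingency tallies,
  correlations, means); probes exceeding the missing-fraction cutoff are
  dropped up front; all-missing rows raise.
- Degenerate 2×2 margins: χ² raises (the caller's routing never sends
  them there); Fisher returns p = 1 for flat tables.
- Constant vectors make Spearman's ρ undefined → NaN, and such probes are
  skipped (with a warning) in correlation pruning.
- Paired comparisons with all-zero differences report p = 1.0 (no
  evidence of difference) at the pipeline level, while the bare
  signed-rank function treats all-zero input as an error.
- Ties everywhere: mid-ranks; AUC ties count 0.5.
- Tie-breaking in enumeration and ranking is lexicographic by probe id,
  making every output order deterministic.
- Matched tumor/normal pairs are deliberately treated as independent
  groups in the contingency tests (no McNemar), reproducing the emulated
  analysis rather than the orthodox paired test.
- Per-probe concordance summaries use α = 0.05 per CpG without
  multiplicity correction, mirroring per-CpG reporting practice in this
  literature.

## Problem sizes in the test suite

The Monte-Carlo suites run at sizes chosen to make their guarantees sharp
but cheap: family-wise error under the global null uses 100 cohorts of
1,000 probes (the Bonferroni guarantee is probe-count-free); planted-truth
recovery and the surrogate pattern use 20 default-condition cohorts
(5,000 probes); logistic parameter recovery uses one draw of n = 2,000 and
null-uniformity 200 replicates of n = 200. Exact-test oracles enumerate
every 2×2 table with total ≤ 40 and all rank splits / sign patterns for
the small-sample Wilcoxon branches.

## Known limitations

- The hypergeometric enrichment test is a deliberate, transparent stand-in
  for fuzzy annotation clustering; it tests single-term
  over-representation only.
- When a gene carries several differential CpGs the smallest-p probe
  represents it; other within-gene probes are only visible through
  `region_profile`.
- Maximal-independent-set enumeration is exact only up to 20 probes per
  term; beyond that a single greedy solution is returned.
- The 8-vs-42 rank-sum comparison has low power by construction (it
  reflects the available specimen counts); "concordant" there means
  "no detectable difference", not equivalence.
- Narrowing enriched terms to three is exposed as an explicit parameter
  (`n_terms_select`) ranked by enrichment p; any performance-based term
  selection is left to the user to avoid circularity.
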