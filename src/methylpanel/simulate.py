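"""Synthetic 450K-style methylation cohorts with planted ground truth.

The generator emulates the data a bronchoscopy/surgery methylation study
produces: a probes x samples matrix of beta values (methylated-allele
fractions in [0, 1]) for six specimen types, a sample sheet with patient
pairing, a probe -> gene -> region-class annotation scaffold, and a GMT
gene-set collection that groups the planted tumor-specific genes into three
functional categories (transcription regulation, cell-cell signaling,
cell-cell adhesion).

The measurement model for one probe in one specimen is a two-compartment
cell mixture,

    beta = clip( pi * beta_tumor + (1 - pi) * beta_background + eps, 0, 1 )

where ``pi`` is the tumor-cell fraction (purity) of the specimen type,
``beta_tumor`` and ``beta_background`` are the true methylation fractions of
the tumor and non-tumor cell compartments, and ``eps`` is Gaussian
measurement noise. Non-differential probes share one methylation state
between the two compartments, so their observed distribution is identical in
every specimen type regardless of purity. Planted differential probes draw
the tumor compartment from a left-skewed high-methylation Beta distribution;
the background compartment everywhere follows a low-mean Beta whose mass
lies almost entirely below the 0.3 dichotomization threshold, mimicking the
array's background signal in unmethylated DNA.

Planted age probes are tumor-hypermethylated *and* drift linearly with
patient age in the normal-cell compartment of normal tissue, so they surface
as tumor/normal differential probes and are then caught by the age filter --
the order in which a real analysis encounters them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "Cohort",
    "sample_beta",
    "generate_cohort",
    "write_cohort",
    "SPECIMEN_TYPES",
    "REGION_CLASSES",
    "PROMOTER_CLASSES",
]

SPECIMEN_TYPES = (
    "tumor_tissue",
    "normal_tissue",
    "bronchial_biopsy",
    "bronchial_washing",
    "sputum",
    "control_washing",
)

#: Probe location classes relative to the transcription start site, in the
#: conventional promoter-to-body order.
REGION_CLASSES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body")
PROMOTER_CLASSES = ("TSS1500", "TSS200", "5UTR", "1stExon")

_SAMPLE_PREFIX = {
    "tumor_tissue": "LTT",
    "normal_tissue": "LNT",
    "bronchial_biopsy": "LCB",
    "bronchial_washing": "BWC",
    "sputum": "SPT",
    "control_washing": "BWN",
}

#: Cohort arm sizes of the study design being emulated: 42 resected tumor /
#: matched normal pairs, 76 cancer and 60 control bronchial washings, 8
#: paired bronchial biopsies, 12 sputum samples.
DEFAULT_ARM_SIZES = {
    "tumor_tissue": 42,
    "normal_tissue": 42,
    "bronchial_biopsy": 8,
    "bronchial_washing": 76,
    "sputum": 12,
    "control_washing": 60,
}

#: Tumor-cell fraction per specimen type. Washing and sputum are dominated
#: by exfoliated normal bronchial epithelial cells, hence near-zero purity.
#: Biopsy defaults to tumor-tissue purity because the empirical finding being
#: emulated is that biopsy methylation is statistically indistinguishable
#: from resected tumor; see docs/methods.md for the reasoning and for the
#: lower presets below.
DEFAULT_PURITY = {
    "tumor_tissue": 0.70,
    "normal_tissue": 0.0,
    "bronchial_biopsy": 0.70,
    "bronchial_washing": 0.10,
    "sputum": 0.05,
    "control_washing": 0.0,
}

#: Alternative biopsy purity presets: the literature's mean tumor area in a
#: bronchial biopsy (33.4%) and an intermediate value.
BIOPSY_PURITY_PRESETS = {"literature_tumor_area": 0.334, "intermediate": 0.60}


@dataclass
class GeneratorConfig:
    """Study conditions for :func:`generate_cohort`.

    Parameters
    ----------
    n_probes, n_diff_probes, n_age_probes
        Total probes, planted tumor-hypermethylated probes, and planted
        age-correlated probes (the latter two disjoint).
    arm_sizes
        Samples per specimen type; tumor and normal tissue must be equal
        (matched pairs), biopsies and sputa are drawn from washing patients.
    purity_by_type
        Tumor-cell fraction pi in [0, 1] per specimen type.
    background_shape, tumor_shape
        Beta-distribution (a, b) for the non-tumor compartment (mean 0.10,
        ~99% of mass below 0.3) and for planted probes in tumor cells
        (mean 0.65, left-skewed).
    age_slope
        Beta increase per year at planted age probes in the normal-cell
        compartment of normal tissue (default 0.010/year, calibrated so the
        induced Spearman correlation in 42 normals matches the gamma ~ 0.64+
        magnitude that survives a P < 1.1E-05 screen).
    noise_sd
        SD of additive Gaussian measurement noise on the clipped beta scale.
    age_range
        Uniform patient-age range in years.
    n_terms, genes_per_term
        Gene-set scaffold: total GO-like terms and genes per term; planted
        differential genes are partitioned across the first three terms.
    seed
        Generator seed; a single global RNG stream is derived from it.
    """

    n_probes: int = 5000
    n_diff_probes: int = 50
    n_age_probes: int = 5
    arm_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ARM_SIZES))
    purity_by_type: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PURITY))
    background_shape: tuple[float, float] = (2.0, 18.0)
    tumor_shape: tuple[float, float] = (6.5, 3.5)
    age_slope: float = 0.010
    noise_sd: float = 0.03
    age_range: tuple[float, float] = (40.0, 75.0)
    n_terms: int = 30
    genes_per_term: int = 40
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if self.n_diff_probes < 0 or self.n_age_probes < 0:
            raise ValueError("planted probe counts must be non-negative")
        if self.n_diff_probes + self.n_age_probes > self.n_probes:
            raise ValueError("n_diff_probes + n_age_probes exceeds n_probes")
        if self.arm_sizes.get("tumor_tissue", 0) != self.arm_sizes.get("normal_tissue", 0):
            raise ValueError("tumor and normal tissue arms must be equal (matched pairs)")
        if self.arm_sizes.get("bronchial_biopsy", 0) > self.arm_sizes.get("bronchial_washing", 0):
            raise ValueError("biopsies are paired with washing patients")
        if self.arm_sizes.get("sputum", 0) > self.arm_sizes.get("bronchial_washing", 0):
            raise ValueError("sputum samples are drawn from washing patients")
        for stype, n in self.arm_sizes.items():
            if n > 0 and stype not in self.purity_by_type:
                raise ValueError(f"purity_by_type is missing specimen type {stype!r}")
        for stype, pi in self.purity_by_type.items():
            if not 0.0 <= pi <= 1.0:
                raise ValueError(f"purity for {stype!r} outside [0, 1]")
        for name in ("background_shape", "tumor_shape"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} parameters must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.age_range[0] >= self.age_range[1] or self.age_range[0] <= 0:
            raise ValueError("age_range must be an increasing positive interval")
        if self.n_terms < 3:
            raise ValueError("need at least 3 terms to host the planted categories")


@dataclass
class SyntheticTruth:
    """Planted ground truth: the oracle for recovery tests."""

    diff_probe_ids: frozenset[str]
    age_probe_ids: frozenset[str]
    purity_per_sample: dict[str, float]
    config: GeneratorConfig

    def __post_init__(self) -> None:
        if self.diff_probe_ids & self.age_probe_ids:
            raise ValueError("differential and age probe sets must be disjoint")


@dataclass
class Cohort:
    """One generated cohort: beta matrix (probes x samples), sample sheet,
    probe annotation, gene sets, and the planted truth."""

    beta: pd.DataFrame
    samples: pd.DataFrame
    annotation: pd.DataFrame
    gene_sets: dict[str, tuple[str, frozenset[str]]]
    truth: SyntheticTruth


def sample_beta(true_tumor_beta, true_background_beta, purity, noise_sd, rng=None):
    """Observed beta of one probe in one specimen under the mixture model.

    clip(pi * beta_tumor + (1 - pi) * beta_background + eps, 0, 1) with
    eps ~ Normal(0, noise_sd). ``rng`` may be omitted when noise_sd is 0.
    """
    t = np.asarray(true_tumor_beta, dtype=float)
    b = np.asarray(true_background_beta, dtype=float)
    pi = np.asarray(purity, dtype=float)
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("purity must lie in [0, 1]")
    if np.any((t < 0) | (t > 1)) or np.any((b < 0) | (b > 1)):
        raise ValueError("beta fractions must lie in [0, 1]")
    mix = pi * t + (1.0 - pi) * b
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        mix = mix + rng.normal(0.0, noise_sd, size=np.shape(mix))
    out = np.clip(mix, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _build_samples(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample sheet with patient pairing: tumor/normal pairs share a surgical
    patient; biopsy and sputum attach to the first washing patients."""
    arms = cfg.arm_sizes
    lo, hi = cfg.age_range
    rows = []

    n_surg = arms.get("tumor_tissue", 0)
    surg_age = rng.uniform(lo, hi, size=n_surg)
    surg_sex = rng.choice(["M", "F"], size=n_surg, p=[0.76, 0.24])
    surg_hist = rng.choice(
        ["adenocarcinoma", "squamous", "other"], size=n_surg, p=[27 / 42, 8 / 42, 7 / 42]
    )
    for i in range(n_surg):
        pid = f"SURG{i + 1:03d}"
        for stype in ("tumor_tissue", "normal_tissue"):
            rows.append(
                dict(
                    sample_id=f"{_SAMPLE_PREFIX[stype]}{i + 1:03d}",
                    patient_id=pid,
                    specimen_type=stype,
                    disease_label="cancer",
                    age=surg_age[i],
                    sex=surg_sex[i],
                    histology=surg_hist[i],
                )
            )

    n_wash = arms.get("bronchial_washing", 0)
    wash_age = rng.uniform(lo, hi, size=n_wash)
    wash_sex = rng.choice(["M", "F"], size=n_wash, p=[0.78, 0.22])
    wash_hist = rng.choice(
        ["adenocarcinoma", "squamous", "other"], size=n_wash, p=[44 / 76, 22 / 76, 10 / 76]
    )
    n_biopsy = arms.get("bronchial_biopsy", 0)
    n_sputum = arms.get("sputum", 0)
    for i in range(n_wash):
        pid = f"BRON{i + 1:03d}"
        rows.append(
            dict(
                sample_id=f"BWC{i + 1:03d}",
                patient_id=pid,
                specimen_type="bronchial_washing",
                disease_label="cancer",
                age=wash_age[i],
                sex=wash_sex[i],
                histology=wash_hist[i],
            )
        )
        if i < n_biopsy:
            rows.append(
                dict(
                    sample_id=f"LCB{i + 1:03d}",
                    patient_id=pid,
                    specimen_type="bronchial_biopsy",
                    disease_label="cancer",
                    age=wash_age[i],
                    sex=wash_sex[i],
                    histology=wash_hist[i],
                )
            )
        if i < n_sputum:
            rows.append(
                dict(
                    sample_id=f"SPT{i + 1:03d}",
                    patient_id=pid,
                    specimen_type="sputum",
                    disease_label="cancer",
                    age=wash_age[i],
                    sex=wash_sex[i],
                    histology=wash_hist[i],
                )
            )

    n_ctrl = arms.get("control_washing", 0)
    ctrl_age = rng.uniform(lo, hi, size=n_ctrl)
    ctrl_sex = rng.choice(["M", "F"], size=n_ctrl)
    for i in range(n_ctrl):
        rows.append(
            dict(
                sample_id=f"BWN{i + 1:03d}",
                patient_id=f"CTRL{i + 1:03d}",
                specimen_type="control_washing",
                disease_label="control",
                age=ctrl_age[i],
                sex=ctrl_sex[i],
                histology="",
            )
        )
    return pd.DataFrame(rows)


def _build_annotation(
    cfg: GeneratorConfig, probe_ids: np.ndarray, planted: np.ndarray
) -> pd.DataFrame:
    # One probe -> one gene scaffold; planted probes are biased to promoter
    # region classes so the promoter-vs-body contrast is reproducible.
    genes = np.array([f"GENE{i + 1:05d}" for i in range(cfg.n_probes)])
    region = np.array([REGION_CLASSES[i % len(REGION_CLASSES)] for i in range(cfg.n_probes)])
    planted_idx = np.flatnonzero(planted)
    region[planted_idx] = [
        PROMOTER_CLASSES[j % len(PROMOTER_CLASSES)] for j in range(planted_idx.size)
    ]
    return pd.DataFrame({"probe_id": probe_ids, "gene": genes, "region_class": region})


_PLANTED_TERMS = (
    ("GO:0006355", "transcription_regulation"),
    ("GO:0007267", "cell_cell_signaling"),
    ("GO:0098609", "cell_cell_adhesion"),
)


def _build_gene_sets(
    cfg: GeneratorConfig,
    annotation: pd.DataFrame,
    diff_idx: np.ndarray,
    age_idx: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, tuple[str, frozenset[str]]]:
    """Partition planted differential genes round-robin across the three
    special terms; pad with unplanted genes; remaining terms hold unplanted
    genes only."""
    genes = annotation["gene"].to_numpy()
    diff_genes = genes[diff_idx]
    planted_all = set(genes[diff_idx]) | set(genes[age_idx])
    free = np.array(sorted(set(genes) - planted_all))

    collection: dict[str, tuple[str, frozenset[str]]] = {}
    buckets: list[list[str]] = [[], [], []]
    for j, g in enumerate(diff_genes):
        buckets[j % 3].append(g)
    for (term_id, label), members in zip(_PLANTED_TERMS, buckets):
        pad = max(0, cfg.genes_per_term - len(members))
        extra = rng.choice(free, size=min(pad, free.size), replace=False)
        collection[term_id] = (label, frozenset(members) | frozenset(extra))
    for t in range(cfg.n_terms - 3):
        members = rng.choice(free, size=min(cfg.genes_per_term, free.size), replace=False)
        collection[f"GO:9{t + 1:06d}"] = (f"background_process_{t + 1}", frozenset(members))
    return collection


def generate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a full cohort deterministically from ``config.seed``.

    ``seed``, when given, overrides ``config.seed``. All randomness flows
    through a single ``numpy`` Generator, so a fixed seed reproduces the
    matrix bit for bit.
    """
    cfg = dataclasses.replace(config) if config is not None else GeneratorConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    probe_ids = np.array([f"cg{i + 1:08d}" for i in range(cfg.n_probes)])
    planted_idx = rng.choice(cfg.n_probes, size=cfg.n_diff_probes + cfg.n_age_probes, replace=False)
    diff_idx = np.sort(planted_idx[: cfg.n_diff_probes])
    age_idx = np.sort(planted_idx[cfg.n_diff_probes :])
    planted_mask = np.zeros(cfg.n_probes, dtype=bool)
    planted_mask[planted_idx] = True

    samples = _build_samples(cfg, rng)
    annotation = _build_annotation(cfg, probe_ids, planted_mask)
    gene_sets = _build_gene_sets(cfg, annotation, diff_idx, age_idx, rng)

    n_samples = len(samples)
    a0, b0 = cfg.background_shape
    at, bt = cfg.tumor_shape

    # Non-tumor compartment: one methylation state per (probe, sample).
    bg = rng.beta(a0, b0, size=(cfg.n_probes, n_samples))
    # Tumor compartment shares the background state except at planted probes.
    tum = bg.copy()
    n_planted = planted_idx.size
    if n_planted:
        tum[np.concatenate([diff_idx, age_idx]), :] = rng.beta(at, bt, size=(n_planted, n_samples))

    # Age drift in the normal-cell compartment of normal tissue, anchored at
    # the cohort mean age so the baseline stays at the background mean and
    # age probes remain tumor-specific (detectable as DMRs) at every age.
    if age_idx.size:
        is_normal = (samples["specimen_type"] == "normal_tissue").to_numpy()
        mid_age = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
        drift = cfg.age_slope * (samples["age"].to_numpy() - mid_age)
        bg[np.ix_(age_idx, is_normal)] = np.clip(
            bg[np.ix_(age_idx, is_normal)] + drift[is_normal], 0.0, 1.0
        )

    purity = samples["specimen_type"].map(cfg.purity_by_type).to_numpy(dtype=float)
    mix = purity[np.newaxis, :] * tum + (1.0 - purity[np.newaxis, :]) * bg
    if cfg.noise_sd > 0:
        mix = mix + rng.normal(0.0, cfg.noise_sd, size=mix.shape)
    beta = pd.DataFrame(
        np.clip(mix, 0.0, 1.0), index=probe_ids, columns=samples["sample_id"].to_numpy()
    )
    beta.index.name = "probe_id"

    truth = SyntheticTruth(
        diff_probe_ids=frozenset(probe_ids[diff_idx]),
        age_probe_ids=frozenset(probe_ids[age_idx]),
        purity_per_sample=dict(zip(samples["sample_id"], purity)),
        config=cfg,
    )
    return Cohort(beta=beta, samples=samples, annotation=annotation, gene_sets=gene_sets, truth=truth)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write beta TSV, sample sheet CSV, annotation TSV, GMT, truth JSON."""
    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "samples": outdir / "samples.csv",
        "annotation": outdir / "annotation.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.json",
    }
    mio.write_beta(cohort.beta, paths["beta"])
    cohort.samples.to_csv(paths["samples"], index=False)
    cohort.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    mio.write_gmt(cohort.gene_sets, paths["gene_sets"])
    truth = cohort.truth
    payload = {
        "diff_probe_ids": sorted(truth.diff_probe_ids),
        "age_probe_ids": sorted(truth.age_probe_ids),
        "purity_per_sample": truth.purity_per_sample,
        "config": dataclasses.asdict(truth.config),
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths
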