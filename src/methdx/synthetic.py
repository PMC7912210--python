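"""Synthetic paired case/control methylome + transcriptome cohorts.

Generates an Illumina-450K-style study — a probe-level beta matrix with the
bimodal marginal typical of array methylation data, a log2 expression matrix,
a probe annotation (gene + region label), sample group labels and a planted
ground truth — so every downstream stage (differential expression and
methylation, dominant-region detection, integration, classification) can be
tested against known effects without any external download.

Planted effects follow the negative-coupling convention: a *hypo-up* gene is
hypo-methylated in 1-2 of its gene regions in cases and up-regulated in
expression; a *hyper-down* gene is the mirror image. The regions that carry
the methylation shift are recorded per gene so dominant-region recovery is a
measurable task.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical gene-region labels, in the fixed order used for tie-breaking.
REGIONS: tuple[str, ...] = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")

INTERGENIC = "Intergenic"

#: Placeholder gene field for intergenic probes in annotation tables.
NO_GENE = "."

#: Upper clip bound keeping beta values strictly below 1.
BETA_MAX = 1.0 - 1e-6

#: Expected Poisson CpG count per region for an average gene. Gene bodies are
#: long and CpG-rich relative to the short promoter-proximal intervals.
DEFAULT_REGIONS_PER_GENE: Mapping[str, float] = {
    "TSS1500": 2.0,
    "TSS200": 1.5,
    "5UTR": 1.0,
    "1stExon": 1.0,
    "Body": 3.0,
    "3UTR": 1.0,
}


class InvalidConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic case/control study.

    Defaults mimic a blood methylation cohort with a 2:1 case:control ratio
    and moderate planted effects: a beta shift of 0.08 in the affected
    region(s) and a one-unit log2 fold-change, against per-entry noise of
    0.05 beta units and 0.5 log2 units.

    Methylation noise has three components: per-probe technical dispersion
    (``beta_dispersion``), a per-(gene, sample) biological effect shared by
    the gene's CpGs (``beta_gene_sd``), and a per-sample global offset
    shared by every CpG of a subject (``beta_subject_sd``, mimicking
    subject-level drivers such as cell composition). The correlated
    components do not average away over many genes, so methylation
    classifiers stay imperfect per sample even when group-level tests detect
    the planted genes — expression effects carry only independent noise and
    dominate, as they do in the blood cohorts this generator emulates.
    """

    n_case: int = 100
    n_control: int = 50
    n_genes: int = 200
    n_intergenic_cpgs: int = 100
    regions_per_gene: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS_PER_GENE)
    )
    frac_hypo_up: float = 0.1
    frac_hyper_down: float = 0.1
    delta_beta_effect: float = 0.08
    log2fc_effect: float = 1.0
    expr_sd: float = 0.5
    beta_dispersion: float = 0.05
    beta_subject_sd: float = 0.04
    beta_gene_sd: float = 0.03
    coupling: str = "negative"
    split_cohorts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_genes"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_intergenic_cpgs < 0:
            raise InvalidConfigError("n_intergenic_cpgs must be >= 0")
        if not 0.0 <= self.frac_hypo_up <= 1.0 or not 0.0 <= self.frac_hyper_down <= 1.0:
            raise InvalidConfigError("effect fractions must lie in [0, 1]")
        if self.frac_hypo_up + self.frac_hyper_down > 1.0:
            raise InvalidConfigError("frac_hypo_up + frac_hyper_down must not exceed 1")
        if not 0.0 <= self.delta_beta_effect < 0.5:
            raise InvalidConfigError("delta_beta_effect must lie in [0, 0.5)")
        if min(self.expr_sd, self.beta_dispersion,
               self.beta_subject_sd, self.beta_gene_sd) < 0:
            raise InvalidConfigError("noise scales must be non-negative")
        if self.coupling not in ("negative", "positive"):
            raise InvalidConfigError("coupling must be 'negative' or 'positive'")
        unknown = set(self.regions_per_gene) - set(REGIONS)
        if unknown:
            raise InvalidConfigError(f"unknown region labels: {sorted(unknown)}")


@dataclass
class SyntheticStudy:
    """One generated cohort: data matrices, annotation, labels and truth.

    ``truth`` is indexed by gene with columns ``is_hypo_up``,
    ``is_hyper_down``, ``log2fc`` (planted expression shift), ``delta_beta``
    (planted beta shift, signed) and ``dominant_regions`` (tuple of region
    labels carrying the shift; empty for null genes).
    """

    expression: pd.DataFrame
    beta: pd.DataFrame
    annotation: pd.DataFrame
    samples: pd.Series
    meth_samples: pd.Series
    truth: pd.DataFrame
    config: CohortConfig


def generate_annotation(
    n_genes: int,
    n_intergenic: int,
    regions_per_gene: Mapping[str, float] | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Build a probe annotation table mapping probes to (gene, region).

    ``regions_per_gene`` maps region label to a CpG-count distribution: a
    float is a Poisson mean, an int is an exact per-gene count (missing
    labels mean zero CpGs). A gene drawing zero CpGs everywhere is given a
    single Body CpG so every gene is observable.
    Intergenic probes carry the region label ``Intergenic`` and the
    placeholder gene ``"."``.

    Returns a DataFrame with columns ``probe_id``, ``gene``, ``region``;
    probe ids are unique, gene-mapped probes carry exactly one region label.
    """
    if n_genes < 1:
        raise InvalidConfigError(f"n_genes must be >= 1, got {n_genes}")
    if n_intergenic < 0:
        raise InvalidConfigError(f"n_intergenic must be >= 0, got {n_intergenic}")
    lams = dict(DEFAULT_REGIONS_PER_GENE if regions_per_gene is None else regions_per_gene)
    unknown = set(lams) - set(REGIONS)
    if unknown:
        raise InvalidConfigError(f"unknown region labels: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    rows: list[tuple[str, str, str]] = []
    for gene in genes:
        counts = {}
        for r in REGIONS:
            lam = lams.get(r, 0)
            counts[r] = int(lam) if isinstance(lam, (int, np.integer)) else int(
                rng.poisson(float(lam))
            )
        if sum(counts.values()) == 0:
            counts["Body"] = 1
        for region in REGIONS:
            for _ in range(counts[region]):
                rows.append(("", gene, region))
    for _ in range(n_intergenic):
        rows.append(("", NO_GENE, INTERGENIC))
    annot = pd.DataFrame(rows, columns=["probe_id", "gene", "region"])
    annot["probe_id"] = [f"cg{i:08d}" for i in range(1, len(annot) + 1)]
    return annot


def _sample_ids(prefix: str, n_case: int, n_control: int) -> pd.Series:
    ids = [f"{prefix}{i:04d}" for i in range(1, n_case + n_control + 1)]
    groups = ["case"] * n_case + ["control"] * n_control
    return pd.Series(groups, index=pd.Index(ids, name="sample_id"), name="group")


def generate_cohort(config: CohortConfig) -> SyntheticStudy:
    """Generate a full synthetic study from ``config``.

    The probe-level beta baseline is drawn from a two-component Beta mixture
    (an unmethylated and a methylated mode), with the mode weights depending
    on region class: promoter-proximal CpGs (TSS1500/TSS200/5UTR/1stExon)
    favour the low mode, gene-body/3UTR/intergenic CpGs the high mode — the
    familiar bimodal 450K marginal. CpGs carrying a planted shift draw their
    baseline from the mid-range [0.3, 0.6] so the shift is not censored by
    clipping at the unit-interval boundary.

    Each affected gene receives the beta shift in 1-2 randomly chosen regions
    (among regions where it has CpGs); those regions are recorded in
    ``truth.dominant_regions``. Expression effects follow the coupling
    convention (negative: hypo-methylated genes are up-regulated).
    """
    ss = np.random.SeedSequence(config.seed)
    ss_annot, ss_data = ss.spawn(2)
    annot = generate_annotation(
        config.n_genes, config.n_intergenic_cpgs, config.regions_per_gene, seed=ss_annot
    )
    rng = np.random.default_rng(ss_data)

    genes = sorted(annot.loc[annot["region"] != INTERGENIC, "gene"].unique())
    n_hypo = int(round(config.frac_hypo_up * config.n_genes))
    n_hyper = int(round(config.frac_hyper_down * config.n_genes))
    flagged = rng.choice(len(genes), size=n_hypo + n_hyper, replace=False)
    hypo_up = {genes[i] for i in flagged[:n_hypo]}
    hyper_down = {genes[i] for i in flagged[n_hypo:]}

    samples = _sample_ids("E" if config.split_cohorts else "S", config.n_case, config.n_control)
    meth_samples = (
        _sample_ids("M", config.n_case, config.n_control) if config.split_cohorts else samples
    )
    case_mask = (meth_samples == "case").to_numpy()

    # Planted effect sign per gene on the methylation side.
    beta_sign = {g: -1.0 for g in hypo_up}
    beta_sign.update({g: +1.0 for g in hyper_down})
    expr_coupling = -1.0 if config.coupling == "negative" else 1.0
    # negative coupling: hypo (beta_sign −1) pairs with up-regulation (+).
    expr_sign = {g: expr_coupling * s for g, s in beta_sign.items()}

    # Choose the planted region set per affected gene: 1-2 regions with CpGs,
    # sampled with probability proportional to CpG count (CpG-rich regions
    # such as the gene body are the likelier carriers of a real signal).
    planted_regions: dict[str, tuple[str, ...]] = {g: () for g in genes}
    cpg_counts = (
        annot.loc[annot["region"] != INTERGENIC]
        .groupby(["gene", "region"]).size().to_dict()
    )
    regions_by_gene: dict[str, list[str]] = {}
    for gene, region in cpg_counts:
        regions_by_gene.setdefault(gene, []).append(region)
    for gene in sorted(beta_sign):
        avail = sorted(regions_by_gene[gene], key=REGIONS.index)
        k = int(rng.integers(1, 2 + 1)) if len(avail) >= 2 else 1
        weights = np.array([cpg_counts[(gene, r)] for r in avail], dtype=float)
        chosen = rng.choice(len(avail), size=k, replace=False, p=weights / weights.sum())
        planted_regions[gene] = tuple(sorted((avail[i] for i in chosen), key=REGIONS.index))

    # Probe baselines: bimodal mixture, mid-range for planted CpGs.
    n_probes = len(annot)
    promoter_like = annot["region"].isin(("TSS1500", "TSS200", "5UTR", "1stExon")).to_numpy()
    p_high = np.where(promoter_like, 0.2, 0.7)
    high_mode = rng.random(n_probes) < p_high
    baseline = np.where(
        high_mode, rng.beta(10.0, 2.0, size=n_probes), rng.beta(2.0, 10.0, size=n_probes)
    )
    probe_shift = np.zeros(n_probes)
    for i, (gene, region) in enumerate(zip(annot["gene"], annot["region"])):
        if gene in beta_sign and region in planted_regions[gene]:
            probe_shift[i] = beta_sign[gene] * config.delta_beta_effect
    planted_probe = probe_shift != 0.0
    baseline[planted_probe] = rng.uniform(0.3, 0.6, size=int(planted_probe.sum()))

    n_meth_samples = len(meth_samples)
    # Correlated noise: one unit per gene (each intergenic CpG is its own
    # unit) shared by the unit's probes, plus one global offset per sample.
    units = [g if g != NO_GENE else p for g, p in zip(annot["gene"], annot["probe_id"])]
    unit_ids = {u: i for i, u in enumerate(dict.fromkeys(units))}
    unit_noise = rng.normal(0.0, config.beta_gene_sd, size=(len(unit_ids), n_meth_samples))
    subject_offset = rng.normal(0.0, config.beta_subject_sd, size=n_meth_samples)
    beta = (
        baseline[:, None]
        + np.outer(probe_shift, case_mask.astype(float))
        + unit_noise[[unit_ids[u] for u in units], :]
        + subject_offset[None, :]
        + rng.normal(0.0, config.beta_dispersion, size=(n_probes, n_meth_samples))
    )
    np.clip(beta, 0.0, BETA_MAX, out=beta)
    beta_df = pd.DataFrame(beta, index=pd.Index(annot["probe_id"], name="probe_id"),
                           columns=meth_samples.index)

    # Expression: per-gene baseline intensity + planted group shift + noise.
    expr_case_mask = (samples == "case").to_numpy()
    expr_base = rng.normal(7.0, 2.0, size=len(genes))
    expr_shift = np.array([expr_sign.get(g, 0.0) * config.log2fc_effect for g in genes])
    expr = (
        expr_base[:, None]
        + np.outer(expr_shift, expr_case_mask.astype(float))
        + rng.normal(0.0, config.expr_sd, size=(len(genes), len(samples)))
    )
    expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples.index)

    truth = pd.DataFrame(
        {
            "is_hypo_up": [g in hypo_up for g in genes],
            "is_hyper_down": [g in hyper_down for g in genes],
            "log2fc": [expr_sign.get(g, 0.0) * config.log2fc_effect for g in genes],
            "delta_beta": [beta_sign.get(g, 0.0) * config.delta_beta_effect for g in genes],
            "dominant_regions": [planted_regions[g] for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )

    assert float(beta_df.to_numpy().min()) >= 0.0 and float(beta_df.to_numpy().max()) < 1.0
    return SyntheticStudy(
        expression=expr_df,
        beta=beta_df,
        annotation=annot,
        samples=samples,
        meth_samples=meth_samples,
        truth=truth,
        config=config,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write a study to ``outdir`` as TSV/CSV/JSON files; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "beta": outdir / "beta.tsv",
        "annotation": outdir / "annotation.tsv",
        "samples": outdir / "samples.csv",
        "truth": outdir / "truth.json",
    }
    study.expression.to_csv(paths["expression"], sep="\t")
    study.beta.to_csv(paths["beta"], sep="\t")
    study.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    sheet = study.samples.rename_axis("sample_id").reset_index()
    if study.config.split_cohorts:
        sheet = pd.concat(
            [sheet, study.meth_samples.rename_axis("sample_id").reset_index()],
            ignore_index=True,
        )
    sheet.to_csv(paths["samples"], index=False)
    truth = study.truth.copy()
    truth["dominant_regions"] = truth["dominant_regions"].map(list)
    paths["truth"].write_text(json.dumps(truth.reset_index().to_dict(orient="records"), indent=1))
    logger.info("wrote synthetic study to %s", outdir)
    return paths
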