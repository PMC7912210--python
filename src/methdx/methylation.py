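"""Region-aware differential methylation from 450K-style beta values.

The analysis chain mirrors how array methylation is summarised in practice:

1. probe beta values, beta = M / (M + U + a) with the stabilising offset
   a = 100 on the methylated/unmethylated intensities;
2. per-(gene, region) mean beta over member CpGs, for the six gene regions
   TSS1500, TSS200, 5UTR, 1stExon, Body, 3UTR;
3. per-gene mean beta over all CpGs annotated to the gene;
4. differentially methylated genes (DMGs) called on the gene-level
   case-minus-control delta-beta by the pooled decile rule: the 0.1 and 0.9
   empirical quantiles of the combined delta-beta vector of all genes and
   all intergenic CpGs, together with a BH-adjusted two-group p < alpha;
5. dominant regions: the region with the most extreme delta-beta in the
   gene's direction, plus every region within ``tol`` (default 0.005) beta
   units of it.

Delta-beta is case minus control throughout, so hypo-methylation in cases is
negative and pairs with the lower-decile gate.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import InsufficientReplicationError, bh_adjust
from .synthetic import INTERGENIC, REGIONS

logger = logging.getLogger(__name__)

#: Intensity offset stabilising beta for low-intensity probes.
DEFAULT_OFFSET = 100.0

#: Default dominant-region tolerance, in beta units.
DOMINANT_TOL = 0.005


def compute_beta(M, U, a: float = DEFAULT_OFFSET):
    """Beta value from methylated/unmethylated intensities: M / (M + U + a).

    Accepts scalars or arrays; requires M >= 0, U >= 0, a >= 0 and
    M + U + a > 0. The result lies in [0, 1), strictly below 1 whenever
    a > 0 or U > 0.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if np.any(M < 0) or np.any(U < 0):
        raise ValueError("intensities must be non-negative")
    if a < 0:
        raise ValueError("offset a must be non-negative")
    denom = M + U + a
    if np.any(denom <= 0):
        raise ValueError("M + U + a must be positive")
    beta = M / denom
    return beta if beta.ndim else float(beta)


def _genic(annotation: pd.DataFrame) -> pd.DataFrame:
    return annotation[annotation["region"] != INTERGENIC]


def _check_probes(beta: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    present = annotation["probe_id"].isin(beta.index)
    if not present.all():
        logger.warning("skipping %d annotated probes absent from the beta matrix",
                       int((~present).sum()))
    annotation = annotation[present]
    if annotation.empty:
        raise ValueError("annotation shares no probes with the beta matrix")
    return annotation


def aggregate_region_beta(beta: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Mean beta per (gene, region, sample) over member CpGs.

    Intergenic probes are excluded; (gene, region) pairs with no CpGs are
    absent from the result rather than filled with zeros. Returns a frame
    with a (gene, region) MultiIndex, sample columns, and an ``n_cpgs``
    membership count column alongside (as attribute ``.attrs['n_cpgs']``
    a Series on the same index).
    """
    annotation = _check_probes(beta, _genic(annotation))
    if annotation.empty:
        raise ValueError("no genic probes to aggregate")
    joined = annotation.set_index("probe_id").join(beta, how="inner")
    grouped = joined.groupby(["gene", "region"], sort=True)
    means = grouped[list(beta.columns)].mean()
    means.attrs["n_cpgs"] = grouped.size().rename("n_cpgs")
    return means


def aggregate_gene_beta(beta: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Mean beta per gene over ALL CpGs annotated to it, regardless of region.

    A probe annotated to several genes contributes to each of them.
    """
    annotation = _check_probes(beta, _genic(annotation))
    if annotation.empty:
        raise ValueError("no genic probes to aggregate")
    joined = annotation.set_index("probe_id").join(beta, how="inner")
    return joined.groupby("gene", sort=True)[list(beta.columns)].mean()


def _two_group_stats(
    values: pd.DataFrame, labels: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    """Delta (case - control mean) and equal-variance two-group p per row."""
    case_cols = labels.index[labels == "case"].intersection(values.columns)
    ctrl_cols = labels.index[labels == "control"].intersection(values.columns)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise InsufficientReplicationError(
            f"need >=2 samples per group, got case={len(case_cols)}, "
            f"control={len(ctrl_cols)}"
        )
    x1 = values[case_cols].to_numpy(dtype=float)
    x0 = values[ctrl_cols].to_numpy(dtype=float)
    delta = x1.mean(axis=1) - x0.mean(axis=1)
    res = stats.ttest_ind(x1, x0, axis=1, equal_var=True)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return delta, np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def call_dmgs(
    gene_beta: pd.DataFrame,
    intergenic_beta: pd.DataFrame,
    labels: pd.Series | dict,
    alpha: float = 0.05,
    deciles: tuple[float, float] = (0.1, 0.9),
) -> pd.DataFrame:
    """Call differentially methylated genes by the pooled decile rule.

    The hypo/hyper thresholds are the ``deciles`` empirical quantiles
    (linear interpolation between order statistics) of the pooled delta-beta
    vector of all genes AND all intergenic CpGs; a gene is called hypo iff
    its delta-beta lies strictly below the lower threshold and its
    BH-adjusted two-group p-value is below ``alpha``, hyper symmetrically
    above the upper threshold.

    Returns a gene-indexed DataFrame with columns ``delta_beta``,
    ``p_value``, ``adj_p``, ``call`` ({hypo, hyper, none}); the quantile
    thresholds and the intergenic delta-beta Series are attached as
    ``.attrs['thresholds']`` and ``.attrs['intergenic_delta']``.
    """
    labels = pd.Series(labels)
    if gene_beta.empty and intergenic_beta.empty:
        raise ValueError("empty pooled delta-beta vector: no genes or intergenic CpGs")
    delta, p = _two_group_stats(gene_beta, labels)
    if intergenic_beta is not None and len(intergenic_beta):
        ig_delta, _ = _two_group_stats(intergenic_beta, labels)
        ig_series = pd.Series(ig_delta, index=intergenic_beta.index, name="delta_beta")
    else:
        ig_series = pd.Series(dtype=float, name="delta_beta")
    pooled = np.concatenate([delta, ig_series.to_numpy()])
    q_lo, q_hi = np.quantile(pooled, deciles)  # linear interpolation

    adj_p = bh_adjust(p)
    call = np.where(
        (delta < q_lo) & (adj_p < alpha), "hypo",
        np.where((delta > q_hi) & (adj_p < alpha), "hyper", "none"),
    )
    table = pd.DataFrame(
        {"delta_beta": delta, "p_value": p, "adj_p": adj_p, "call": call},
        index=gene_beta.index.rename("gene"),
    )
    table.attrs["thresholds"] = (float(q_lo), float(q_hi))
    table.attrs["intergenic_delta"] = ig_series
    return table


def region_delta_beta(
    region_beta: pd.DataFrame, labels: pd.Series | dict
) -> pd.DataFrame:
    """Case-minus-control delta-beta per (gene, region) from region means."""
    labels = pd.Series(labels)
    delta, p = _two_group_stats(region_beta, labels)
    return pd.DataFrame(
        {"delta_beta": delta, "p_value": p}, index=region_beta.index
    )


def find_dominant_regions(
    region_delta: Mapping[str, Mapping[str, float]] | pd.Series,
    direction: str,
    tol: float = DOMINANT_TOL,
    extreme: str = "directional",
) -> dict[str, tuple[str, ...]]:
    """Dominant region set per gene from per-region delta-beta values.

    The extreme region is the argmin of delta-beta for ``direction='hypo'``
    and the argmax for ``'hyper'`` (with ``extreme='signed-min'``, the argmin
    regardless of direction — the literal "smallest delta beta" reading).
    Every region whose delta-beta differs from the extreme by strictly less
    than ``tol`` joins the set, so a gene can have more than one dominant
    region. Ties in the extreme are broken by the fixed region order
    TSS1500, TSS200, 5UTR, 1stExon, Body, 3UTR.

    ``region_delta`` is a mapping gene -> {region: delta_beta} or an
    equivalent (gene, region)-indexed Series.
    """
    if direction not in ("hypo", "hyper"):
        raise ValueError("direction must be 'hypo' or 'hyper'")
    if extreme not in ("directional", "signed-min"):
        raise ValueError("extreme must be 'directional' or 'signed-min'")
    if isinstance(region_delta, pd.Series):
        region_delta = {
            gene: sub.droplevel(0).to_dict()
            for gene, sub in region_delta.groupby(level=0)
        }
    take_min = extreme == "signed-min" or direction == "hypo"

    result: dict[str, tuple[str, ...]] = {}
    for gene, per_region in region_delta.items():
        if not per_region:
            raise ValueError(f"gene {gene!r} has no regions with a defined delta-beta")
        items = sorted(per_region.items(), key=lambda kv: REGIONS.index(kv[0]))
        values = np.array([v for _, v in items], dtype=float)
        ext = values.min() if take_min else values.max()
        members = tuple(r for (r, v) in items if abs(v - ext) < tol)
        result[gene] = members
    return result
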