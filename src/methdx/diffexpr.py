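"""Two-group differential expression with an empirical-Bayes moderated t.

The model is the standard one for normalized log2 expression matrices: per
gene, the effect is the case-minus-control mean difference (log2 fold-change)
and the pooled within-group variance s^2 (d = n1 + n2 - 2 df) is shrunk
toward an ensemble prior,

    s2_post = (d0 * s0^2 + d * s^2) / (d0 + d),

with the prior degrees of freedom d0 and prior variance s0^2 estimated from
the distribution of all per-gene variances by the log-variance moments
method (digamma/trigamma matching of a scaled-F model). The moderated
t = log2fc / sqrt(s2_post * (1/n1 + 1/n2)) is referred to a t distribution
with d + d0 degrees of freedom. With moderation disabled (d0 = 0) the
statistic reduces exactly to the ordinary equal-variance two-sample t.

Genes are called differentially expressed with a Benjamini-Hochberg adjusted
p-value below ``alpha`` (default 0.05) and |log2FC| strictly above ``lfc``
(default 0.2).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)


class InsufficientReplicationError(ValueError):
    """A group has fewer than two samples."""


class DegenerateVarianceError(ValueError):
    """Every gene has zero within-group variance; no inference is possible."""


def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the asymptotic start x ~ 1/y + 0.5 and the monotone update in 1/x;
    converges in a handful of steps for y in (0, inf).
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def estimate_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Estimate prior df ``d0`` and prior variance ``s0^2`` from per-gene s^2.

    Moments method on z = log s^2: under the scaled-F model, z minus its
    known sampling digamma/log terms has residual variance trigamma(d0/2);
    inverting trigamma yields d0, and the mean yields s0^2. If the observed
    spread does not exceed the sampling spread, d0 is infinite (complete
    shrinkage) and s0^2 is the geometric-mean-based estimate.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise DegenerateVarianceError("all per-gene variances are zero")
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    n = e.size
    evar = np.var(e, ddof=1) - special.polygamma(1, d / 2.0) if n > 1 else 0.0
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(evar)[0])
        s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(e)))
    return d0, s0_2


def fit_moderated_de(
    expression: pd.DataFrame,
    labels: pd.Series | dict,
    moderation: bool = True,
) -> pd.DataFrame:
    """Fit the two-group (case vs control) model to every gene.

    Parameters
    ----------
    expression
        Genes x samples log2 matrix; column names must appear in ``labels``.
    labels
        Sample -> group mapping with groups ``case`` and ``control``.
    moderation
        If False, d0 is forced to 0 and the statistic is the ordinary
        pooled-variance Student t.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``t_stat``,
    ``p_value``, ``adj_p``, ``direction`` (direction uses the default
    thresholds; see :func:`call_degs` for threshold control).
    """
    labels = pd.Series(labels)
    common = [s for s in expression.columns if s in labels.index]
    if len(common) < len(expression.columns):
        logger.warning("dropping %d samples absent from the sample sheet",
                       len(expression.columns) - len(common))
    expression = expression[common]
    groups = labels.loc[common]
    case_cols = groups.index[groups == "case"]
    ctrl_cols = groups.index[groups == "control"]
    n1, n0 = len(case_cols), len(ctrl_cols)
    if n1 < 2 or n0 < 2:
        raise InsufficientReplicationError(
            f"need >=2 samples per group, got case={n1}, control={n0}"
        )

    if expression.isna().any(axis=None):
        bad = expression.index[expression.isna().any(axis=1)]
        logger.warning("dropping %d genes with missing values", len(bad))
        expression = expression.drop(index=bad)

    x1 = expression[case_cols].to_numpy(dtype=float)
    x0 = expression[ctrl_cols].to_numpy(dtype=float)
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    log2fc = m1 - m0
    d = float(n1 + n0 - 2)
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x0.var(axis=1, ddof=1) * (n0 - 1)
    s2 = ss / d
    if np.all(s2 == 0):
        raise DegenerateVarianceError("all genes have zero within-group variance")

    if moderation:
        d0, s0_2 = estimate_variance_prior(s2, d)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
            df_total = d + d0
    else:
        s2_post = s2
        df_total = d

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, log2fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_stat), df=df_total)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)

    table = pd.DataFrame(
        {"log2fc": log2fc, "t_stat": t_stat, "p_value": p},
        index=expression.index.rename("gene"),
    )
    table["adj_p"] = bh_adjust(table["p_value"].to_numpy())
    up, down = call_degs(table)
    table["direction"] = "none"
    table.loc[sorted(up), "direction"] = "up"
    table.loc[sorted(down), "direction"] = "down"
    return table


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    adj_p(i) = min over j with p(j) >= p(i) of p(j) * n / rank(j), clipped
    at 1; equivalently p sorted ascending, scaled by n/rank, cumulative
    minimum from the largest down.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def call_degs(
    table: pd.DataFrame, alpha: float = 0.05, lfc: float = 0.2
) -> tuple[set[str], set[str]]:
    """Split a DE table into up- and down-regulated gene sets.

    Strict inequalities on both gates: adj_p < ``alpha`` and
    log2fc > ``lfc`` (up) or log2fc < -``lfc`` (down).
    """
    sig = table["adj_p"] < alpha
    up = set(table.index[sig & (table["log2fc"] > lfc)])
    down = set(table.index[sig & (table["log2fc"] < -lfc)])
    return up, down
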