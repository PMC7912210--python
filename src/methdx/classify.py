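"""Random-forest signature classifiers with incremental feature selection.

Three feature views are supported for a given gene signature: the log2
expression matrix, the gene-level mean beta over all regions, and the mean
beta over each gene's dominant region set only. For each view the procedure
is:

1. rank genes by random-forest importance (mean decrease in impurity by
   default, permutation importance optionally) computed once on the full
   data set;
2. add genes one-by-one in importance order; for every prefix size k,
   estimate out-of-sample performance by leave-one-out cross-validation
   (n models, each sample scored by a forest never trained on it) and the
   rank-based AUC of the resulting case-probabilities;
3. report the AUC-versus-k curve, the best k (largest AUC, smallest k on
   ties), and the final AUC with a rank-sum p-value against AUC = 0.5.

Ranking on the full data before cross-validation replicates the published
protocol and is optimistically biased; ``nested=True`` re-ranks inside every
leave-one-out fold for an unbiased estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

logger = logging.getLogger(__name__)

VIEW_KINDS = ("expression", "beta_all_regions", "beta_dominant_regions")

#: Forest size; split candidates default to sqrt(G) inside sklearn.
DEFAULT_N_TREES = 500


@dataclass
class FeatureView:
    """A genes x samples feature matrix of one kind, with no missing entries."""

    kind: str
    matrix: pd.DataFrame  # genes x samples

    def __post_init__(self) -> None:
        if self.kind not in VIEW_KINDS:
            raise ValueError(f"kind must be one of {VIEW_KINDS}")
        if self.matrix.isna().any(axis=None):
            bad = self.matrix.index[self.matrix.isna().any(axis=1)]
            logger.warning("%s view: dropping %d genes with missing values",
                           self.kind, len(bad))
            self.matrix = self.matrix.drop(index=bad)
        if self.kind != "expression":
            vals = self.matrix.to_numpy()
            if vals.size and (vals.min() < 0 or vals.max() >= 1):
                raise ValueError("beta views must have values in [0, 1)")

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    def subset(self, genes) -> "FeatureView":
        return FeatureView(self.kind, self.matrix.loc[list(genes)])


@dataclass
class ClassifierReport:
    """Importance ranking, AUC-by-k curve and final LOO evaluation."""

    kind: str
    ranked: pd.DataFrame  # index gene, columns raw_importance, scaled_importance
    auc_by_k: dict[int, float]
    best_k: int
    loo_scores: pd.Series  # sample -> out-of-fold case-probability at best_k
    auc: float
    auc_p: float


def _as_xy(view: FeatureView, labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    labels = pd.Series(labels)
    cols = [c for c in view.matrix.columns if c in labels.index]
    X = view.matrix[cols].to_numpy(dtype=float).T  # samples x genes
    y = (labels.loc[cols] == "case").to_numpy(dtype=int)
    return X, y


def _forest(seed: int, n_trees: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )


def rank_importance(
    view: FeatureView,
    labels: pd.Series | dict,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    method: str = "mdi",
    n_repeats: int = 1,
) -> pd.Series:
    """Rank genes by random-forest importance, descending.

    ``method='mdi'`` (default) uses mean decrease in impurity;
    ``'permutation'`` uses permutation importance (``n_repeats`` shuffles per
    feature inside sklearn). With ``n_repeats > 1`` under MDI, importance is
    averaged over that many independently seeded forests. Deterministic for
    a fixed seed; ties broken by gene symbol.
    """
    labels = pd.Series(labels)
    X, y = _as_xy(view, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if method not in ("mdi", "permutation"):
        raise ValueError("method must be 'mdi' or 'permutation'")
    if method == "mdi":
        imps = np.zeros(X.shape[1])
        for r in range(max(1, n_repeats)):
            imps += _forest(seed + r, n_trees).fit(X, y).feature_importances_
        raw = imps / max(1, n_repeats)
    else:
        forest = _forest(seed, n_trees).fit(X, y)
        raw = permutation_importance(
            forest, X, y, n_repeats=max(5, n_repeats), random_state=seed
        ).importances_mean
    series = pd.Series(raw, index=view.matrix.index, name="raw_importance")
    # Sort by importance descending, gene symbol ascending on ties.
    order = sorted(series.index, key=lambda g: (-series[g], str(g)))
    return series.loc[order]


def scale_importance(raw: np.ndarray | pd.Series | list[float]):
    """Min-max scale importances to [0, 100]: top feature 100.00, bottom 0.00.

    An all-equal input (including a singleton) maps to all zeros with a
    warning, since the range is degenerate.
    """
    values = np.asarray(pd.Series(raw).to_numpy(), dtype=float)
    if values.size == 0:
        raise ValueError("empty importance vector")
    lo, hi = values.min(), values.max()
    if hi == lo:
        warnings.warn("all importances equal; scaled importances set to 0")
        scaled = np.zeros_like(values)
    else:
        scaled = 100.0 * (values - lo) / (hi - lo)
    if isinstance(raw, pd.Series):
        return pd.Series(scaled, index=raw.index, name="scaled_importance")
    return scaled


def loo_scores(
    view: FeatureView,
    labels: pd.Series | dict,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> pd.Series:
    """Out-of-fold case-probability per sample under leave-one-out CV.

    Trains n forests; the i-th is fit on all samples but the i-th and scores
    only that held-out sample.
    """
    labels = pd.Series(labels)
    X, y = _as_xy(view, labels)
    cols = [c for c in view.matrix.columns if c in labels.index]
    n = len(cols)
    if n < 3:
        raise ValueError(f"leave-one-out needs >=3 samples, got {n}")
    scores = np.empty(n)
    for i in range(n):
        train = np.arange(n) != i
        y_train = y[train]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"fold {i}: training set has a single class")
        forest = _forest(seed, n_trees).fit(X[train], y_train)
        case_col = int(np.where(forest.classes_ == 1)[0][0])
        scores[i] = forest.predict_proba(X[i : i + 1])[0, case_col]
    return pd.Series(scores, index=pd.Index(cols, name="sample_id"), name="loo_score")


def roc_auc(scores: pd.Series | dict, labels: pd.Series | dict) -> tuple[float, float]:
    """Rank-based AUC and its rank-sum p-value against no discrimination.

    AUC = U / (n_case * n_control) with ties counted one half — the
    probability a random case scores above a random control. The p-value is
    the two-sided normal-approximated (tie-corrected) Mann-Whitney test of
    the score distributions.
    """
    scores = pd.Series(scores)
    labels = pd.Series(labels).loc[scores.index]
    case = scores[labels == "case"].to_numpy(dtype=float)
    ctrl = scores[labels == "control"].to_numpy(dtype=float)
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError("both classes must be present")
    res = stats.mannwhitneyu(case, ctrl, alternative="two-sided", method="asymptotic")
    auc = float(res.statistic) / (len(case) * len(ctrl))
    return auc, float(res.pvalue)


def incremental_selection(
    view: FeatureView,
    ranked_genes: list[str],
    labels: pd.Series | dict,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    nested: bool = False,
    raw_importance: pd.Series | None = None,
) -> ClassifierReport:
    """Evaluate top-k prefixes of the ranking under LOO; pick the best k.

    For k = 1..G the top-k genes (by the supplied ranking) form the feature
    set; the LOO AUC is recorded and best_k is the argmax, smallest k on
    ties. ``nested=True`` re-ranks features within every training fold
    before scoring the held-out sample, removing the selection bias of
    ranking on the full data.
    """
    labels = pd.Series(labels)
    ranked_genes = list(ranked_genes)
    if not ranked_genes:
        raise ValueError("empty ranking")
    G = len(ranked_genes)
    auc_by_k: dict[int, float] = {}
    scores_by_k: dict[int, pd.Series] = {}
    for k in range(1, G + 1):
        if nested:
            scores = _nested_loo_scores(view, labels, k, seed, n_trees)
        else:
            scores = loo_scores(view.subset(ranked_genes[:k]), labels, seed, n_trees)
        auc_by_k[k] = roc_auc(scores, labels)[0]
        scores_by_k[k] = scores
    best_k = max(auc_by_k, key=lambda k: (auc_by_k[k], -k))
    best_scores = scores_by_k[best_k]
    auc, auc_p = roc_auc(best_scores, labels)

    if raw_importance is None:
        raw_importance = pd.Series(
            np.linspace(1.0, 0.0, G), index=ranked_genes, name="raw_importance"
        )
    ranked = raw_importance.loc[ranked_genes].to_frame("raw_importance")
    ranked["scaled_importance"] = scale_importance(ranked["raw_importance"])
    return ClassifierReport(
        kind=view.kind,
        ranked=ranked,
        auc_by_k=auc_by_k,
        best_k=best_k,
        loo_scores=best_scores,
        auc=auc,
        auc_p=auc_p,
    )


def _nested_loo_scores(
    view: FeatureView, labels: pd.Series, k: int, seed: int, n_trees: int
) -> pd.Series:
    """LOO scores where the top-k ranking is recomputed inside each fold."""
    cols = [c for c in view.matrix.columns if c in labels.index]
    scores = {}
    for i, held_out in enumerate(cols):
        train_cols = [c for c in cols if c != held_out]
        train_view = FeatureView(view.kind, view.matrix[train_cols])
        ranking = rank_importance(train_view, labels.loc[train_cols], seed, n_trees)
        top_k = list(ranking.index[:k])
        X_train = view.matrix.loc[top_k, train_cols].to_numpy(dtype=float).T
        y_train = (labels.loc[train_cols] == "case").to_numpy(dtype=int)
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"fold {i}: training set has a single class")
        forest = _forest(seed, n_trees).fit(X_train, y_train)
        case_col = int(np.where(forest.classes_ == 1)[0][0])
        x_test = view.matrix.loc[top_k, [held_out]].to_numpy(dtype=float).T
        scores[held_out] = forest.predict_proba(x_test)[0, case_col]
    return pd.Series(scores, name="loo_score").rename_axis("sample_id")


def build_views(
    expression: pd.DataFrame,
    gene_beta: pd.DataFrame,
    region_beta: pd.DataFrame,
    dominant: dict[str, tuple[str, ...]],
    genes: list[str],
) -> dict[str, FeatureView]:
    """Assemble the three feature views for a gene signature.

    ``region_beta`` is the (gene, region) x sample mean-beta frame; the
    dominant view averages each gene's dominant regions (weighting each
    region equally). Genes absent from a matrix — or lacking dominant-region
    records — are dropped from that view with a warning.
    """
    views: dict[str, FeatureView] = {}

    expr_genes = [g for g in genes if g in expression.index]
    _warn_missing("expression", genes, expr_genes)
    views["expression"] = FeatureView("expression", expression.loc[expr_genes])

    beta_genes = [g for g in genes if g in gene_beta.index]
    _warn_missing("beta_all_regions", genes, beta_genes)
    views["beta_all_regions"] = FeatureView("beta_all_regions", gene_beta.loc[beta_genes])

    rows = {}
    for g in genes:
        regions = dominant.get(g, ())
        keys = [(g, r) for r in regions if (g, r) in region_beta.index]
        if keys:
            rows[g] = region_beta.loc[keys].mean(axis=0)
    _warn_missing("beta_dominant_regions", genes, list(rows))
    dom = pd.DataFrame(rows).T.rename_axis("gene") if rows else pd.DataFrame(
        index=pd.Index([], name="gene"), columns=region_beta.columns
    )
    views["beta_dominant_regions"] = FeatureView("beta_dominant_regions", dom)
    return views


def _warn_missing(kind: str, wanted: list[str], got: list[str]) -> None:
    missing = set(wanted) - set(got)
    if missing:
        logger.warning("%s view: %d of %d signature genes unavailable, dropped",
                       kind, len(missing), len(wanted))
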