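"""Age/tissue-associated gene screening and ANOVA F-score ranking.

The F-score for a gene across c label groups is the classic one-way ANOVA
statistic written out explicitly:

    MSB = sum_j n_j (xbar_j - xbarbar)^2 / (c - 1)
    MSE = SSE / (n - c),   SSE = sum_j sum_i (x_ij - xbar_j)^2
    F   = MSB / MSE

Genes are ranked descending by F (rank 1 = largest F), ties broken by
ascending gene id.  MSE == 0 with MSB > 0 yields F = +inf (the gene
perfectly separates the groups and outranks every finite F); a constant
gene yields F = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .damage import FeatureMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# core F computation (genes in columns of X)

def f_scores_array(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way ANOVA F per column of X (samples × features)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    c = len(groups)
    n = X.shape[0]
    if c < 2:
        raise ValueError("need at least 2 groups for an F-score")
    if n <= c:
        raise ValueError("need more samples than groups (n > c)")
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    sse = np.zeros(X.shape[1])
    for g in groups:
        sub = X[labels == g]
        mean_g = sub.mean(axis=0)
        ssb += len(sub) * (mean_g - grand) ** 2
        sse += ((sub - mean_g) ** 2).sum(axis=0)
    msb = ssb / (c - 1)
    mse = sse / (n - c)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / mse
    # MSE == 0: either perfect group separation (F = +inf, outranks all finite
    # F) or a constant gene (F = 0).  Group means of a constant gene can carry
    # float fuzz relative to the grand mean, so "constant" is judged against a
    # scale-relative tolerance, not exact zero.
    scale = np.abs(X).max(axis=0, initial=0.0)
    ssb_tol = n * (1e-9 * scale) ** 2
    f[mse == 0] = np.inf
    f[(mse == 0) & (ssb <= ssb_tol)] = 0.0
    return f


@dataclass
class GeneRanking:
    """Per-gene F-scores and deterministic ranks for one target label."""

    target: str  # "age" | "tissue"
    metric: str
    table: pd.DataFrame  # index gene_id; columns F, rank

    @property
    def ranked_genes(self) -> list[str]:
        return list(self.table.sort_values("rank").index)


def _rank_by_f(f: pd.Series) -> pd.Series:
    """Rank 1 = largest F; ties broken by ascending gene_id."""
    order = sorted(f.index, key=lambda gid: (-f[gid], gid))
    return pd.Series(np.arange(1, len(order) + 1), index=order, name="rank").reindex(f.index)


def anova_f_scores(
    matrix: FeatureMatrix | pd.DataFrame, labels: Sequence, target: str = "age"
) -> GeneRanking:
    """Rank genes by the one-way ANOVA F-score against a categorical label.

    ``labels`` align with the matrix's sample columns.  Age groups are treated
    as categorical here even though they are numeric months.
    """
    values = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    metric = matrix.metric if isinstance(matrix, FeatureMatrix) else "unknown"
    labels = np.asarray(list(labels))
    if len(labels) != values.shape[1]:
        raise ValueError("labels must align with matrix samples")
    f = f_scores_array(values.to_numpy().T, labels)
    fs = pd.Series(f, index=values.index, name="F")
    table = pd.DataFrame({"F": fs, "rank": _rank_by_f(fs)})
    return GeneRanking(target=target, metric=metric, table=table)


class AnovaFScoreSelector(SelectorMixin, BaseEstimator):
    """Select the top-k features by one-way ANOVA F-score.

    sklearn-compatible transformer: ``fit(X, y)`` computes per-feature
    F-scores against categorical ``y``; ``transform(X)`` keeps the ``k``
    features with the largest F (ties broken by ascending feature index,
    matching the gene-id tie rule when columns are sorted by gene id).

    Attributes
    ----------
    f_scores_ : ndarray of shape (n_features,)
    ranks_ : ndarray of shape (n_features,), 1 = largest F
    """

    def __init__(self, k: int = 500):
        self.k = k

    def fit(self, X, y):
        X = validate_data(self, X, ensure_2d=True, dtype=float)
        y = np.asarray(y)
        if self.k < 1 or self.k > X.shape[1]:
            raise ValueError(f"k={self.k} out of range for {X.shape[1]} features")
        self.f_scores_ = f_scores_array(X, y)
        order = np.lexsort((np.arange(len(self.f_scores_)), -self.f_scores_))
        ranks = np.empty(len(order), dtype=int)
        ranks[order] = np.arange(1, len(order) + 1)
        self.ranks_ = ranks
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.ranks_ <= self.k


# ---------------------------------------------------------------------------
# Spearman screens

def _spearman_vs_covariate(values: pd.DataFrame, covariate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized mid-rank Spearman rho and two-sided t-approximation p-values
    of every matrix row against one covariate."""
    n = values.shape[1]
    ranks = values.rank(axis=1).to_numpy()
    cov_rank = pd.Series(covariate).rank().to_numpy()
    rx = ranks - ranks.mean(axis=1, keepdims=True)
    ry = cov_rank - cov_rank.mean()
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx @ ry) / denom
    rho = np.where(denom == 0, np.nan, rho)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(rho), 1.0, np.where(np.abs(rho) == 1.0, 0.0, p))
    return rho, p


@dataclass
class CorrelationScreen:
    """Per-gene Spearman correlation of a metric with age."""

    alpha: float
    table: pd.DataFrame  # index gene_id; columns rho, p, sign
    per_tissue_rho: pd.DataFrame | None = None  # genes × tissues

    @property
    def significant_fraction(self) -> float:
        return float((self.table["sign"] != "none").mean())

    @property
    def range(self) -> pd.Series:
        if self.per_tissue_rho is None:
            raise ValueError("per-tissue correlations were not computed")
        return self.per_tissue_rho.max(axis=1) - self.per_tissue_rho.min(axis=1)


def spearman_age_screen(
    matrix: FeatureMatrix | pd.DataFrame, metadata: pd.DataFrame, alpha: float = 0.05
) -> CorrelationScreen:
    """Screen genes for monotone association with age (numeric months).

    Two-sided mid-rank Spearman per gene; a gene is flagged positive/negative
    when p < alpha, and ``none`` otherwise.  Constant genes get sign ``none``
    and p = 1.
    """
    values = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    age = metadata.loc[values.columns, "age_months"].to_numpy(dtype=float)
    if len(np.unique(age)) < 3:
        raise ValueError("need at least 3 distinct age values for the screen")
    rho, p = _spearman_vs_covariate(values, age)
    sign = np.where(np.isnan(rho) | (p >= alpha), "none", np.where(rho > 0, "positive", "negative"))
    table = pd.DataFrame({"rho": rho, "p": p, "sign": sign}, index=values.index)
    return CorrelationScreen(alpha=alpha, table=table)


def per_tissue_correlation_range(
    matrix: FeatureMatrix | pd.DataFrame, metadata: pd.DataFrame
) -> pd.Series:
    """max - min across tissues of per-tissue Spearman correlation with age.

    Genes constant within a tissue contribute rho = 0 for that tissue, which
    keeps the range comparable across metrics.
    """
    values = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    meta = metadata.loc[values.columns]
    tissues = sorted(meta["tissue"].unique())
    if len(tissues) == 1:
        logger.warning("single tissue in metadata; correlation range is 0 for all genes")
        return pd.Series(0.0, index=values.index, name="range")
    per_tissue = {}
    for tissue in tissues:
        cols = meta.index[meta["tissue"] == tissue]
        age = meta.loc[cols, "age_months"].to_numpy(dtype=float)
        if len(cols) < 3 or len(np.unique(age)) < 2:
            raise ValueError(f"tissue {tissue!r} needs >= 3 samples with >= 2 distinct ages")
        rho, _ = _spearman_vs_covariate(values[cols], age)
        n_const = int(np.isnan(rho).sum())
        if n_const:
            logger.info("tissue %s: %d constant genes set to rho=0", tissue, n_const)
        per_tissue[tissue] = np.nan_to_num(rho, nan=0.0)
    per_tissue_rho = pd.DataFrame(per_tissue, index=values.index)
    rng = per_tissue_rho.max(axis=1) - per_tissue_rho.min(axis=1)
    rng.name = "range"
    return rng


def compare_ranges(ranges: Mapping[str, Sequence[float]]) -> dict:
    """One-way ANOVA across metrics' correlation-range vectors plus Tukey HSD.

    Returns ``{"anova_p": p, "tukey": {(a, b): adjusted_p}}``.  Fully
    degenerate input (no variance anywhere, equal means) yields p = 1.
    """
    names = list(ranges.keys())
    groups = [np.asarray(ranges[name], dtype=float) for name in names]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    means = [g.mean() for g in groups]
    if all(g.var() == 0 for g in groups) and len(set(means)) == 1:
        anova_p = 1.0
        tukey_p = np.ones((len(groups), len(groups)))
    else:
        f, anova_p = stats.f_oneway(*groups)
        anova_p = 1.0 if np.isnan(anova_p) else float(anova_p)
        res = stats.tukey_hsd(*groups)
        tukey_p = np.nan_to_num(res.pvalue, nan=1.0)
    tukey = {}
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                tukey[(a, b)] = float(tukey_p[i, j])
    return {"anova_p": float(anova_p), "tukey": tukey}


# ---------------------------------------------------------------------------
# gene sets and overlaps

DEFAULT_GENE_SET_SIZES = (15, 25, 50, 75, 100, 150, 200, 300, 400, 500)


def top_k_gene_sets(
    ranking: GeneRanking, sizes: Sequence[int] = DEFAULT_GENE_SET_SIZES
) -> dict[int, list[str]]:
    """Nested top-k gene sets from a ranking (set(k1) ⊂ set(k2) for k1 < k2)."""
    sizes = list(sizes)
    if sizes != sorted(sizes):
        raise ValueError("sizes must be ascending")
    genes = ranking.ranked_genes
    if sizes[-1] > len(genes):
        raise ValueError(f"requested top-{sizes[-1]} but only {len(genes)} genes ranked")
    return {k: genes[:k] for k in sizes}


def overlap_test(set_a: Sequence[str], set_b: Sequence[str], universe_size: int) -> tuple[int, float]:
    """Hypergeometric upper-tail test of the overlap of two gene sets.

    p = P(X >= |A ∩ B|) with |A| draws from a universe containing |B| marked
    genes.
    """
    a, b = set(set_a), set(set_b)
    if max(len(a), len(b)) > universe_size:
        raise ValueError("sets larger than the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(b), len(a)))
    return k, min(p, 1.0)
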