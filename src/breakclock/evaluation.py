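"""Repeated random-split evaluation of age and tissue prediction models.

Ten model families (six classifiers, four regression-style models wrapped by
a nearest-class adapter) are trained on genes × samples feature matrices
restricted to a gene set, over repeated seeded 80/20 splits.  Each held-out
fold is scored with one-vs-rest macro AUC, macro F1, MAE and Spearman
correlation on encoded labels.

Feature selection can run on all samples before splitting (``full_data``,
mirroring a select-then-split protocol) or inside each training split
(``within_train``, the leakage-free alternative); the difference between the
two on null data is itself a tested property.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import ElasticNet, Lasso, LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted, validate_data

from .damage import FeatureMatrix
from .selection import GeneRanking, anova_f_scores, f_scores_array

logger = logging.getLogger(__name__)

METHOD_IDS = (
    "logreg", "rf", "gnb", "hist_gbm", "reg_gbm",
    "adaboost", "lasso", "enet", "dtree_reg", "dtree_clf",
)

#: families whose native output is a continuous prediction
REGRESSION_METHODS = frozenset({"lasso", "enet", "dtree_reg"})


class RegressionClassAdapter(ClassifierMixin, BaseEstimator):
    """Turn a regressor into a classifier over ordered numeric class values.

    The regressor is fit on the numeric class values; a prediction is scored
    against each class as ``-|prediction - value_k|`` and the row is
    softmax-normalized.  The predicted class is the nearest class value, ties
    going to the lower class.
    """

    def __init__(self, estimator=None):
        self.estimator = estimator

    def fit(self, X, y):
        X = validate_data(self, X, ensure_2d=True, dtype=float)
        y = np.asarray(y, dtype=float)
        self.classes_ = np.unique(y)
        self.estimator_ = clone(self.estimator) if self.estimator is not None else Lasso()
        self.estimator_.fit(X, y)
        return self

    def decision_scores(self, X) -> np.ndarray:
        check_is_fitted(self)
        pred = np.asarray(self.estimator_.predict(X), dtype=float)
        return regression_adapter(pred, self.classes_)

    def predict_proba(self, X) -> np.ndarray:
        return self.decision_scores(X)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_scores(X)
        return self.classes_[np.argmax(scores, axis=1)]


def regression_adapter(predictions: np.ndarray, class_values: np.ndarray) -> np.ndarray:
    """Per-class score matrix from continuous predictions.

    score(sample, k) = -|prediction - class_value_k|, row-softmaxed.  With
    argmax tie-breaking on the first maximum, an equidistant prediction is
    assigned the lower class.
    """
    class_values = np.asarray(class_values, dtype=float)
    if not np.all(np.diff(class_values) > 0):
        raise ValueError("class_values must be sorted ascending and distinct")
    raw = -np.abs(predictions[:, None] - class_values[None, :])
    shifted = raw - raw.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    return expd / expd.sum(axis=1, keepdims=True)


class FlooredGaussianNB(GaussianNB):
    """GaussianNB with an absolute per-feature variance floor.

    Constant features inside a training split would otherwise produce zero
    variance (and NaN likelihoods when every feature is constant, since the
    stock smoothing is relative to the largest feature variance).
    """

    def __init__(self, var_floor: float = 1e-9, **kwargs):
        super().__init__(**kwargs)
        self.var_floor = var_floor

    def fit(self, X, y, sample_weight=None):
        super().fit(X, y, sample_weight=sample_weight)
        n_floored = int((self.var_ < self.var_floor).sum())
        if n_floored:
            logger.debug("GaussianNB: floored %d zero-variance entries", n_floored)
        self.var_ = np.maximum(self.var_, self.var_floor)
        return self


def make_estimator(method_id: str, seed: int):
    """Instantiate one of the ten model families with library defaults.

    Only the random seed is set (plus bounded iteration counts where the
    library default does not converge on unscaled features); no
    hyperparameter tuning.
    """
    if method_id == "logreg":
        return LogisticRegression(max_iter=5000, random_state=seed)
    if method_id == "rf":
        return RandomForestClassifier(random_state=seed)
    if method_id == "gnb":
        return FlooredGaussianNB()
    if method_id == "hist_gbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, verbose=-1)
    if method_id == "reg_gbm":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed, verbosity=0)
    if method_id == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if method_id == "lasso":
        return RegressionClassAdapter(Lasso(random_state=seed))
    if method_id == "enet":
        return RegressionClassAdapter(ElasticNet(random_state=seed))
    if method_id == "dtree_reg":
        return RegressionClassAdapter(DecisionTreeRegressor(random_state=seed))
    if method_id == "dtree_clf":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown method_id {method_id!r}; choose from {METHOD_IDS}")


# ---------------------------------------------------------------------------
# configuration and results

@dataclass(frozen=True)
class EvalConfig:
    method_id: str = "logreg"
    target: str = "age"  # "age" | "tissue"
    train_fraction: float = 0.8
    n_iterations: int = 100
    seed: int = 0
    label_encoding: str = "class_index"  # "class_index" | "months"
    split_mode: str = "stratified"  # "stratified" | "plain"
    selection_mode: str = "full_data"  # "full_data" | "within_train"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.method_id not in METHOD_IDS:
            raise ValueError(f"unknown method_id {self.method_id!r}")
        if self.target not in {"age", "tissue"}:
            raise ValueError("target must be 'age' or 'tissue'")
        if self.label_encoding not in {"class_index", "months"}:
            raise ValueError("label_encoding must be 'class_index' or 'months'")
        if self.target == "tissue" and self.label_encoding == "months":
            raise ValueError("months encoding only applies to the age target")
        if self.split_mode not in {"stratified", "plain"}:
            raise ValueError("split_mode must be 'stratified' or 'plain'")
        if self.selection_mode not in {"full_data", "within_train"}:
            raise ValueError("selection_mode must be 'full_data' or 'within_train'")


@dataclass
class EvalResult:
    """Per-iteration and aggregate scores for one (metric, gene set, method)."""

    metric: str
    region_mode: str
    method_id: str
    gene_set_size: int
    seed: int
    per_iteration: pd.DataFrame  # columns: auc, f1, mae, spearman

    @property
    def aggregates(self) -> dict[str, float]:
        return {k: float(self.per_iteration[k].mean()) for k in ("auc", "f1", "mae", "spearman")}

    @property
    def mean_auc(self) -> float:
        return self.aggregates["auc"]


# ---------------------------------------------------------------------------
# metrics

def compute_classification_metrics(
    true_labels: np.ndarray,
    class_scores: np.ndarray,
    label_values: np.ndarray,
    label_encoding: str = "class_index",
) -> dict[str, float]:
    """AUC / F1 / MAE / Spearman from a per-class score matrix.

    AUC is one-vs-rest, macro-averaged over classes present in the truth with
    at least one negative (others are skipped and logged).  Predictions are
    the argmax class (first maximum on ties).  MAE and Spearman are computed
    on encoded labels: class index 0..K-1 by default, or the raw numeric
    values (months) when requested.
    """
    label_values = np.asarray(label_values)
    true_labels = np.asarray(true_labels)
    class_scores = np.asarray(class_scores, dtype=float)
    if class_scores.shape != (len(true_labels), len(label_values)):
        raise ValueError("class_scores must be samples × classes aligned with label_values")
    pred_idx = np.argmax(class_scores, axis=1)
    true_idx = np.searchsorted(label_values, true_labels)
    if not np.array_equal(label_values[true_idx], true_labels):
        raise ValueError("true_labels contain values outside label_values")

    aucs = []
    for k in range(len(label_values)):
        is_k = true_idx == k
        if is_k.all() or not is_k.any():
            logger.debug("class %r absent from truth or has no negatives; skipped in macro AUC",
                         label_values[k])
            continue
        aucs.append(roc_auc_score(is_k, class_scores[:, k]))
    auc = float(np.mean(aucs)) if aucs else float("nan")

    present = np.unique(true_idx)
    f1 = float(f1_score(true_idx, pred_idx, labels=present, average="macro", zero_division=0))

    if label_encoding == "months":
        enc_true = label_values[true_idx].astype(float)
        enc_pred = label_values[pred_idx].astype(float)
    else:
        enc_true, enc_pred = true_idx.astype(float), pred_idx.astype(float)
    mae = float(np.abs(enc_pred - enc_true).mean())
    if np.ptp(enc_pred) == 0 or np.ptp(enc_true) == 0:
        spearman = 0.0  # constant vector: correlation undefined, scored as no association
    else:
        spearman = float(stats.spearmanr(enc_pred, enc_true).statistic)
    return {"auc": auc, "f1": f1, "mae": mae, "spearman": spearman}


def _class_scores(model, X: np.ndarray, n_classes: int, class_index: np.ndarray) -> np.ndarray:
    """Samples × n_classes score matrix, zero-filled for classes unseen in training."""
    proba = model.predict_proba(X)
    full = np.zeros((X.shape[0], n_classes))
    seen = np.asarray(model.classes_, dtype=int)
    full[:, class_index[seen]] = proba
    return full


# ---------------------------------------------------------------------------
# the harness

def _encode_target(metadata: pd.DataFrame, sample_ids: Sequence[str], config: EvalConfig):
    """Class values (sorted ascending) and per-sample class indices."""
    meta = metadata.loc[list(sample_ids)]
    if config.target == "age":
        raw = meta["age_months"].to_numpy(dtype=float)
    else:
        raw = meta["tissue"].to_numpy()
    label_values = np.unique(raw)
    y_idx = np.searchsorted(label_values, raw)
    return label_values, y_idx


def _adapter_targets(label_values: np.ndarray, y_idx: np.ndarray, config: EvalConfig):
    """Numeric regression targets/class values under the configured encoding."""
    if config.label_encoding == "months" and config.target == "age":
        return label_values.astype(float), label_values[y_idx].astype(float)
    idx_values = np.arange(len(label_values), dtype=float)
    return idx_values, y_idx.astype(float)


def run_evaluation(
    matrix: FeatureMatrix,
    metadata: pd.DataFrame,
    gene_set: Sequence[str],
    config: EvalConfig,
) -> EvalResult:
    """Repeated random-split evaluation of one model family on one gene set.

    Each iteration draws a fresh seeded train/test split, fits the model on
    the training samples restricted to ``gene_set`` (or, under
    ``within_train`` selection, to the top-|gene_set| genes ranked inside the
    training split), and scores the held-out samples.  Deterministic given
    (seed, config, inputs).
    """
    gene_set = list(gene_set)
    missing = set(gene_set) - set(matrix.gene_ids)
    if missing:
        raise ValueError(f"gene_set contains genes absent from the matrix: {sorted(missing)[:5]}")
    sample_ids = matrix.sample_ids
    label_values, y_idx = _encode_target(metadata, sample_ids, config)
    counts = np.bincount(y_idx)
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 samples")
    X_all = matrix.values.T.to_numpy(dtype=float)  # samples × genes
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    sel_cols = np.array([gene_index[g] for g in gene_set])
    idx_class_values, _ = _adapter_targets(label_values, y_idx, config)

    ss = np.random.SeedSequence(config.seed)
    iter_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_iterations)]

    rows = []
    for it, it_seed in enumerate(iter_seeds):
        train_idx, test_idx = _draw_split(y_idx, config, it_seed)
        if config.selection_mode == "within_train":
            f = f_scores_array(X_all[train_idx], y_idx[train_idx])
            order = np.lexsort((np.arange(len(f)), -f))
            cols = np.sort(order[: len(gene_set)])
        else:
            cols = sel_cols
        X_train, X_test = X_all[np.ix_(train_idx, cols)], X_all[np.ix_(test_idx, cols)]
        model = make_estimator(config.method_id, it_seed)
        if config.method_id in REGRESSION_METHODS:
            _, y_numeric = _adapter_targets(label_values, y_idx, config)
            model.fit(X_train, y_numeric[train_idx])
            # adapter classes_ reflect training classes; rebuild scores on the full set
            pred = model.estimator_.predict(X_test)
            scores = regression_adapter(np.asarray(pred, dtype=float), idx_class_values)
        else:
            model.fit(X_train, y_idx[train_idx])
            scores = _class_scores(model, X_test, len(label_values), np.arange(len(label_values)))
        m = compute_classification_metrics(
            label_values[y_idx[test_idx]], scores, label_values, config.label_encoding
        )
        rows.append(m)
    per_iteration = pd.DataFrame(rows)
    return EvalResult(
        metric=matrix.metric,
        region_mode=matrix.region_mode,
        method_id=config.method_id,
        gene_set_size=len(gene_set),
        seed=config.seed,
        per_iteration=per_iteration,
    )


def _draw_split(y_idx: np.ndarray, config: EvalConfig, seed: int, max_redraws: int = 100):
    """One train/test split; plain splits are redrawn until every class
    appears on both sides (logged), stratified splits guarantee it."""
    n = len(y_idx)
    all_idx = np.arange(n)
    if config.split_mode == "stratified":
        train_idx, test_idx = train_test_split(
            all_idx, train_size=config.train_fraction, random_state=seed, stratify=y_idx
        )
        return np.sort(train_idx), np.sort(test_idx)
    rng = np.random.default_rng(seed)
    n_classes = y_idx.max() + 1
    for attempt in range(max_redraws):
        perm = rng.permutation(n)
        n_train = int(round(config.train_fraction * n))
        train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        if (len(np.unique(y_idx[train_idx])) == n_classes
                and len(np.unique(y_idx[test_idx])) == n_classes):
            if attempt:
                logger.info("plain split redrawn %d time(s)", attempt)
            return train_idx, test_idx
    raise RuntimeError(f"could not draw a split covering all classes in {max_redraws} attempts")


# ---------------------------------------------------------------------------
# grid, DDR comparison, metric-vs-metric test

def evaluate_grid(
    matrices: Mapping[str, FeatureMatrix],
    metadata: pd.DataFrame,
    rankings: Mapping[str, GeneRanking],
    gene_set_sizes: Sequence[int],
    methods: Sequence[str],
    config: EvalConfig,
    include_all_genes: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full factorial evaluation: metrics × gene sets × methods.

    Returns (results, summary).  ``results`` has one row per combination with
    the aggregate scores; ``summary`` has, per (method, metric), the maximum
    over gene sets of mean AUC and a tier flag: Tier I if mean AUC peaks at
    the largest nested gene set, Tier II if it peaks at an interior size (the
    all-genes set is excluded from tier assignment).
    """
    rows = []
    for metric_key, matrix in matrices.items():
        ranked = rankings[metric_key].ranked_genes
        sets: list[tuple[int, list[str], bool]] = [
            (k, ranked[:k], False) for k in sorted(gene_set_sizes)
        ]
        if include_all_genes:
            sets.append((len(matrix.gene_ids), list(matrix.gene_ids), True))
        for method in methods:
            for k, gene_set, is_all in sets:
                res = run_evaluation(matrix, metadata, gene_set, replace(config, method_id=method))
                rows.append({
                    "metric": metric_key, "region_mode": matrix.region_mode, "method": method,
                    "gene_set_size": k, "all_genes": is_all, **res.aggregates,
                })
    results = pd.DataFrame(rows)
    summaries = []
    for (metric_key, method), grp in results.groupby(["metric", "method"]):
        nested = grp[~grp["all_genes"]].sort_values("gene_set_size")
        best = grp.loc[grp["auc"].idxmax()]
        tier = ""
        if len(nested) >= 2:
            peak_size = nested.loc[nested["auc"].idxmax(), "gene_set_size"]
            tier = "I" if peak_size == nested["gene_set_size"].max() else "II"
        summaries.append({
            "metric": metric_key, "method": method, "max_mean_auc": float(grp["auc"].max()),
            "best_gene_set_size": int(best["gene_set_size"]), "tier": tier,
        })
    return results, pd.DataFrame(summaries)


def ddr_comparison(
    tpm_matrix: FeatureMatrix,
    metadata: pd.DataFrame,
    ddr_genes: Sequence[str],
    config: EvalConfig,
    n_random_sets: int = 100,
) -> dict:
    """Fixed gene list (e.g. DNA damage response genes) vs size-matched random
    expressed gene sets, on the expression metric.

    The fixed list is evaluated once; ``n_random_sets`` random sets of the
    same size are drawn (seeded) from the matrix's genes and evaluated with
    the same config.  Returns the two AUC summaries and a two-sided t-test
    between the fixed list's per-iteration AUCs and the pooled per-iteration
    AUCs of the random sets.
    """
    ddr_genes = list(ddr_genes)
    expressed = list(tpm_matrix.gene_ids)
    missing = set(ddr_genes) - set(expressed)
    if missing:
        raise ValueError(f"DDR genes absent from the expressed matrix: {sorted(missing)[:5]}")
    if len(ddr_genes) > len(expressed):
        raise ValueError("more DDR genes than expressed genes")
    if n_random_sets < 2:
        logger.warning("n_random_sets=%d gives the t-test very little power", n_random_sets)
    ddr_result = run_evaluation(tpm_matrix, metadata, ddr_genes, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    random_aucs, random_means = [], []
    for _ in range(n_random_sets):
        random_set = list(rng.choice(expressed, size=len(ddr_genes), replace=False))
        res = run_evaluation(tpm_matrix, metadata, random_set, config)
        random_aucs.append(res.per_iteration["auc"].to_numpy())
        random_means.append(res.mean_auc)
    pooled = np.concatenate(random_aucs)
    p = compare_metric_performance(ddr_result.per_iteration["auc"].to_numpy(), pooled)
    return {
        "ddr_result": ddr_result,
        "ddr_mean_auc": ddr_result.mean_auc,
        "random_mean_auc": float(np.mean(random_means)),
        "random_mean_aucs": np.asarray(random_means),
        "t_test_p": p,
    }


def compare_metric_performance(auc_a: Sequence[float], auc_b: Sequence[float]) -> float:
    """Two-sample two-tailed t-test p-value between per-iteration AUC vectors."""
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("AUC vectors must be non-empty")
    if a.var() == 0 and b.var() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    p = stats.ttest_ind(a, b).pvalue
    return 1.0 if np.isnan(p) else float(p)
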