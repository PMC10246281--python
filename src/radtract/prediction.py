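"""Experiment harness: feature selection, forest models, cross-validation,
importance aggregation and paired method comparison.

The pipeline mirrors common radiomics practice: constant and highly
correlated features are dropped, a univariate filter keeps the top 500,
and a 500-tree random forest is evaluated with repeated, differently
seeded leave-one-out cross-validation.  Feature selection is re-fit
inside every training fold — never on held-out rows — and per-feature
importances (mean decrease in impurity) are aggregated to parcels or
feature classes by group summation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.feature_selection import f_classif, f_regression
from sklearn.metrics import mean_absolute_error, roc_auc_score
from sklearn.model_selection import train_test_split


@dataclass
class SelectionConfig:
    """Constant removal, correlation pruning and univariate capping."""

    correlation_threshold: float = 0.95
    k_select: int = 500
    task: str = "classify"  # chooses ANOVA-F vs F-regression scores

    def __post_init__(self) -> None:
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation threshold must be in (0, 1]")
        if self.k_select < 1:
            raise ValueError("k_select must be >= 1")


def select_features(
    X: pd.DataFrame,
    y: np.ndarray,
    cfg: SelectionConfig | None = None,
    train_mask: np.ndarray | None = None,
) -> List[str]:
    """Deterministic column subset fitted on the training rows only.

    Order of operations: drop constant columns, greedily drop the later
    column of every pair with |Pearson r| above the threshold, rank the
    survivors by univariate score and keep the top ``k_select``.
    Columns containing NaN on the training rows are treated as
    degenerate and dropped up front.
    """
    cfg = cfg or SelectionConfig()
    if len(X) == 0:
        raise ValueError("no rows")
    if train_mask is None:
        train_mask = np.ones(len(X), dtype=bool)
    Xt = X.loc[np.asarray(train_mask)]
    yt = np.asarray(y)[np.asarray(train_mask)]

    values = Xt.to_numpy(dtype=float)
    ok = ~np.any(np.isnan(values), axis=0)
    std = np.zeros(values.shape[1])
    std[ok] = values[:, ok].std(axis=0)
    keep = ok & (std > 0)
    cols = np.asarray(X.columns)[keep]
    values = values[:, keep]
    if values.shape[1] == 0:
        return []

    corr = np.corrcoef(values, rowvar=False)
    if corr.ndim == 0:
        corr = corr.reshape(1, 1)
    np.fill_diagonal(corr, 0.0)
    alive = np.ones(len(cols), dtype=bool)
    for i in range(len(cols)):
        if not alive[i]:
            continue
        too_high = np.abs(corr[i]) > cfg.correlation_threshold
        too_high[: i + 1] = False
        alive &= ~too_high
    cols = cols[alive]
    values = values[:, alive]

    if len(cols) <= cfg.k_select:
        return list(cols)
    score_fn = f_classif if cfg.task == "classify" else f_regression
    scores, _ = score_fn(values, yt)
    scores = np.nan_to_num(scores, nan=-np.inf)
    order = np.argsort(-scores, kind="stable")[: cfg.k_select]
    return list(cols[np.sort(order)])


@dataclass
class ModelReport:
    """Aggregated cross-validation outcome."""

    scores: np.ndarray  # one entry per seed
    metric: str
    predictions: pd.DataFrame  # per-seed, per-subject held-out predictions
    feature_importances: List[Dict[str, float]]  # one dict per fitted model
    extras: Dict[str, float] = field(default_factory=dict)

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.scores))

    @property
    def sd_score(self) -> float:
        return float(np.std(self.scores))


def _auroc(y_true: np.ndarray, proba: np.ndarray, classes: np.ndarray) -> float:
    if len(classes) == 2:
        return float(roc_auc_score(y_true == classes[1], proba[:, 1]))
    return float(
        roc_auc_score(y_true, proba, multi_class="ovr", average="macro", labels=classes)
    )


def cross_validate_classifier(
    X: pd.DataFrame,
    y: Sequence,
    n_seeds: int = 10,
    n_trees: int = 500,
    selection: SelectionConfig | None = None,
    base_seed: int = 0,
) -> ModelReport:
    """Repeated, differently seeded leave-one-out cross-validation.

    For every seed: LOO folds with selection re-fit on each training
    fold, a random forest fit, and the held-out class probability
    recorded; AUROC is pooled over the folds of a seed (one-vs-rest
    macro average for more than two classes).  Reported as the per-seed
    score vector.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if np.min([np.sum(y == c) for c in classes]) < 2:
        raise ValueError("need at least two subjects per class")
    selection = selection or SelectionConfig(task="classify")
    n = len(X)
    scores = []
    importances: List[Dict[str, float]] = []
    pred_rows = []
    for s in range(n_seeds):
        seed = base_seed + s
        proba = np.zeros((n, len(classes)))
        for i in range(n):
            train = np.ones(n, dtype=bool)
            train[i] = False
            cols = select_features(X, y, selection, train_mask=train)
            if not cols:
                # fully degenerate fold (all features constant): fall back
                # to the training class frequencies
                freq = np.array([np.mean(y[train] == c) for c in classes])
                proba[i] = freq
                importances.append({})
                continue
            clf = RandomForestClassifier(
                n_estimators=n_trees, random_state=seed, n_jobs=1
            )
            clf.fit(X.loc[train, cols], y[train])
            proba[i] = clf.predict_proba(X.loc[[X.index[i]], cols])[0]
            importances.append(dict(zip(cols, clf.feature_importances_)))
        scores.append(_auroc(y, proba, classes))
        for i in range(n):
            pred_rows.append(
                {"seed": seed, "subject": X.index[i], "true": y[i],
                 **{f"p_{c}": proba[i, j] for j, c in enumerate(classes)}}
            )
    return ModelReport(
        scores=np.asarray(scores),
        metric="auroc",
        predictions=pd.DataFrame(pred_rows),
        feature_importances=importances,
    )


def evaluate_regression(
    X: pd.DataFrame,
    y: Sequence[float],
    n_seeds: int = 10,
    n_trees: int = 500,
    test_size: float = 0.3,
    selection: SelectionConfig | None = None,
    base_seed: int = 0,
) -> ModelReport:
    """Forest regression on a fixed train/test split, repeated over seeds.

    The split (default 70/30, stratified by outcome quartile) is fixed by
    ``base_seed``; each seed refits selection and the forest.  Scores are
    per-seed Pearson r on the test set; MAE and the two-sided t-test p
    for r go to ``extras``.  Constant predictions are flagged and
    reported as r = 0, p = 1.
    """
    y = np.asarray(y, dtype=float)
    quartile = np.searchsorted(np.quantile(y, [0.25, 0.5, 0.75]), y)
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_size, random_state=base_seed, stratify=quartile
    )
    if len(test_idx) < 3:
        raise ValueError("test split too small")
    selection = selection or SelectionConfig(task="regress")
    scores, maes, pvals = [], [], []
    importances: List[Dict[str, float]] = []
    pred_rows = []
    train = np.zeros(len(y), dtype=bool)
    train[train_idx] = True
    for s in range(n_seeds):
        seed = base_seed + s
        cols = select_features(X, y, selection, train_mask=train)
        if cols:
            reg = RandomForestRegressor(
                n_estimators=n_trees, random_state=seed, n_jobs=1
            )
            reg.fit(X.loc[train, cols], y[train])
            pred = reg.predict(X.iloc[test_idx][cols])
            importances.append(dict(zip(cols, reg.feature_importances_)))
        else:
            # no usable features: constant mean prediction, flagged below
            pred = np.full(len(test_idx), y[train].mean())
            importances.append({})
        maes.append(mean_absolute_error(y[test_idx], pred))
        if np.std(pred) == 0 or np.std(y[test_idx]) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(y[test_idx], pred)
        scores.append(float(r))
        pvals.append(float(p))
        for j, i in enumerate(test_idx):
            pred_rows.append(
                {"seed": seed, "subject": X.index[i], "true": y[i], "pred": pred[j]}
            )
    return ModelReport(
        scores=np.asarray(scores),
        metric="pearson_r",
        predictions=pd.DataFrame(pred_rows),
        feature_importances=importances,
        extras={
            "mae_mean": float(np.mean(maes)),
            "mae_sd": float(np.std(maes)),
            "p_mean": float(np.mean(pvals)),
        },
    )


def aggregate_importance(
    report: ModelReport,
    group_of_feature: Callable[[str], str] | Dict[str, str],
) -> pd.Series:
    """Group-summed feature importances, averaged over fitted models.

    ``group_of_feature`` maps a feature name to its group (parcel or
    feature class); a missing mapping raises rather than dropping the
    feature.  Features never selected in a model contribute zero to that
    model.  When the grouping covers all features the group importances
    of each model sum to 1, so the averaged values do too.
    """
    if not report.feature_importances:
        raise ValueError("report holds no fitted models")
    lookup = group_of_feature.get if isinstance(group_of_feature, dict) else None
    totals: Dict[str, float] = {}
    for model_imp in report.feature_importances:
        for feat, imp in model_imp.items():
            if lookup is not None:
                group = lookup(feat)
                if group is None:
                    raise KeyError(f"feature {feat!r} missing from the group map")
            else:
                group = group_of_feature(feat)
            totals[group] = totals.get(group, 0.0) + imp
    n_models = len(report.feature_importances)
    return pd.Series({g: v / n_models for g, v in totals.items()}).sort_index()


def compare_methods(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    n_comparisons: int = 1,
    alpha: float = 0.05,
) -> Tuple[float, float, str]:
    """Paired two-sided Wilcoxon signed-rank test with Bonferroni cap.

    Returns ``(p_raw, p_bonferroni, winner)`` where the winner is the
    higher-mean method when the corrected p falls below ``alpha``, else
    "tie".  The exact null distribution is used for up to 25 pairs.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b) or len(a) < 5:
        raise ValueError("need equal-length paired vectors of length >= 5")
    diff = a - b
    if np.all(diff == 0):
        return 1.0, 1.0, "tie"
    # exact null distribution for small samples; zeros force the normal
    # approximation (the exact distribution is undefined with zeros)
    method = "exact" if len(a) <= 25 and not np.any(diff == 0) else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    p_raw = float(res.pvalue)
    p_bonf = min(1.0, p_raw * n_comparisons)
    if p_bonf < alpha:
        winner = "A" if a.mean() > b.mean() else "B"
    else:
        winner = "tie"
    return p_raw, p_bonf, winner
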