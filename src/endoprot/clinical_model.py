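"""Clinical prediction of endotype membership and per-cluster comparisons.

A random forest predicts the proteomics-derived cluster labels from
clinical and laboratory variables alone, ranking predictors by two
importances: mean decrease in accuracy (per-feature permutation measured
on each tree's out-of-bag samples) and Gini impurity decrease. A
threshold scan reports whether a single laboratory value cleanly separates
the clusters (as circulating eosinophil count did between the published
endotypes), and descriptive group comparisons use the Wilcoxon rank-sum
test for numeric variables and the chi-squared test for categorical ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .data_io_qc import ClinicalTable

logger = logging.getLogger("endoprot")


@dataclass
class ImportanceTable:
    """Dual variable-importance ranking of clinical predictors."""

    table: pd.DataFrame  # mean_decrease_accuracy, gini_decrease, rank_mda, rank_gini


@dataclass
class ComparisonTable:
    """Per-variable descriptive statistics and two-group tests."""

    table: pd.DataFrame  # group summaries, test, statistic, p, significant


@dataclass
class ThresholdReport:
    feature: str
    extrema: pd.DataFrame  # per-cluster min/max
    separating_value: float | None
    best_threshold: float
    split_accuracy: float


def _prepare_features(data: pd.DataFrame) -> pd.DataFrame:
    """Numeric matrix for the forest: categoricals one-hot encoded, missing
    values median/mode-imputed (imputation is refit per training fold by
    the caller when cross-validating; here it serves the single OOB fit)."""
    num = data.select_dtypes(include=[np.number]).copy()
    cat = data.select_dtypes(exclude=[np.number])
    for col in cat.columns:
        dummies = pd.get_dummies(cat[col], prefix=col, dtype=float)
        num = pd.concat([num, dummies], axis=1)
    for col in num.columns:
        if num[col].isna().any():
            num[col] = num[col].fillna(num[col].median())
    return num


def _oob_masks(rf: RandomForestClassifier, n: int) -> list[np.ndarray]:
    """Out-of-bag sample masks per tree, reconstructed by replaying
    scikit-learn's bootstrap draw from each tree's random state."""
    masks = []
    for tree in rf.estimators_:
        sampled = np.random.RandomState(tree.random_state).randint(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        masks.append(mask)
    return masks


def _oob_accuracy(rf, X: np.ndarray, y: np.ndarray, masks) -> float:
    """Forest OOB accuracy by majority vote over each sample's OOB trees."""
    n, n_classes = len(y), len(rf.classes_)
    votes = np.zeros((n, n_classes))
    for tree, mask in zip(rf.estimators_, masks):
        if not mask.any():
            continue
        pred = tree.predict(X[mask])
        votes[np.flatnonzero(mask), pred.astype(int)] += 1
    covered = votes.sum(axis=1) > 0
    return float((votes[covered].argmax(axis=1) == y[covered]).mean())


def _permutation_mda(rf, X: np.ndarray, y: np.ndarray, masks, seed: int) -> np.ndarray:
    """Mean decrease in accuracy: per tree, the drop in out-of-bag accuracy
    when one feature is permuted within the tree's OOB block, averaged over
    trees (the classic unscaled permutation importance)."""
    rng = np.random.default_rng(seed)
    n_features = X.shape[1]
    drops = np.zeros(n_features)
    counts = np.zeros(n_features)
    for tree, mask in zip(rf.estimators_, masks):
        if not mask.any():
            continue
        Xo = X[mask]
        yo = y[mask]
        base = float((tree.predict(Xo) == yo).mean())
        for f in range(n_features):
            Xp = Xo.copy()
            Xp[:, f] = rng.permutation(Xp[:, f])
            drops[f] += base - float((tree.predict(Xp) == yo).mean())
            counts[f] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, drops / np.maximum(counts, 1), 0.0)


def fit_rf_predictor(
    clinical: ClinicalTable | pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
) -> tuple[RandomForestClassifier, ImportanceTable, float]:
    """Fit the clinical random-forest predictor of cluster membership.

    Returns the fitted forest, the dual importance table (permutation MDA
    on out-of-bag samples, Gini impurity decrease, and ranks for both) and
    the out-of-bag accuracy.
    """
    data = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    labels = labels.dropna()
    data = data.reindex(labels.index)
    y_raw = labels.astype(str)
    classes = sorted(y_raw.unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to fit a predictor")
    y = y_raw.map({c: i for i, c in enumerate(classes)}).to_numpy()
    feats = _prepare_features(data)
    X = feats.to_numpy(dtype=float)
    n = len(y)

    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=seed,
    ).fit(X, y)
    masks = _oob_masks(rf, n)
    mda = _permutation_mda(rf, X, y, masks, seed=seed)
    table = pd.DataFrame(
        {
            "mean_decrease_accuracy": mda,
            "gini_decrease": rf.feature_importances_,
        },
        index=feats.columns,
    )
    table["rank_mda"] = table["mean_decrease_accuracy"].rank(ascending=False, method="first").astype(int)
    table["rank_gini"] = table["gini_decrease"].rank(ascending=False, method="first").astype(int)
    logger.info("fit_rf_predictor: OOB accuracy %.3f over %d features", rf.oob_score_, X.shape[1])
    return rf, ImportanceTable(table), float(rf.oob_score_)


def threshold_scan(
    clinical: ClinicalTable | pd.DataFrame,
    labels: pd.Series,
    feature: str,
) -> ThresholdReport:
    """Per-cluster extrema of one numeric feature and the best single-split
    threshold; reports a clean separating value when one cluster's maximum
    lies below the other's minimum."""
    data = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    vals = data[feature].reindex(labels.index).astype(float)
    ok = vals.notna() & labels.notna()
    if not ok.any():
        raise ValueError(f"feature {feature!r} has no observed values")
    vals, labs = vals[ok], labels[ok].astype(str)
    groups = sorted(labs.unique())
    extrema = pd.DataFrame(
        {
            "min": [vals[labs == g].min() for g in groups],
            "max": [vals[labs == g].max() for g in groups],
            "n": [int((labs == g).sum()) for g in groups],
        },
        index=groups,
    )
    separating = None
    if len(groups) == 2:
        lo, hi = groups
        if extrema.loc[lo, "max"] < extrema.loc[hi, "min"]:
            separating = float((extrema.loc[lo, "max"] + extrema.loc[hi, "min"]) / 2)
        elif extrema.loc[hi, "max"] < extrema.loc[lo, "min"]:
            separating = float((extrema.loc[hi, "max"] + extrema.loc[lo, "min"]) / 2)
    # best single split by accuracy over candidate midpoints
    order = np.sort(vals.unique())
    candidates = (order[:-1] + order[1:]) / 2 if len(order) > 1 else order
    best_t, best_acc = float(order[0]), 0.0
    y = labs.to_numpy()
    for t in candidates:
        below = vals.to_numpy() <= t
        for g_below, g_above in ((groups[0], groups[-1]), (groups[-1], groups[0])):
            acc = float(((below & (y == g_below)) | (~below & (y == g_above))).mean())
            if acc > best_acc:
                best_acc, best_t = acc, float(t)
    return ThresholdReport(
        feature=feature,
        extrema=extrema,
        separating_value=separating,
        best_threshold=best_t,
        split_accuracy=best_acc,
    )


def wilcoxon_rank_sum(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have <= ``exact_max_n`` observations
    and no ties; otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= exact_max_n and len(y) <= exact_max_n and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_squared(contingency: pd.DataFrame, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test of independence on a contingency table."""
    table = contingency.to_numpy(dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table (empty row/column)")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def compare_groups(
    clinical: ClinicalTable | pd.DataFrame,
    labels: pd.Series,
    categorical: list[str] | None = None,
    alpha: float = 0.05,
    yates: bool = False,
) -> ComparisonTable:
    """Descriptive two-group comparison of every clinical variable.

    Numeric variables: group mean (SD) and the Wilcoxon rank-sum test.
    Categorical variables (non-numeric dtype, or named in ``categorical``):
    group counts and the chi-squared test. Degenerate variables are skipped
    with a warning.
    """
    data = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    labels = labels.dropna().astype(str)
    data = data.reindex(labels.index)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("compare_groups expects exactly 2 groups")
    g1, g2 = groups
    categorical = set(categorical or [])
    rows = []
    for col in data.columns:
        series = data[col]
        is_cat = col in categorical or not pd.api.types.is_numeric_dtype(series)
        if not is_cat and pd.api.types.is_numeric_dtype(series) and series.dropna().nunique() == 2 \
                and set(series.dropna().unique()) <= {0, 1}:
            is_cat = True  # 0/1 coded categorical (e.g. sex)
        try:
            if is_cat:
                cont = pd.crosstab(series, labels)
                stat, p = chi_squared(cont, yates=yates)
                summary = {
                    f"{g}_summary": "/".join(str(int(v)) for v in cont[g]) for g in groups
                }
                test = "chi-squared"
            else:
                x = series[labels == g1].dropna().astype(float)
                y = series[labels == g2].dropna().astype(float)
                if len(x) < 2 or len(y) < 2:
                    raise ValueError("fewer than 2 observations in a group")
                stat, p = wilcoxon_rank_sum(x, y)
                summary = {
                    f"{g1}_summary": f"{x.mean():.3g} ({x.std(ddof=1):.3g})",
                    f"{g2}_summary": f"{y.mean():.3g} ({y.std(ddof=1):.3g})",
                }
                test = "wilcoxon"
        except ValueError as exc:
            warnings.warn(f"variable {col!r} skipped: {exc}")
            continue
        rows.append({"variable": col, "test": test, "statistic": stat, "p": p, **summary})
    table = pd.DataFrame(rows).set_index("variable") if rows else pd.DataFrame()
    if len(table):
        table["significant"] = table["p"] < alpha
    return ComparisonTable(table)
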