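"""Endotype discovery: k-means, WCSS scree, stability, reproducibility, t-SNE.

The cluster-determination protocol mirrors a three-part validation strategy:
(1) a WCSS scree over k = 1..10 to bracket plausible cluster counts; (2) a
stability check that perturbs the dataset by including/excluding healthy
controls and compares patient assignments through a confusion matrix; and
(3) a reproducibility statistic — repeated random splits, independent
k-means on each part, and a random-forest prediction rule carried from the
training to the testing part, summarised as median percent accuracies over
100 iterations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE

logger = logging.getLogger("endoprot")


@dataclass
class ClusterModel:
    """A fitted k-means model with size-canonicalised cluster indices."""

    k: int
    assignments: pd.Series  # sample id -> cluster index (0-based)
    centroids: np.ndarray  # k x p
    wcss: float
    seed: int
    restarts: int

    @property
    def sample_ids(self) -> pd.Index:
        return self.assignments.index

    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


@dataclass
class StabilityReport:
    """Agreement between two clusterings of the shared patient samples."""

    confusion: pd.DataFrame  # patient-model clusters x all-data clusters
    mapping: dict[int, int]  # patient-model cluster -> matched all-data cluster
    agreement: float
    outliers: list[str]
    hc_majority_cluster: int | None = None


@dataclass
class ReproducibilityReport:
    """Accuracies (percent) of the split / cluster / predict protocol."""

    train_accuracy: list[float]
    test_accuracy: list[float]
    iterations: int
    split_fraction: float
    n_skipped: int = 0

    @property
    def median_train(self) -> float:
        return float(np.median(self.train_accuracy))

    @property
    def median_test(self) -> float:
        return float(np.median(self.test_accuracy))


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def _canonicalise(labels: np.ndarray, k: int, index: pd.Index) -> np.ndarray:
    """Relabel clusters by descending size; ties broken by the smallest
    member position, so the labeling is reproducible run to run."""
    order = sorted(
        range(k),
        key=lambda c: (-(labels == c).sum(), int(np.argmax(labels == c)) if (labels == c).any() else len(labels)),
    )
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in labels])


def kmeans_fit(X, k: int, restarts: int = 25, seed: int = 0) -> ClusterModel:
    """Lloyd's algorithm with k-means++ starts, best of ``restarts`` by WCSS."""
    Xf = _as_frame(X)
    n = len(Xf)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n} samples")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(Xf.to_numpy())
    labels = _canonicalise(km.labels_, k, Xf.index)
    # reorder centroids to the canonical labels
    inverse = np.empty(k, dtype=int)
    for orig in range(k):
        mask = km.labels_ == orig
        if mask.any():
            inverse[labels[np.argmax(mask)]] = orig
    centroids = km.cluster_centers_[inverse]
    return ClusterModel(
        k=k,
        assignments=pd.Series(labels, index=Xf.index, name="cluster"),
        centroids=centroids,
        wcss=float(km.inertia_),
        seed=seed,
        restarts=restarts,
    )


def wcss_scree(X, k_max: int = 10, restarts: int = 25, seed: int = 0) -> pd.DataFrame:
    """WCSS of the best-of-restarts fit for k = 1..k_max."""
    Xf = _as_frame(X)
    if k_max > len(Xf):
        raise ValueError("k_max exceeds the sample count")
    rows = [(k, kmeans_fit(Xf, k, restarts=restarts, seed=seed).wcss) for k in range(1, k_max + 1)]
    return pd.DataFrame(rows, columns=["k", "wcss"])


def stability_compare(
    model_patients: ClusterModel,
    model_all: ClusterModel,
    hc_ids,
) -> StabilityReport:
    """Compare patient assignments with and without HC perturbation.

    The all-data model's HC-majority cluster is identified first; patient
    clusters are then matched across the two models by maximum agreement
    (Hungarian assignment on the negated contingency). Outliers are patients
    whose all-data cluster is not the one matched to their patient-model
    cluster — notably patients landing in the HC-majority cluster.
    """
    hc_ids = pd.Index(hc_ids)
    patients = model_patients.sample_ids
    if not patients.isin(model_all.sample_ids).all():
        raise ValueError("patient samples must be a subset of the all-data model")

    hc_in_all = model_all.sample_ids.intersection(hc_ids)
    hc_majority = None
    if len(hc_in_all):
        hc_majority = int(model_all.assignments.loc[hc_in_all].mode().iloc[0])

    a = model_patients.assignments.loc[patients]
    b = model_all.assignments.loc[patients]
    confusion = pd.crosstab(a, b).reindex(
        index=range(model_patients.k), columns=range(model_all.k), fill_value=0
    )
    cost = -confusion.to_numpy(dtype=float)
    rows, cols = linear_sum_assignment(cost)
    mapping = {int(r): int(confusion.columns[c]) for r, c in zip(rows, cols)}
    matched = sum(confusion.iat[r, c] for r, c in zip(rows, cols))
    agreement = matched / len(patients)
    outliers = [
        s for s in patients
        if int(b.loc[s]) != mapping.get(int(a.loc[s]), -1)
    ]
    return StabilityReport(
        confusion=confusion,
        mapping=mapping,
        agreement=float(agreement),
        outliers=outliers,
        hc_majority_cluster=hc_majority,
    )


def _best_permutation_accuracy(pred: np.ndarray, ref: np.ndarray, k: int) -> float:
    """Agreement maximised over relabelings of one side (exact for small k,
    Hungarian otherwise)."""
    if k <= 4:
        best = 0
        for perm in itertools.permutations(range(k)):
            mapped = np.array([perm[c] for c in pred])
            best = max(best, int((mapped == ref).sum()))
        return best / len(ref)
    confusion = np.zeros((k, k))
    for p_, r_ in zip(pred, ref):
        confusion[p_, r_] += 1
    rows, cols = linear_sum_assignment(-confusion)
    return confusion[rows, cols].sum() / len(ref)


def reproducibility(
    X,
    k: int = 2,
    iterations: int = 100,
    split_fraction: float = 0.7,
    seed: int = 0,
    restarts: int = 25,
    n_trees: int = 500,
) -> ReproducibilityReport:
    """Repeated-split reproducibility of a k-means clustering.

    Each iteration: (1) random split into training/testing parts; (2)
    independent k-means (same k) on each part; (3) a random-forest rule
    (``n_trees`` trees, sqrt-p features per split) trained on the training
    part's cluster labels, with training accuracy the resubstitution
    agreement; (4) the rule predicts the testing part, and testing accuracy
    is the agreement with the testing part's own k-means labels maximised
    over cluster-label permutations. Accuracies are reported in percent.
    """
    Xf = _as_frame(X)
    n = len(Xf)
    n_train = int(round(split_fraction * n))
    if min(n_train, n - n_train) < k:
        raise ValueError("split leaves fewer samples than clusters")
    master = np.random.SeedSequence(seed)
    sub_seeds = master.generate_state(iterations * 3).reshape(iterations, 3) % (2 ** 31)

    train_acc: list[float] = []
    test_acc: list[float] = []
    skipped = 0
    Xnp = Xf.to_numpy()
    for it in range(iterations):
        s_split, s_km, s_rf = (int(s) for s in sub_seeds[it])
        order = np.random.default_rng(s_split).permutation(n)
        tr, te = order[:n_train], order[n_train:]
        try:
            km_tr = KMeans(n_clusters=k, n_init=restarts, random_state=s_km).fit(Xnp[tr])
            km_te = KMeans(n_clusters=k, n_init=restarts, random_state=s_km).fit(Xnp[te])
            if len(np.unique(km_tr.labels_)) < 2:
                raise ValueError("degenerate training clustering")
            rf = RandomForestClassifier(
                n_estimators=n_trees, max_features="sqrt", random_state=s_rf
            ).fit(Xnp[tr], km_tr.labels_)
            train_acc.append(100.0 * float((rf.predict(Xnp[tr]) == km_tr.labels_).mean()))
            pred_te = rf.predict(Xnp[te])
            test_acc.append(
                100.0 * _best_permutation_accuracy(pred_te, km_te.labels_, k)
            )
        except ValueError as exc:  # degenerate split
            logger.warning("reproducibility iteration %d skipped: %s", it, exc)
            skipped += 1
    if skipped > 0.10 * iterations:
        raise RuntimeError(f"{skipped}/{iterations} iterations degenerate")
    return ReproducibilityReport(
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        iterations=iterations,
        split_fraction=split_fraction,
        n_skipped=skipped,
    )


@dataclass
class Ellipse:
    """95% bivariate-normal contour of one cluster in the embedding."""

    center: tuple[float, float]
    width: float
    height: float
    angle_deg: float


def embed_2d(
    X,
    seed: int = 0,
    perplexity: float | None = None,
    labels: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict[int, Ellipse]]:
    """t-SNE embedding to 2-D with per-cluster 95% confidence ellipses.

    Deterministic given the seed (exact-gradient t-SNE). Ellipses are the
    chi-square(2, 0.95) contours of a bivariate normal fitted to each
    cluster's embedded coordinates; clusters with < 3 members get no
    ellipse.
    """
    Xf = _as_frame(X)
    n = len(Xf)
    if n < 4:
        raise ValueError("t-SNE needs at least 4 samples")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    if perplexity >= (n - 1):
        raise ValueError("perplexity too large for the sample count")
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed,
        init="pca", method="exact",
    ).fit_transform(Xf.to_numpy())
    emb = pd.DataFrame(coords, index=Xf.index, columns=["tsne1", "tsne2"])
    ellipses: dict[int, Ellipse] = {}
    if labels is not None:
        chi2_95 = stats.chi2.ppf(0.95, df=2)
        for lab in sorted(pd.Series(labels).unique()):
            pts = emb.loc[labels.index[labels == lab]].to_numpy()
            if len(pts) < 3:
                continue
            cov = np.cov(pts.T)
            evals, evecs = np.linalg.eigh(cov)
            evals = np.maximum(evals, 0.0)
            angle = float(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])))
            ellipses[int(lab)] = Ellipse(
                center=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                width=float(2 * np.sqrt(evals[-1] * chi2_95)),
                height=float(2 * np.sqrt(evals[0] * chi2_95)),
                angle_deg=angle,
            )
    return emb, ellipses
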