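"""Signed weighted co-expression network analysis of protein profiles.

A signed adjacency ``a_ij = ((1 + cor_ij)/2)^beta`` is built from Pearson
correlations across samples, with the soft power beta chosen as the lowest
integer at which the scale-free topology fit reaches R^2 = 0.9. The
topological overlap measure (TOM) converts adjacency into a shared-
neighborhood similarity; modules are branches of an average-linkage
dendrogram on 1 - TOM, subject to a minimum size, a kME rescue of
unassigned proteins, and an eigenprotein-correlation merge step. Each
module is summarised by its eigenprotein (first principal component of the
z-scaled member profiles), its kME table and its hub (highest intramodular
kME), and correlated against clinical traits with BH adjustment over the
whole module x trait grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data_io_qc import ClinicalTable, zscale_values
from .diffexp import bh_adjust

logger = logging.getLogger("endoprot")

#: Conventional module color sequence (largest module first); "grey"
#: is reserved for unassigned proteins.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]

GREY = "grey"


@dataclass
class NetworkModel:
    power: int
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    fit_table: pd.DataFrame  # power, r_squared, slope, mean_connectivity


@dataclass
class ModuleAssignment:
    labels: pd.Series  # protein -> module color ("grey" = unassigned)
    merge_history: list[tuple[str, str]] = field(default_factory=list)

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def members(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]

    def modules(self) -> list[str]:
        """Non-grey module names, largest first."""
        sizes = self.sizes().drop(GREY, errors="ignore")
        return list(sizes.index)


@dataclass
class EigenproteinSet:
    me: pd.DataFrame  # samples x modules, per-sample eigenprotein scores
    kme: pd.DataFrame  # proteins x modules, Pearson correlation with each ME
    hubs: dict[str, str]  # module -> hub protein
    variance_explained: dict[str, float] = field(default_factory=dict)


@dataclass
class ModuleTraitCorr:
    r: pd.DataFrame  # modules x traits
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    n_obs: pd.DataFrame


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def _safe_corr(X: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between proteins; zero-variance proteins get
    zero correlation to everything (diagonal kept at 1)."""
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} zero-variance proteins: correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(X.to_numpy(), rowvar=False)
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=X.columns, columns=X.columns)


def signed_adjacency(X: pd.DataFrame, power: int) -> pd.DataFrame:
    """Signed soft-thresholded adjacency: ((1 + cor)/2)^power, unit diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    cor = _safe_corr(X)
    adj = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(adj.values, 1.0)
    return adj


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit: R^2 of log10 p(k) on log10 k over
    equal-width connectivity bins (R^2 forced to 0 for positive slopes)."""
    k = np.asarray(connectivity, dtype=float)
    if np.allclose(k, k[0]):
        raise ValueError("constant connectivity; fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.array([k[which == b].mean() if (which == b).any() else np.nan for b in range(n_bins)])
    freq = np.array([(which == b).mean() for b in range(n_bins)])
    ok = (freq > 0) & np.isfinite(mean_k) & (mean_k > 0)
    if ok.sum() < 3:
        raise ValueError("too few occupied bins for a scale-free fit")
    x, y = np.log10(mean_k[ok]), np.log10(freq[ok])
    slope, _, r, _, _ = stats.linregress(x, y)
    r2 = float(r ** 2) if slope < 0 else 0.0
    return r2, float(slope)


def pick_soft_power(
    X: pd.DataFrame,
    powers=range(1, 21),
    r2_target: float = 0.9,
) -> tuple[int, pd.DataFrame]:
    """Lowest power whose scale-free fit R^2 reaches the target; falls back
    to the best-fitting power (with a warning) when none reaches it."""
    if X.shape[1] < 30:
        raise ValueError("soft-power selection needs >= 30 proteins")
    cor = _safe_corr(X)
    base = (1.0 + cor.to_numpy()) / 2.0
    rows = []
    adj = np.ones_like(base)
    prev_power = 0
    for beta in powers:
        adj = adj * base ** (beta - prev_power)
        prev_power = beta
        k = adj.sum(axis=0) - np.diag(adj)
        try:
            r2, slope = scale_free_fit(k)
        except ValueError as exc:
            logger.warning("power %d skipped: %s", beta, exc)
            r2, slope = np.nan, np.nan
        rows.append((beta, r2, slope, float(k.mean())))
    fit_table = pd.DataFrame(rows, columns=["power", "r_squared", "slope", "mean_connectivity"])
    reached = fit_table[fit_table["r_squared"] >= r2_target]
    if len(reached):
        power = int(reached["power"].iloc[0])
    else:
        # plateau rule: the R^2 curve saturates well before its argmax;
        # take the smallest power within 0.02 of the best fit
        best = float(fit_table["r_squared"].max())
        plateau = fit_table[fit_table["r_squared"] >= best - 0.02]
        power = int(plateau["power"].iloc[0])
        warnings.warn(
            f"no power reached scale-free R^2 {r2_target}; "
            f"using plateau beta={power} (best R^2 {best:.3f})"
        )
    return power, fit_table


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Signed topological overlap:
    tom_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj over u != i, j; unit diagonal."""
    A = adjacency.to_numpy(dtype=float)
    k = A.sum(axis=0) - np.diag(A)
    # l_ij excluding u in {i, j}; diagonal of A is 1
    L = A @ A - A * (np.diag(A)[:, None] + np.diag(A)[None, :])
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def _eigenprotein(Xz: pd.DataFrame, members: pd.Index) -> tuple[pd.Series, float]:
    """First principal component of the z-scaled member submatrix, oriented
    to correlate positively with the average member profile; returns the
    per-sample scores and the fraction of variance explained."""
    sub = Xz[list(members)].to_numpy()
    if sub.shape[1] == 0 or not np.isfinite(sub).all() or np.allclose(sub, 0):
        return pd.Series(0.0, index=Xz.index), 0.0
    u, s, _ = np.linalg.svd(sub, full_matrices=False)
    scores = u[:, 0] * s[0]
    avg = sub.mean(axis=1)
    if np.dot(scores, avg) < 0:
        scores = -scores
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    return pd.Series(scores / np.sqrt(len(scores) - 1), index=Xz.index), var_explained


def _cor_with(X: pd.DataFrame, v: pd.Series) -> pd.Series:
    """Pearson correlation of each column of X with vector v."""
    xv = X.to_numpy()
    vv = v.to_numpy()
    xc = xv - xv.mean(axis=0)
    vc = vv - vv.mean()
    denom = np.sqrt((xc ** 2).sum(axis=0) * (vc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = xc.T @ vc / denom
    return pd.Series(np.nan_to_num(r, nan=0.0), index=X.columns)


def detect_modules(
    tom: pd.DataFrame,
    X: pd.DataFrame,
    min_module_size: int = 20,
    cut_quantile: float = 0.99,
    merge_height: float = 0.25,
    kme_rescue: float = 0.3,
) -> ModuleAssignment:
    """Dendrogram-based module detection on the TOM dissimilarity.

    Average-linkage clustering of 1 - TOM is cut at the ``cut_quantile`` of
    its merge heights; branches below ``min_module_size`` fall to grey;
    grey proteins whose best kME reaches ``kme_rescue`` are rescued into
    that module; modules whose eigenproteins correlate above
    ``1 - merge_height`` are merged iteratively. Final modules are named by
    the conventional color sequence, largest first.
    """
    proteins = tom.index
    if len(proteins) < min_module_size:
        warnings.warn("fewer proteins than min_module_size; everything grey")
        return ModuleAssignment(pd.Series(GREY, index=proteins))
    diss = 1.0 - tom.to_numpy()
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    Z = hierarchy.linkage(squareform(diss, checks=False), method="average")
    cut_h = float(np.quantile(Z[:, 2], cut_quantile))
    flat = hierarchy.fcluster(Z, t=cut_h, criterion="distance")

    labels = pd.Series(flat, index=proteins)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_module_size].index
    labels = labels.where(labels.isin(keep), other=0)  # 0 = grey

    Xz = zscale_values(X[list(proteins)])

    # kME rescue of grey proteins
    module_ids = [m for m in sorted(labels.unique()) if m != 0]
    if module_ids and (labels == 0).any():
        mes = {m: _eigenprotein(Xz, labels.index[labels == m])[0] for m in module_ids}
        grey_idx = labels.index[labels == 0]
        kme_grey = pd.DataFrame({m: _cor_with(Xz[list(grey_idx)], me) for m, me in mes.items()})
        best = kme_grey.idxmax(axis=1)
        best_val = kme_grey.max(axis=1)
        rescued = best_val >= kme_rescue
        labels.loc[grey_idx[rescued]] = best[rescued]
        if rescued.any():
            logger.info("detect_modules: rescued %d grey proteins by kME", int(rescued.sum()))

    # iterative ME-correlation merge
    merge_history: list[tuple[str, str]] = []
    while True:
        module_ids = [m for m in sorted(labels.unique()) if m != 0]
        if len(module_ids) < 2:
            break
        mes = pd.DataFrame({m: _eigenprotein(Xz, labels.index[labels == m])[0] for m in module_ids})
        cor = mes.corr().to_numpy()
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] <= 1.0 - merge_height:
            break
        a, b = module_ids[i], module_ids[j]
        labels = labels.replace(b, a)
        merge_history.append((str(a), str(b)))
        logger.info("detect_modules: merged modules %s and %s (ME cor %.3f)", a, b, cor[i, j])

    # canonical color names, largest module first
    sizes = labels[labels != 0].value_counts()
    name_of = {m: MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
               for i, m in enumerate(sizes.index)}
    name_of[0] = GREY
    named = labels.map(name_of)
    history = [(name_of.get(int(a), str(a)), name_of.get(int(b), str(b))) for a, b in merge_history]
    return ModuleAssignment(named, history)


def module_eigenproteins(X: pd.DataFrame, modules: ModuleAssignment) -> EigenproteinSet:
    """Eigenprotein scores, all-protein kME table and per-module hubs."""
    Xz = zscale_values(X)
    me_cols: dict[str, pd.Series] = {}
    var_exp: dict[str, float] = {}
    for mod in modules.modules():
        members = modules.members(mod)
        if len(members) < 2:
            warnings.warn(f"module {mod} has < 2 members; zero eigenprotein")
            me_cols[mod] = pd.Series(0.0, index=Xz.index)
            var_exp[mod] = 0.0
            continue
        me_cols[mod], var_exp[mod] = _eigenprotein(Xz, members)
    me = pd.DataFrame(me_cols, index=Xz.index)
    kme = pd.DataFrame({mod: _cor_with(Xz, me[mod]) for mod in me.columns})
    hubs = {}
    for mod in me.columns:
        members = modules.members(mod)
        if len(members):
            hubs[mod] = str(kme.loc[members, mod].idxmax())
    return EigenproteinSet(me=me, kme=kme, hubs=hubs, variance_explained=var_exp)


# ---------------------------------------------------------------------------
# Module-trait correlation
# ---------------------------------------------------------------------------

def module_trait_correlation(
    eigen: EigenproteinSet,
    clinical: ClinicalTable | pd.DataFrame,
    samples: pd.Index | None = None,
    min_obs: int = 3,
) -> ModuleTraitCorr:
    """Pearson correlation of each eigenprotein with each numeric trait.

    Pairwise-complete observations; two-sided p by the t transform; BH over
    the full module x trait grid. Constant traits come back as missing.
    """
    data = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    me = eigen.me
    if samples is not None:
        idx = pd.Index(samples)
        me = me.loc[me.index.intersection(idx)]
    data = data.reindex(me.index)
    traits = data.select_dtypes(include=[np.number]).columns
    r = pd.DataFrame(np.nan, index=me.columns, columns=traits)
    p = pd.DataFrame(np.nan, index=me.columns, columns=traits)
    n_obs = pd.DataFrame(0, index=me.columns, columns=traits)
    for trait in traits:
        tv = data[trait].astype(float)
        for mod in me.columns:
            pair = pd.concat([me[mod], tv], axis=1).dropna()
            n = len(pair)
            n_obs.loc[mod, trait] = n
            if n < min_obs or pair.iloc[:, 1].nunique() < 2 or pair.iloc[:, 0].nunique() < 2:
                continue
            rv, pv = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r.loc[mod, trait] = rv
            p.loc[mod, trait] = pv
    flat = p.to_numpy().ravel()
    ok = np.isfinite(flat)
    adj = np.full_like(flat, np.nan)
    if ok.any():
        adj[ok] = bh_adjust(flat[ok])
    p_adj = pd.DataFrame(adj.reshape(p.shape), index=p.index, columns=p.columns)
    return ModuleTraitCorr(r=r, p_raw=p, p_adj=p_adj, n_obs=n_obs)
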