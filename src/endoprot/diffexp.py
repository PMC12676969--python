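"""Moderated differential expression of NPX proteins.

Per-protein ordinary least squares with age/sex covariates, followed by an
empirical-Bayes step that moderates residual variances by borrowing
strength across proteins: residual variances are modeled as scaled
chi-square draws around a prior (d0, s0^2) estimated by the method of
moments on log variances, and each protein's variance is shrunk to the
posterior mean before forming the moderated t statistic. NPX is already a
log2 unit, so the contrast coefficient IS the log2 fold change, and the
published >1.2 / <-1.2 cutoff applies to it directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data_io_qc import ClinicalTable, NPXMatrix

logger = logging.getLogger("endoprot")


@dataclass
class DEResult:
    """Per-protein moderated statistics plus the global variance prior."""

    table: pd.DataFrame  # coef, se, s2, df_resid, t_mod, p_raw, p_adj, significant
    d0: float
    s0_sq: float
    lfc: float | None = None
    alpha: float | None = None


@dataclass
class DEGroups:
    """The three-way partition of upregulated proteins across contrasts."""

    upregulated_ad: set[str]
    stepwise: set[str]
    unique: set[str]


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def build_design(
    clinical: ClinicalTable | pd.DataFrame | None,
    contrast: pd.Series,
    age_col: str = "Age",
    sex_col: str = "Sex",
) -> pd.DataFrame:
    """Intercept + 0/1 contrast indicator + centered age + 0/1 sex.

    ``contrast`` is a boolean/0-1 Series over the samples to model (1 = the
    group of interest). Covariates are taken from the clinical table when
    present; age is centered, which leaves the contrast coefficient
    untouched but improves conditioning.
    """
    idx = contrast.index
    design = pd.DataFrame({"intercept": 1.0, "contrast": contrast.astype(float)}, index=idx)
    data = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    if data is not None:
        if age_col in data.columns:
            age = data[age_col].reindex(idx).astype(float)
            design["age"] = age - age.mean()
        if sex_col in data.columns:
            design["sex"] = data[sex_col].reindex(idx).astype(float)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if len(design) - design.shape[1] < 1:
        raise ValueError("no residual degrees of freedom")
    return design


def fit_linear_models(
    npx: NPXMatrix | pd.DataFrame,
    design: pd.DataFrame,
    coef_col: str = "contrast",
) -> pd.DataFrame:
    """Per-protein OLS; returns coef, unscaled se factor, s2 and residual df.

    The unscaled standard error is sqrt((X'X)^-1 diagonal) for the contrast
    column, so that se = sqrt(s2) * stdev_unscaled.
    """
    Y = npx.values if isinstance(npx, NPXMatrix) else npx
    Y = Y.loc[design.index]
    X = design.to_numpy(dtype=float)
    n, q = X.shape
    if np.linalg.matrix_rank(X) < q:
        raise ValueError("design matrix is rank deficient")
    df = n - q
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y.to_numpy()  # q x p
    resid = Y.to_numpy() - X @ beta
    s2 = (resid ** 2).sum(axis=0) / df
    ci = design.columns.get_loc(coef_col)
    unscaled = float(np.sqrt(xtx_inv[ci, ci]))
    return pd.DataFrame(
        {
            "coef": beta[ci],
            "stdev_unscaled": unscaled,
            "s2": s2,
            "df_resid": float(df),
        },
        index=Y.columns,
    )


# ---------------------------------------------------------------------------
# Empirical Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment estimator of the scaled-chi-square prior (d0, s0^2).

    Works on z = log(s2): e = z - digamma(df/2) + log(df/2) is an unbiased
    estimate of log(s0^2) with known excess variance trigamma(df/2); the
    prior df solves trigamma(d0/2) = Var(e) - mean trigamma(df/2). A
    non-positive right-hand side means the observed variances are no more
    dispersed than sampling noise alone, so d0 = +inf (full pooling).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive finite variances")
    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    G = len(e)
    ebar = e.mean()
    target = float(np.mean((e - ebar) ** 2 * G / (G - 1) - special.polygamma(1, d / 2.0)))
    if target <= 0:
        logger.info("variance prior: no excess dispersion; d0 = +inf (full pooling)")
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * _trigamma_inverse(target)
    s0_sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def ebayes_moderate(fits: pd.DataFrame, d0_override: float | None = None) -> DEResult:
    """Moderate residual variances and compute moderated t / p values.

    Posterior variance: s~2 = (d0*s0^2 + df*s2) / (d0 + df); moderated
    t = coef / (sqrt(s~2) * stdev_unscaled) on d0 + df degrees of freedom.
    ``d0_override=0`` reproduces the ordinary t; ``d0_override=inf`` pools
    every variance to s0^2.
    """
    s2 = fits["s2"].to_numpy(dtype=float)
    df = fits["df_resid"].to_numpy(dtype=float)
    d0, s0_sq = estimate_variance_prior(s2, df)
    if d0_override is not None:
        d0 = float(d0_override)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post) * fits["stdev_unscaled"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = fits["coef"].to_numpy() / se
    p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    table = fits.copy()
    table["s2_post"] = s2_post
    table["se"] = se
    table["t_mod"] = t_mod
    table["p_raw"] = p_raw
    table["p_adj"] = bh_adjust(p_raw)
    return DEResult(table=table, d0=float(d0), s0_sq=float(s0_sq))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Thresholding and grouping
# ---------------------------------------------------------------------------

def threshold_de(
    de: DEResult,
    lfc: float = 1.2,
    alpha: float = 0.05,
    direction: str = "up",
) -> set[str]:
    """Proteins exceeding the log2 fold-change cutoff at adjusted p < alpha.

    The cutoffs are strict (> lfc, < alpha), so a coefficient of exactly
    1.2 does not pass.
    """
    if lfc <= 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    t = de.table
    sig = t["p_adj"] < alpha
    if direction == "up":
        hit = (t["coef"] > lfc) & sig
    elif direction == "down":
        hit = (t["coef"] < -lfc) & sig
    elif direction == "both":
        hit = (t["coef"].abs() > lfc) & sig
    else:
        raise ValueError(f"unknown direction: {direction!r}")
    return set(t.index[hit])


def venn_trichotomy(up_all_vs_hc: set, up_c1_vs_c2: set) -> DEGroups:
    """Partition the two upregulated sets into the three published groups:
    stepwise = both contrasts; unique = cluster contrast only;
    upregulated_ad = all-AD contrast only."""
    up_all = set(up_all_vs_hc)
    up_c1 = set(up_c1_vs_c2)
    stepwise = up_all & up_c1
    return DEGroups(
        upregulated_ad=up_all - stepwise,
        stepwise=stepwise,
        unique=up_c1 - up_all,
    )


def volcano_table(de: DEResult, lfc: float = 1.2, alpha: float = 0.05) -> pd.DataFrame:
    """Export-ready (log2FC, -log10 adjusted p, flag) table."""
    t = de.table
    tiny = np.finfo(float).tiny
    y = -np.log10(np.maximum(t["p_adj"].to_numpy(), tiny))
    return pd.DataFrame(
        {
            "coef": t["coef"],
            "neg_log10_p_adj": y,
            "flag": (t["coef"].abs() > lfc) & (t["p_adj"] < alpha),
        },
        index=t.index,
    )


def mean_variance_table(npx: NPXMatrix, fits: pd.DataFrame) -> pd.DataFrame:
    """Mean NPX vs log residual variance per protein (model diagnostic)."""
    return pd.DataFrame(
        {
            "mean_npx": npx.values.mean(axis=0),
            "log_s2": np.log(fits["s2"]),
        },
        index=fits.index,
    )


def run_contrast(
    npx: NPXMatrix,
    clinical: ClinicalTable | None,
    group_of_interest: pd.Series,
    lfc: float = 1.2,
    alpha: float = 0.05,
) -> DEResult:
    """Convenience wrapper: design, fit, moderate, threshold for one contrast
    restricted to the samples where ``group_of_interest`` is not null."""
    mask = group_of_interest.notna()
    contrast = group_of_interest[mask].astype(float)
    sub = npx.subset_samples(contrast.index)
    design = build_design(clinical, contrast)
    fits = fit_linear_models(sub, design)
    de = ebayes_moderate(fits)
    de.lfc, de.alpha = lfc, alpha
    de.table["significant"] = (de.table["coef"].abs() > lfc) & (de.table["p_adj"] < alpha)
    return de
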