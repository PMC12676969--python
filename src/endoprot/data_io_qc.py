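"""NPX and clinical table I/O, coefficient-of-variation QC, and scaling.

Olink panels report relative protein abundance as NPX (Normalized Protein
eXpression), a log2-scale unit. This module reads NPX matrices from wide or
long CSV layouts, applies the marker-variability filter based on the
coefficient of variation (CoV = sd/mean), and z-scales proteins for the
distance- and correlation-based stages downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("endoprot")

VALID_GROUPS = ("AD", "HC")


class FormatError(ValueError):
    """Input file does not conform to the expected CSV layout."""


class IntegrityError(ValueError):
    """Input file parses but violates a data-integrity constraint."""


@dataclass
class NPXMatrix:
    """Samples x proteins expression matrix on the log2 NPX scale.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with one column per protein assay.
    group
        Per-sample label, ``"AD"`` or ``"HC"``, aligned to ``values.index``.
    panel
        Optional per-protein Olink subpanel label (inflammation / oncology /
        neurology / cardiometabolic), aligned to ``values.columns``.
    """

    values: pd.DataFrame
    group: pd.Series
    panel: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise IntegrityError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise IntegrityError("duplicate protein ids")
        self.group = self.group.reindex(self.values.index)
        if self.group.isna().any():
            raise IntegrityError("every sample needs a group label")
        bad = set(self.group.unique()) - set(VALID_GROUPS)
        if bad:
            raise IntegrityError(f"invalid group labels: {sorted(bad)}")
        if self.panel is not None:
            self.panel = self.panel.reindex(self.values.columns)

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, ids) -> "NPXMatrix":
        ids = pd.Index(ids)
        return NPXMatrix(
            self.values.loc[ids],
            self.group.loc[ids],
            self.panel,
        )

    def subset_proteins(self, ids) -> "NPXMatrix":
        ids = pd.Index(ids)
        return NPXMatrix(
            self.values[ids],
            self.group,
            self.panel.loc[ids] if self.panel is not None else None,
        )


@dataclass
class QCReport:
    """Per-protein CoV table and attrition counts for one filter pass."""

    table: pd.DataFrame  # columns: cov_pct, passed
    threshold: float
    scale: str
    mode: str
    n_before: int
    n_after: int
    n_dropped_undefined: int = 0

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="protein")


@dataclass
class ClinicalTable:
    """Clinical/laboratory variables, one row per sample."""

    data: pd.DataFrame
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise IntegrityError("duplicate sample ids in clinical table")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def aligned_to(self, npx: NPXMatrix, strict: bool = False) -> "ClinicalTable":
        """Reorder rows to the NPX sample order; strict mode refuses gaps."""
        missing = npx.sample_ids.difference(self.data.index)
        if strict and len(missing):
            raise IntegrityError(f"clinical table missing samples: {list(missing)[:5]}")
        return ClinicalTable(self.data.reindex(npx.sample_ids), self.units)


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def read_npx(path, layout: str = "wide") -> NPXMatrix:
    """Read an NPX matrix from CSV.

    Wide layout: columns ``SampleID, Group, <assay>, <assay>, ...`` with one
    row per sample. Long layout: columns ``SampleID, Assay, NPX`` plus
    optional ``Panel`` and ``Group``; row order defines sample/protein order
    by first appearance.
    """
    if layout == "wide":
        df = pd.read_csv(path)
        if df.shape[1] < 3 or df.columns[0] != "SampleID" or df.columns[1] != "Group":
            raise FormatError("wide layout requires SampleID, Group, then assay columns")
        if df["SampleID"].duplicated().any():
            raise IntegrityError("duplicate SampleID rows")
        values = df.set_index("SampleID").drop(columns=["Group"]).astype(float)
        group = df.set_index("SampleID")["Group"]
        return NPXMatrix(values, group)
    if layout == "long":
        df = pd.read_csv(path)
        required = {"SampleID", "Assay", "NPX"}
        if not required.issubset(df.columns):
            raise FormatError(f"long layout requires columns {sorted(required)}")
        if df.duplicated(subset=["SampleID", "Assay"]).any():
            dups = df[df.duplicated(subset=["SampleID", "Assay"], keep=False)]
            raise IntegrityError(
                f"duplicate (sample, assay) pairs, e.g. {tuple(dups.iloc[0][['SampleID', 'Assay']])}"
            )
        sample_order = df["SampleID"].drop_duplicates().tolist()
        assay_order = df["Assay"].drop_duplicates().tolist()
        values = (
            df.pivot(index="SampleID", columns="Assay", values="NPX")
            .reindex(index=sample_order, columns=assay_order)
            .astype(float)
        )
        values.index.name = "SampleID"
        if "Group" in df.columns:
            grp = df.drop_duplicates("SampleID").set_index("SampleID")["Group"]
            per_sample = df.groupby("SampleID")["Group"].nunique()
            if (per_sample > 1).any():
                raise IntegrityError("inconsistent Group labels within a sample")
            group = grp.reindex(sample_order)
        else:
            warnings.warn("long NPX file has no Group column; labeling all samples AD")
            group = pd.Series("AD", index=values.index)
        panel = None
        if "Panel" in df.columns:
            panel = (
                df.drop_duplicates("Assay").set_index("Assay")["Panel"].reindex(assay_order)
            )
        return NPXMatrix(values, group, panel)
    raise ValueError(f"unknown layout: {layout!r}")


def write_npx(npx: NPXMatrix, path) -> None:
    """Write the wide CSV layout (SampleID, Group, assays) losslessly."""
    out = npx.values.copy()
    out.insert(0, "Group", npx.group)
    out.to_csv(path, index_label="SampleID")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path)
    if df.columns[0] != "SampleID":
        raise FormatError("clinical CSV must start with a SampleID column")
    return ClinicalTable(df.set_index("SampleID"))


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, index_label="SampleID")


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------

def impute_missing(npx: NPXMatrix, max_missing_frac: float = 0.25) -> NPXMatrix:
    """Drop proteins with too many missing values, median-impute the rest.

    Proteins missing in more than ``max_missing_frac`` of samples are removed;
    remaining gaps are filled with the per-protein median across samples.
    """
    frac = npx.values.isna().mean(axis=0)
    keep = frac[frac <= max_missing_frac].index
    dropped = npx.n_proteins - len(keep)
    if dropped:
        logger.info("impute_missing: dropped %d proteins (>%.0f%% missing)",
                    dropped, 100 * max_missing_frac)
    out = npx.subset_proteins(keep)
    n_imputed = int(out.values.isna().sum().sum())
    if n_imputed:
        logger.info("impute_missing: imputed %d entries by per-protein median", n_imputed)
        out = NPXMatrix(out.values.fillna(out.values.median(axis=0)), out.group, out.panel)
    return out


def cov_filter(
    npx: NPXMatrix,
    threshold: float = 20.0,
    scale: str = "linear",
    mode: str = "keep-above",
) -> tuple[NPXMatrix, QCReport]:
    """Filter proteins by coefficient of variation across all samples.

    CoV% = 100 * sd / mean, computed on the linear scale 2**NPX by default
    (CoV of log-scale values is not scale-invariant) or directly on NPX with
    ``scale="log"``. ``mode="keep-above"`` retains proteins with CoV strictly
    above the threshold (a variability filter); ``keep-below`` retains
    CoV <= threshold (the conventional assay-noise filter).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if npx.n_samples < 2:
        raise ValueError("CoV needs at least 2 samples")
    if scale == "linear":
        x = np.exp2(npx.values)
    elif scale == "log":
        x = npx.values
    else:
        raise ValueError(f"unknown scale: {scale!r}")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    defined = mean != 0
    n_undef = int((~defined).sum())
    if n_undef:
        warnings.warn(f"{n_undef} proteins have zero mean on the {scale} scale; dropped")
    cov = pd.Series(np.nan, index=npx.protein_ids)
    cov[defined] = 100.0 * sd[defined] / mean[defined].abs()
    if mode == "keep-above":
        passed = cov > threshold
    elif mode == "keep-below":
        passed = cov <= threshold
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    passed &= defined
    report = QCReport(
        table=pd.DataFrame({"cov_pct": cov, "passed": passed}),
        threshold=threshold,
        scale=scale,
        mode=mode,
        n_before=npx.n_proteins,
        n_after=int(passed.sum()),
        n_dropped_undefined=n_undef,
    )
    logger.info("cov_filter: %d -> %d proteins (CoV %s %.3g%%, %s scale)",
                report.n_before, report.n_after,
                ">" if mode == "keep-above" else "<=", threshold, scale)
    return npx.subset_proteins(npx.protein_ids[passed]), report


def zscale(npx: NPXMatrix) -> NPXMatrix:
    """Center and scale each protein to mean 0, sd 1 (n-1 denominator).

    Constant proteins map to all-zero columns with a warning.
    """
    if npx.n_samples < 2:
        raise ValueError("zscale needs at least 2 samples")
    sd = npx.values.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant proteins scaled to zeros")
    safe_sd = sd.where(~constant, 1.0)
    out = (npx.values - npx.values.mean(axis=0)) / safe_sd
    out.loc[:, constant] = 0.0
    return NPXMatrix(out, npx.group, npx.panel)


def zscale_values(values: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scaling for a bare DataFrame (helper for network stages)."""
    sd = values.std(axis=0, ddof=1)
    safe_sd = sd.where(sd != 0, 1.0)
    out = (values - values.mean(axis=0)) / safe_sd
    out.loc[:, sd == 0] = 0.0
    return out
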