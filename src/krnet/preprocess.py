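"""Light preprocessing and unsupervised QC for normalized omics matrices.

Input matrices are assumed to be already platform-normalized: log2 expression
for gene/miRNA layers, beta values in [0, 1] for methylation. This module
provides the generic steps that are applied on top of that — quantile
normalization, per-sample median centering, a PCA-based check that the two
phenotype classes separate, and the conventional per-dataset differential
expression baseline (Welch t with Benjamini-Hochberg adjustment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LAYERS = ("gene", "mirna", "methylation")

#: |log2 fold change| threshold of the conventional per-dataset analysis
#: (fold change >= 2 on the natural scale).
DE_LFC_THRESHOLD = 1.0
#: adjusted-p threshold of the conventional per-dataset analysis.
DE_ADJ_P_THRESHOLD = 0.05


@dataclass
class OmicsStudy:
    """One normalized feature x sample matrix with binary class labels.

    Parameters
    ----------
    study_id : str
        Unique identifier of the study (e.g. an accession).
    layer : {"gene", "mirna", "methylation"}
        Omics layer the matrix belongs to.
    matrix : pandas.DataFrame
        Features as rows, samples as columns. Log2 scale for expression
        layers, beta values in [0, 1] for methylation.
    classes : pandas.Series
        Per-sample labels, values in {"normal", "tumor"}, indexed by the
        matrix columns.
    """

    study_id: str
    layer: str
    matrix: pd.DataFrame
    classes: pd.Series

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.matrix.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.matrix.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.classes = self.classes.reindex(self.matrix.columns)
        if self.classes.isna().any():
            raise ValueError("class labels missing for some samples")
        labels = set(self.classes.unique())
        if not labels <= {"normal", "tumor"}:
            raise ValueError(f"unexpected class labels {labels - {'normal', 'tumor'}}")
        if labels != {"normal", "tumor"}:
            raise ValueError("both classes (normal, tumor) must be present")
        if self.layer == "methylation":
            vals = self.matrix.to_numpy()
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise ValueError("methylation beta values must lie in [0, 1]")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def tumor_mask(self) -> np.ndarray:
        return (self.classes == "tumor").to_numpy()

    def n_per_class(self) -> tuple[int, int]:
        """(n_normal, n_tumor)."""
        t = int(self.tumor_mask.sum())
        return len(self.classes) - t, t


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common reference distribution.

    The reference is the row-wise mean of the column-sorted matrix; each
    column's values are replaced by the reference values at their ordinal
    within-column ranks, so every column ends up with an identical sorted
    value vector while within-column order is preserved. The operation is
    idempotent.
    """
    if matrix.size == 0:
        raise ValueError("empty matrix")
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    x = matrix.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("matrix contains non-finite values")
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    rows = np.arange(x.shape[0])
    for j in range(x.shape[1]):
        out[order[:, j], j] = reference[rows]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each column's median so every sample is centered at 0."""
    if matrix.shape[0] == 0:
        raise ValueError("empty column")
    x = matrix.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("matrix contains non-finite values")
    return matrix - np.median(x, axis=0)


@dataclass
class PcaQcResult:
    """PCA scores per sample plus a PC1 class-separation test."""

    scores: pd.DataFrame  # samples x components, columns PC1..PCk
    variance_ratio: np.ndarray
    class_separation_p: float  # Welch t on PC1 scores, tumor vs normal


def pca_qc(study: OmicsStudy, n_components: int = 3) -> PcaQcResult:
    """Project samples onto principal components of the feature space.

    Features are mean-centered before the SVD (no scaling). The PC1 scores
    of the two classes are compared with a two-sided Welch t test; good
    datasets show tumor and normal separating along PC1.
    """
    n_samples = study.matrix.shape[1]
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    max_comp = min(study.matrix.shape) - 1
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds {max_comp}")
    X = study.matrix.to_numpy(dtype=float).T  # samples x features
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    t = study.tumor_mask
    pc1 = scores[:, 0]
    if t.sum() >= 2 and (~t).sum() >= 2:
        p = float(stats.ttest_ind(pc1[t], pc1[~t], equal_var=False).pvalue)
    else:
        p = float("nan")
    df = pd.DataFrame(
        scores,
        index=study.matrix.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return PcaQcResult(scores=df, variance_ratio=pca.explained_variance_ratio_, class_separation_p=p)


@dataclass
class DEResult:
    """Per-feature differential expression (tumor vs normal).

    ``table`` columns: log2fc (tumor - normal mean), t, pvalue, qvalue
    (Benjamini-Hochberg), untestable, significant.
    """

    study_id: str
    table: pd.DataFrame
    lfc_threshold: float = DE_LFC_THRESHOLD
    adj_p_threshold: float = DE_ADJ_P_THRESHOLD

    @property
    def significant_features(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def differential_expression(
    study: OmicsStudy,
    lfc_threshold: float = DE_LFC_THRESHOLD,
    adj_p_threshold: float = DE_ADJ_P_THRESHOLD,
) -> DEResult:
    """Welch t test per feature with BH adjustment — the per-dataset baseline.

    Features with zero variance in both classes and zero mean difference are
    flagged untestable with p = 1 by convention. The significance flag
    requires |log2FC| >= ``lfc_threshold`` and adjusted p < ``adj_p_threshold``.
    """
    t_mask = study.tumor_mask
    if t_mask.sum() < 2 or (~t_mask).sum() < 2:
        raise ValueError("each class needs >= 2 samples")
    x = study.matrix.to_numpy(dtype=float)
    tum, nor = x[:, t_mask], x[:, ~t_mask]
    log2fc = tum.mean(axis=1) - nor.mean(axis=1)
    res = stats.ttest_ind(tum, nor, axis=1, equal_var=False)
    tstat = np.asarray(res.statistic, dtype=float)
    pval = np.asarray(res.pvalue, dtype=float)

    var0 = (tum.var(axis=1) == 0) & (nor.var(axis=1) == 0)
    untestable = var0 & (log2fc == 0)
    tstat[untestable] = 0.0
    pval[untestable] = 1.0
    degenerate_shift = var0 & (log2fc != 0)  # distinct constants: infinitely strong evidence
    tstat[degenerate_shift] = np.sign(log2fc[degenerate_shift]) * np.inf
    pval[degenerate_shift] = 0.0
    pval = np.nan_to_num(pval, nan=1.0)

    qval = multipletests(pval, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": tstat,
            "pvalue": pval,
            "qvalue": qval,
            "untestable": untestable,
        },
        index=study.matrix.index,
    )
    table["significant"] = (
        (np.abs(table["log2fc"]) >= lfc_threshold)
        & (table["qvalue"] < adj_p_threshold)
        & ~table["untestable"]
    )
    logger.info(
        "DE %s: %d/%d significant at |log2FC|>=%g, adj p<%g",
        study.study_id, int(table["significant"].sum()), len(table), lfc_threshold, adj_p_threshold,
    )
    return DEResult(study_id=study.study_id, table=table,
                    lfc_threshold=lfc_threshold, adj_p_threshold=adj_p_threshold)
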