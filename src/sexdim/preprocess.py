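"""Normalization, noise filtering and PCA-based exploration of expression data.

The preprocessing chain for bulk immune RNA-seq here is: floor linear
expression at 1 and log2-transform, drop genes that never clear a noise
threshold in enough samples, then z-score per gene before PCA. Raw-count
inputs are first normalized by the median-of-ratios method. Quantile
normalization and median polish serve the ATAC and microarray summarization
paths respectively.

The sample standard deviation (n-1 denominator) is used everywhere; see
:data:`SD_DDOF`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from sexdim.io_formats import ExpressionMatrix, SampleMetadata, ValidationError
from sexdim.differential import bh_adjust, build_pairing

__all__ = [
    "SD_DDOF",
    "NoiseFilterSpec",
    "PcaResult",
    "floor_log_transform",
    "noise_filter",
    "zscore_normalize",
    "median_of_ratios_normalize",
    "quantile_normalize",
    "median_polish",
    "pca_decompose",
    "contributing_genes",
    "first_sex_separating_pc",
]

#: Degrees-of-freedom correction for every standard deviation in the package.
SD_DDOF = 1


@dataclass(frozen=True)
class NoiseFilterSpec:
    """Noise-filter parameters: keep genes with log2 expression strictly
    above ``threshold`` in at least ``min_samples`` samples.

    Typical values: threshold 5 or 6 log2 units, min_samples equal to the
    size of the smallest comparison group (e.g. 6 or 2).
    """

    threshold: float
    min_samples: int

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValidationError("noise threshold must be >= 0")
        if self.min_samples < 1:
            raise ValidationError("min_samples must be >= 1")


@dataclass
class PcaResult:
    """Sample-wise PCA of a gene-standardized matrix.

    scores: samples x components; coefficients: genes x components with
    unit column norm; variance_explained: fraction per component,
    non-increasing. Component signs are fixed so the largest-magnitude
    gene coefficient of each component is positive.
    """

    scores: pd.DataFrame
    coefficients: pd.DataFrame
    variance_explained: np.ndarray


def floor_log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace linear values below 1 with 1, then log2-transform."""
    if matrix.scale != "linear":
        raise ValidationError(f"floor_log_transform expects linear scale, got {matrix.scale!r}")
    values = matrix.values.to_numpy()
    if values.size and values.min() < 0:
        raise ValidationError("negative expression values")
    out = pd.DataFrame(
        np.log2(np.maximum(values, 1.0)), index=matrix.values.index, columns=matrix.values.columns
    )
    return ExpressionMatrix(
        out, scale="log2", gene_symbols=matrix.gene_symbols, gene_chromosome=matrix.gene_chromosome
    )


def noise_filter(
    matrix: ExpressionMatrix, spec: NoiseFilterSpec
) -> tuple[ExpressionMatrix, list[str]]:
    """Keep genes expressed strictly above the threshold in enough samples.

    Returns the filtered matrix (gene order preserved) and the dropped ids.
    """
    if matrix.scale != "log2":
        raise ValidationError("noise_filter expects log2-scale values")
    above = (matrix.values.to_numpy() > spec.threshold).sum(axis=1)
    keep = above >= spec.min_samples
    kept = [g for g, k in zip(matrix.gene_ids, keep) if k]
    dropped = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    return matrix.subset_genes(kept), dropped


def zscore_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene and scale to unit sample SD."""
    values = matrix.values.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=SD_DDOF)
    zero = sd == 0
    if zero.any():
        names = [g for g, z in zip(matrix.gene_ids, zero) if z][:10]
        raise ValidationError(f"zero-variance genes cannot be z-scored: {names}")
    out = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        scale="log2",
        gene_symbols=matrix.gene_symbols,
        gene_chromosome=matrix.gene_chromosome,
    )


def median_of_ratios_normalize(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, pd.Series]:
    """DESeq2-style median-of-ratios normalization of a raw-count matrix.

    Size factor for sample j is the median over all-sample-expressed genes
    of count_gj divided by the gene's geometric mean across samples.
    """
    if matrix.scale != "counts":
        raise ValidationError("median_of_ratios expects raw counts")
    counts = matrix.values.to_numpy(dtype=float)
    expressed = (counts > 0).all(axis=1)
    if not expressed.any():
        raise ValidationError("no gene has nonzero counts in every sample")
    ref = counts[expressed]
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(ref) - log_geomean, axis=0))
    normalized = counts / factors
    out = ExpressionMatrix(
        pd.DataFrame(normalized, index=matrix.values.index, columns=matrix.values.columns),
        scale="linear",
        gene_symbols=matrix.gene_symbols,
        gene_chromosome=matrix.gene_chromosome,
    )
    return out, pd.Series(factors, index=matrix.values.columns, name="size_factor")


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean sorted profile across columns.

    Ties within a column receive the mean of the reference values their
    ranks span (the classic limma/``normalize.quantiles`` behavior).
    """
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("quantile normalization requires finite values")
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, arr.shape[0] + 1), reference)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def median_polish(
    values: np.ndarray, max_iter: int = 10, tol: float = 1e-6
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey's median polish of a two-way table, rows swept first.

    Returns (overall, row_effects, col_effects, residuals) satisfying the
    exact decomposition ``values = overall + row + col + residuals``.
    Iteration stops when the largest sweep adjustment falls below ``tol``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("median_polish needs a matrix of at least 2x2")
    residuals = arr.copy()
    overall = 0.0
    row_eff = np.zeros(arr.shape[0])
    col_eff = np.zeros(arr.shape[1])
    for _ in range(max_iter):
        row_med = np.median(residuals, axis=1)
        residuals -= row_med[:, None]
        row_eff += row_med
        col_med_of_rows = np.median(row_eff)
        row_eff -= col_med_of_rows
        overall += col_med_of_rows

        col_med = np.median(residuals, axis=0)
        residuals -= col_med[None, :]
        col_eff += col_med
        row_med_of_cols = np.median(col_eff)
        col_eff -= row_med_of_cols
        overall += row_med_of_cols

        delta = max(np.abs(row_med).max(), np.abs(col_med).max())
        if delta < tol:
            break
    return overall, row_eff, col_eff, residuals


def pca_decompose(matrix: ExpressionMatrix, n_components: int | None = None) -> PcaResult:
    """Sample-wise PCA of a z-normalized genes x samples matrix.

    Samples are observations, genes are variables. Signs are fixed so that
    the largest-|coefficient| gene of each component loads positively.
    """
    X = matrix.values.to_numpy(dtype=float).T  # samples x genes
    n_max = min(X.shape[0] - 1, X.shape[1]) if X.shape[0] > 1 else 1
    if n_components is None:
        n_components = n_max
    if n_components > min(X.shape):
        raise ValidationError(
            f"n_components={n_components} exceeds min(genes, samples)={min(X.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    coeffs = pca.components_.T  # genes x components
    # deterministic sign: largest-magnitude loading positive
    flip = np.sign(coeffs[np.abs(coeffs).argmax(axis=0), np.arange(coeffs.shape[1])])
    flip[flip == 0] = 1.0
    scores = scores * flip
    coeffs = coeffs * flip
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=comp_names),
        coefficients=pd.DataFrame(coeffs, index=matrix.gene_ids, columns=comp_names),
        variance_explained=pca.explained_variance_ratio_,
    )


def contributing_genes(
    pca: PcaResult, component: int, threshold: float = 0.05
) -> list[str]:
    """Genes whose |coefficient| on a component exceeds the threshold,
    sorted by decreasing |coefficient|."""
    coeffs = pca.coefficients.iloc[:, component]
    selected = coeffs[coeffs.abs() > threshold]
    return selected.abs().sort_values(ascending=False).index.tolist()


def first_sex_separating_pc(
    pca: PcaResult,
    metadata: SampleMetadata,
    blocking_keys: tuple[str, ...] = ("cell_type", "dataset"),
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[int | None, pd.Series]:
    """First principal component whose scores separate the sexes.

    Each component's female and male scores are compared with a paired
    two-sided t-test (samples paired on the blocking keys), and p-values
    are BH-adjusted across the components tested. Returns the smallest
    0-based component index with pFDR below ``alpha`` (None if no
    component passes) plus the full pFDR vector.
    """
    design = build_pairing(metadata, blocking_keys, seed=seed)
    if not design.pairs:
        raise ValidationError("no complete female/male pair under the blocking keys")
    f_ids = [f for f, _ in design.pairs]
    m_ids = [m for _, m in design.pairs]
    f_scores = pca.scores.loc[f_ids].to_numpy()
    m_scores = pca.scores.loc[m_ids].to_numpy()
    res = stats.ttest_rel(f_scores, m_scores, axis=0)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    pfdr = bh_adjust(pvals)
    passing = np.flatnonzero(pfdr < alpha)
    index = int(passing[0]) if passing.size else None
    return index, pd.Series(pfdr, index=pca.scores.columns, name="pFDR")
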