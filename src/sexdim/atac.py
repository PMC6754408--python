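"""Differential chromatin accessibility between sexes.

ATAC-seq log2 accessibility has strongly intensity-dependent noise: dim
open chromatin regions (OCRs) fluctuate far more between replicates than
bright ones, so a single global variance misstates significance at both
ends of the intensity range. The adjusted test implemented here scores
each OCR's female-minus-male difference against the spread of differences
among OCRs of similar overall intensity: a one-log2-unit window around the
OCR's mean intensity supplies a local null scale estimated by the median
absolute deviation (MAD, converted to an SD with the normal-consistency
factor 1.4826), assuming most OCRs are not differential. The resulting
z-scores are referred to the standard normal and BH-adjusted.

A differential OCR (DO) is one with pFDR < 0.05 and a fold change above
2-fold, partitioned by annotation class (TSS / gene body / distal
enhancer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sexdim.io_formats import OcrTable, SampleMetadata, ValidationError
from sexdim.differential import bh_adjust
from sexdim.resampling import GroupLabelShuffle, permutation_pvalue

__all__ = [
    "MAD_TO_SD",
    "DOResult",
    "mad_adjusted_test",
    "global_mad_test",
    "call_dos",
    "genebody_fc_comparison",
]

#: Normal-consistency factor converting a MAD into an SD estimate.
MAD_TO_SD = 1.4826


@dataclass
class DOResult:
    """Per-OCR adjusted-test summary.

    ``table`` columns: mean_F, mean_M, log2fc, window_mean, window_size,
    sigma, z, p, pFDR, is_DO, expanded_window, global_fallback,
    annotation_class, associated_gene.
    """

    table: pd.DataFrame
    window_width: float
    min_window: int

    def dos(self) -> pd.DataFrame:
        return self.table[self.table["is_DO"]]


def _sex_means(ocr: OcrTable, metadata: SampleMetadata) -> tuple[np.ndarray, np.ndarray]:
    meta = metadata.subset(ocr.sample_ids).table
    f_ids = meta.index[meta["sex"] == "F"]
    m_ids = meta.index[meta["sex"] == "M"]
    if len(f_ids) == 0 or len(m_ids) == 0:
        raise ValidationError("both sexes must be present")
    return (
        ocr.values[f_ids].mean(axis=1).to_numpy(),
        ocr.values[m_ids].mean(axis=1).to_numpy(),
    )


def mad_adjusted_test(
    ocr: OcrTable,
    metadata: SampleMetadata,
    window_width: float = 1.0,
    min_window: int = 50,
    alpha: float = 0.05,
    fc_fold: float = 2.0,
) -> DOResult:
    """Intensity-windowed MAD-adjusted z-test of female-minus-male differences.

    For OCR i with overall mean intensity m_i, the window holds every
    other OCR j with |m_j - m_i| <= window_width / 2 (the focal OCR is
    left out so its own difference cannot inflate its null scale);
    windows smaller than ``min_window`` are expanded symmetrically to the
    nearest OCRs in intensity and flagged. sigma_i = 1.4826 x MAD of the
    window's differences; z_i = d_i / sigma_i; two-sided normal p; BH
    across OCRs. A zero window MAD falls back to the global MAD
    (flagged); a zero global MAD is an error.
    """
    if len(ocr.ocr_ids) < min_window + 1:
        raise ValidationError(f"need more than min_window={min_window} OCRs")
    mean_f, mean_m = _sex_means(ocr, metadata)
    d = mean_f - mean_m
    m = ocr.values.mean(axis=1).to_numpy()

    order = np.argsort(m, kind="stable")
    m_sorted = m[order]
    d_sorted = d[order]
    n = m.size
    half = window_width / 2.0

    global_med = np.median(d)
    global_mad = np.median(np.abs(d - global_med))
    if global_mad == 0:
        raise ValidationError("global MAD of sex differences is zero")

    lo_all = np.searchsorted(m_sorted, m_sorted - half, side="left")
    hi_all = np.searchsorted(m_sorted, m_sorted + half, side="right")

    sigma = np.empty(n)
    win_size = np.empty(n, dtype=int)
    win_mean = np.empty(n)
    expanded = np.zeros(n, dtype=bool)
    fallback = np.zeros(n, dtype=bool)
    for k in range(n):
        lo, hi = int(lo_all[k]), int(hi_all[k])
        if hi - lo - 1 < min_window:
            expanded[k] = True
            while hi - lo - 1 < min_window and (lo > 0 or hi < n):
                left_gap = m_sorted[k] - m_sorted[lo - 1] if lo > 0 else np.inf
                right_gap = m_sorted[hi] - m_sorted[k] if hi < n else np.inf
                if left_gap <= right_gap:
                    lo -= 1
                else:
                    hi += 1
        window = np.concatenate([d_sorted[lo:k], d_sorted[k + 1 : hi]])
        med = np.median(window)
        mad = np.median(np.abs(window - med))
        if mad == 0:
            fallback[k] = True
            mad = global_mad
        sigma[k] = MAD_TO_SD * mad
        win_size[k] = hi - lo - 1
        win_mean[k] = m_sorted[lo:hi].mean()

    # back to original OCR order
    inverse = np.empty(n, dtype=int)
    inverse[order] = np.arange(n)
    sigma = sigma[inverse]
    win_size = win_size[inverse]
    win_mean = win_mean[inverse]
    expanded = expanded[inverse]
    fallback = fallback[inverse]

    z = d / sigma
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "mean_F": mean_f,
            "mean_M": mean_m,
            "log2fc": d,
            "window_mean": win_mean,
            "window_size": win_size,
            "sigma": sigma,
            "z": z,
            "p": p,
            "pFDR": bh_adjust(p),
            "expanded_window": expanded,
            "global_fallback": fallback,
            "annotation_class": ocr.annotation["annotation_class"].to_numpy(),
            "associated_gene": ocr.annotation["associated_gene"].to_numpy(),
        },
        index=ocr.annotation.index,
    )
    table["is_DO"] = (table["pFDR"] < alpha) & (table["log2fc"].abs() > np.log2(fc_fold))
    return DOResult(table, window_width=window_width, min_window=min_window)


def global_mad_test(ocr: OcrTable, metadata: SampleMetadata) -> pd.DataFrame:
    """Ordinary z-test with a single global MAD-derived scale.

    The unadjusted comparator for the windowed test: it ignores the
    intensity dependence of the variance.
    """
    mean_f, mean_m = _sex_means(ocr, metadata)
    d = mean_f - mean_m
    mad = np.median(np.abs(d - np.median(d)))
    if mad == 0:
        raise ValidationError("global MAD of sex differences is zero")
    z = d / (MAD_TO_SD * mad)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"log2fc": d, "z": z, "p": p, "pFDR": bh_adjust(p)}, index=ocr.annotation.index
    )


def call_dos(
    result: DOResult, alpha: float = 0.05, fc_fold: float = 2.0
) -> dict[str, dict[str, object]]:
    """Partition DOs by annotation class and sex direction.

    Returns, per annotation class, the female- and male-higher DO ids and
    the count of unique associated genes.
    """
    table = result.table
    is_do = (table["pFDR"] < alpha) & (table["log2fc"].abs() > np.log2(fc_fold))
    out: dict[str, dict[str, object]] = {}
    for cls, sub in table[is_do].groupby("annotation_class"):
        genes = sub.loc[sub["associated_gene"] != "", "associated_gene"].unique()
        out[str(cls)] = {
            "female": sub.index[sub["log2fc"] > 0].tolist(),
            "male": sub.index[sub["log2fc"] < 0].tolist(),
            "n_unique_genes": int(len(genes)),
        }
    return out


def genebody_fc_comparison(
    ocr: OcrTable,
    metadata: SampleMetadata,
    female_sdegs,
    male_sdegs,
    B: int = 1000,
    seed: int = 0,
) -> dict[str, object]:
    """Compare gene-body accessibility fold changes of SDEGs vs other genes.

    Gene-body OCR log2 fold changes are averaged per associated gene;
    each SDEG list's distribution is tested against the remaining genes
    with a Welch t plus a gene-label permutation p.
    """
    female_sdegs, male_sdegs = list(female_sdegs), list(male_sdegs)
    if not female_sdegs and not male_sdegs:
        raise ValidationError("both SDEG lists are empty; nothing to compare")
    body = ocr.subset_class("gene_body")
    if not body.ocr_ids:
        raise ValidationError("no gene_body OCRs in the table")
    mean_f, mean_m = _sex_means(body, metadata)
    fc = pd.Series(mean_f - mean_m, index=body.annotation.index)
    per_gene = fc.groupby(body.annotation["associated_gene"]).mean()
    per_gene = per_gene[per_gene.index != ""]

    out: dict[str, object] = {"per_gene_fc": per_gene}
    for label, sdegs in (("female", female_sdegs), ("male", male_sdegs)):
        group = [g for g in sdegs if g in per_gene.index]
        rest = per_gene.index.difference(group)
        if len(group) < 2 or len(rest) < 2:
            out[label] = None
            continue
        a = per_gene.loc[group].to_numpy()
        b = per_gene.loc[rest].to_numpy()
        t_obs, p_obs = _safe_welch(a, b)
        values = np.concatenate([a, b])

        def welch_t(data: np.ndarray, mask: np.ndarray) -> float:
            return _safe_welch(data[mask], data[~mask])[0]

        perm = permutation_pvalue(
            welch_t,
            values,
            GroupLabelShuffle(values.size, len(group)),
            B=B,
            seed=seed,
            tail="two",
            exhaustive=False,
        )
        out[label] = {
            "n": len(group),
            "t": t_obs,
            "p": p_obs,
            "perm_p": perm.p,
        }
    return out


def _safe_welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t with deterministic handling of zero-variance degeneracy."""
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), float(np.nextafter(0.0, 1.0))
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
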