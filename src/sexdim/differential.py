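"""Sex-biased differential-expression machinery.

The core design pairs each female sample with a male sample matched on
blocking factors (cell type, dataset, age group), tests each gene with a
classical paired t-test on the within-pair log2 differences, adjusts with
Benjamini-Hochberg, and calls a gene sexually differentially expressed
(SDEG) when pFDR < 0.2 and the female-minus-male fold change exceeds
1.5-fold. An unpaired (Welch) variant serves designs without natural
pairing, e.g. interferon-stimulation contrasts with stricter cutoffs
(pFDR < 0.05, two-fold). A two-factor ANOVA with interaction extends the
sex test across tissues (sex, tissue, sex x tissue).

Fold changes are differences of group means on the log2 scale, i.e. log2
ratios of geometric means, reported female minus male.

Degenerate zero-variance genes never propagate NaN: they are flagged and
given p = 1 when the group means agree, or the smallest positive float
when the means differ but there is no residual variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from sexdim.io_formats import ExpressionMatrix, SampleMetadata, ValidationError

__all__ = [
    "PairedDesign",
    "DEResult",
    "AnovaResult",
    "build_pairing",
    "paired_ttest",
    "unpaired_ttest",
    "bh_adjust",
    "call_sdegs",
    "two_way_anova",
    "call_tissue_genes",
]

#: Smallest positive float, reported when a difference is exact (no residual
#: variance) so that downstream FDR vectors stay complete.
_P_MIN = np.nextafter(0.0, 1.0)


@dataclass
class PairedDesign:
    """Ordered (female, male) sample pairs matched on blocking keys."""

    pairs: list[tuple[str, str]]
    blocking_keys: tuple[str, ...]
    seed: int
    unpaired: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f, m in self.pairs:
            if f in seen or m in seen:
                raise ValidationError("a sample appears in more than one pair")
            seen.update((f, m))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class DEResult:
    """Per-gene differential-expression summary.

    ``table`` columns: mean_F, mean_M, log2fc (F-M), t, p, pFDR,
    degenerate, called.
    """

    table: pd.DataFrame
    design: str = ""

    def called_genes(self) -> list[str]:
        return self.table.index[self.table["called"]].tolist()


@dataclass
class AnovaResult:
    """Per-gene two-way ANOVA summary.

    ``table`` columns: p_sex, p_tissue, p_interaction, pfdr_sex,
    pfdr_tissue, pfdr_interaction, and one ``fc_<tissue>`` column per
    tissue holding the tissue-stratified female-minus-male log2 fold
    change.
    """

    table: pd.DataFrame
    tissues: list[str]


def build_pairing(
    metadata: SampleMetadata, blocking_keys, seed: int = 0
) -> PairedDesign:
    """Pair female with male samples within blocking-key strata.

    Within each stratum, replicates are matched uniformly at random
    (driven by ``seed``); surplus samples of either sex are reported
    unpaired and excluded. A stratum with only one sex contributes no
    pairs.
    """
    blocking_keys = tuple(blocking_keys)
    missing = [k for k in blocking_keys if k not in metadata.table.columns]
    if missing:
        raise ValidationError(f"metadata lacks blocking keys: {missing}")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    unpaired: list[str] = []
    table = metadata.table
    groups = table.groupby(list(blocking_keys), sort=True) if blocking_keys else [((), table)]
    for _, stratum in groups:
        females = stratum.index[stratum["sex"] == "F"].tolist()
        males = stratum.index[stratum["sex"] == "M"].tolist()
        rng.shuffle(females)
        rng.shuffle(males)
        k = min(len(females), len(males))
        pairs.extend(zip(females[:k], males[:k]))
        unpaired.extend(females[k:])
        unpaired.extend(males[k:])
    return PairedDesign(pairs=pairs, blocking_keys=blocking_keys, seed=seed, unpaired=unpaired)


def _degenerate_fill(log2fc: np.ndarray, degenerate: np.ndarray, t: np.ndarray, p: np.ndarray):
    """Replace NaN/inf statistics of zero-variance genes deterministically."""
    zero_diff = degenerate & (log2fc == 0)
    exact_diff = degenerate & (log2fc != 0)
    t[zero_diff] = 0.0
    p[zero_diff] = 1.0
    t[exact_diff] = np.sign(log2fc[exact_diff]) * np.inf
    p[exact_diff] = _P_MIN
    return t, p


def paired_ttest(matrix: ExpressionMatrix, design: PairedDesign) -> DEResult:
    """Two-sided paired t-test per gene on within-pair F-M differences."""
    if design.n_pairs < 2:
        raise ValidationError("paired t-test needs at least 2 pairs")
    f_ids = [f for f, _ in design.pairs]
    m_ids = [m for _, m in design.pairs]
    values = matrix.values
    missing = [s for s in f_ids + m_ids if s not in values.columns]
    if missing:
        raise ValidationError(f"pair members missing from matrix: {missing}")
    F = values[f_ids].to_numpy(dtype=float)
    M = values[m_ids].to_numpy(dtype=float)
    diffs = F - M
    n = diffs.shape[1]
    mean_d = diffs.mean(axis=1)
    sd_d = diffs.std(axis=1, ddof=1)
    degenerate = sd_d == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd_d / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    t, p = _degenerate_fill(mean_d, degenerate, t, p)
    table = pd.DataFrame(
        {
            "mean_F": F.mean(axis=1),
            "mean_M": M.mean(axis=1),
            "log2fc": mean_d,
            "t": t,
            "p": p,
            "pFDR": bh_adjust(p),
            "degenerate": degenerate,
            "called": False,
        },
        index=values.index,
    )
    return DEResult(table, design="paired")


def unpaired_ttest(
    matrix: ExpressionMatrix,
    group_a,
    group_b,
    equal_var: bool = False,
) -> DEResult:
    """Two-sided two-sample t-test per gene; Welch by default.

    ``log2fc`` is mean(group_a) - mean(group_b); with group_a the female
    samples this is the female-minus-male fold change.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    A = matrix.values[group_a].to_numpy(dtype=float)
    B = matrix.values[group_b].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(A, B, axis=1, equal_var=equal_var)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    log2fc = mean_a - mean_b
    degenerate = (A.std(axis=1) == 0) & (B.std(axis=1) == 0)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    t, p = _degenerate_fill(log2fc, degenerate, t, p)
    table = pd.DataFrame(
        {
            "mean_F": mean_a,
            "mean_M": mean_b,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "pFDR": bh_adjust(p),
            "degenerate": degenerate,
            "called": False,
        },
        index=matrix.values.index,
    )
    return DEResult(table, design="unpaired")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_sdegs(
    de: DEResult, alpha: float = 0.2, fc_fold: float = 1.5
) -> tuple[list[str], list[str]]:
    """Call SDEGs: pFDR < alpha and |log2fc| > log2(fc_fold) (both strict).

    Returns (female-higher genes, male-higher genes) and sets the
    ``called`` flag on the result table in place.
    """
    lfc_cut = np.log2(fc_fold)
    table = de.table
    called = (table["pFDR"] < alpha) & (table["log2fc"].abs() > lfc_cut)
    table["called"] = called
    female = table.index[called & (table["log2fc"] > 0)].tolist()
    male = table.index[called & (table["log2fc"] < 0)].tolist()
    return female, male


def _sum_coded_design(sex: np.ndarray, tissue: np.ndarray, tissues: list[str]):
    """Sum-to-zero coded design matrix blocks for sex, tissue, interaction."""
    n = sex.shape[0]
    s = np.where(sex == "F", 1.0, -1.0)[:, None]
    k = len(tissues)
    T = np.zeros((n, k - 1))
    for i, level in enumerate(tissues[:-1]):
        T[tissue == level, i] = 1.0
    T[tissue == tissues[-1], :] = -1.0
    inter = s * T
    intercept = np.ones((n, 1))
    return intercept, s, T, inter


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares per column of Y after projecting onto X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return np.einsum("ij,ij->j", resid, resid)


def two_way_anova(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    tissue_key: str = "tissue",
    ss_type: int = 3,
) -> AnovaResult:
    """Per-gene two-factor ANOVA with interaction: sex, tissue, sex x tissue.

    Type III sums of squares with sum-to-zero contrasts by default (robust
    to unbalanced replicate counts); Type II via ``ss_type=2``. BH
    adjustment is applied per effect across genes. Per-tissue female-minus-
    male log2 fold changes come from tissue-stratified group means.
    """
    meta = metadata.subset(matrix.sample_ids).table
    if tissue_key not in meta.columns:
        raise ValidationError(f"metadata lacks factor column {tissue_key!r}")
    sex = meta["sex"].to_numpy()
    tissue = meta[tissue_key].astype(str).to_numpy()
    tissues = sorted(pd.unique(tissue))
    if len(tissues) < 2:
        raise ValidationError("two-way ANOVA needs at least 2 tissues")
    empty = [
        (s, t)
        for s in ("F", "M")
        for t in tissues
        if not ((sex == s) & (tissue == t)).any()
    ]
    if empty:
        raise ValidationError(f"empty (sex, tissue) cells: {empty}")

    Y = matrix.values.to_numpy(dtype=float).T  # samples x genes
    intercept, S, T, I = _sum_coded_design(sex, tissue, tissues)
    full = np.hstack([intercept, S, T, I])
    df_resid = Y.shape[0] - full.shape[1]
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom")
    rss_full = _rss(full, Y)

    if ss_type == 3:
        reduced = {
            "sex": np.hstack([intercept, T, I]),
            "tissue": np.hstack([intercept, S, I]),
            "interaction": np.hstack([intercept, S, T]),
        }
    elif ss_type == 2:
        reduced = {
            "sex": (np.hstack([intercept, T]), np.hstack([intercept, S, T])),
            "tissue": (np.hstack([intercept, S]), np.hstack([intercept, S, T])),
            "interaction": (np.hstack([intercept, S, T]), full),
        }
    else:
        raise ValidationError("ss_type must be 2 or 3")

    df_effect = {"sex": 1, "tissue": len(tissues) - 1, "interaction": len(tissues) - 1}
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for effect, design in reduced.items():
            if ss_type == 3:
                extra = _rss(design, Y) - rss_full
                denom = rss_full
            else:
                small, big = design
                extra = _rss(small, Y) - _rss(big, Y)
                denom = rss_full
            F = (extra / df_effect[effect]) / (denom / df_resid)
            p = stats.f.sf(F, df_effect[effect], df_resid)
            out[f"p_{effect}"] = np.where(np.isnan(p), 1.0, p)
    table = pd.DataFrame(out, index=matrix.values.index)
    for effect in ("sex", "tissue", "interaction"):
        table[f"pfdr_{effect}"] = bh_adjust(table[f"p_{effect}"].to_numpy())
    for t in tissues:
        f_cols = meta.index[(sex == "F") & (tissue == t)]
        m_cols = meta.index[(sex == "M") & (tissue == t)]
        table[f"fc_{t}"] = (
            matrix.values[f_cols].mean(axis=1) - matrix.values[m_cols].mean(axis=1)
        )
    return AnovaResult(table, tissues=tissues)


def call_tissue_genes(
    anova: AnovaResult,
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    alpha: float = 0.2,
    fc_fold: float = 1.5,
    expr_threshold: float = 5.0,
    tissue_key: str = "tissue",
    expression_rule: str = "all_one_sex",
) -> tuple[list[str], dict[str, list[str]]]:
    """Call overall sex-effect genes and per-tissue interaction genes.

    A sex-effect gene has interaction-free evidence in every tissue:
    pfdr_sex < alpha, and |fold change| > log2(fc_fold) with a consistent
    sign in ALL tissues. An interaction gene for tissue T has
    pfdr_interaction < alpha, |fold change in T| > log2(fc_fold), and
    clears the expression gate in T.

    ``expression_rule`` selects the gate: ``all_one_sex`` requires
    expression above ``expr_threshold`` in every female or every male
    sample of the tissue; ``two_samples`` requires it in at least two
    samples of the tissue.
    """
    lfc_cut = np.log2(fc_fold)
    table = anova.table
    fc_cols = [f"fc_{t}" for t in anova.tissues]
    fc = table[fc_cols].to_numpy()

    sig_sex = table["pfdr_sex"].to_numpy() < alpha
    big_all = (np.abs(fc) > lfc_cut).all(axis=1)
    consistent = (fc > 0).all(axis=1) | (fc < 0).all(axis=1)
    sex_genes = table.index[sig_sex & big_all & consistent].tolist()

    meta = metadata.subset(matrix.sample_ids).table
    sig_inter = table["pfdr_interaction"].to_numpy() < alpha
    interaction: dict[str, list[str]] = {}
    for j, t in enumerate(anova.tissues):
        in_t = meta[tissue_key].astype(str) == t
        f_cols = meta.index[in_t & (meta["sex"] == "F")]
        m_cols = meta.index[in_t & (meta["sex"] == "M")]
        expr = matrix.values[list(f_cols) + list(m_cols)]
        if expression_rule == "all_one_sex":
            gate = (matrix.values[f_cols] > expr_threshold).all(axis=1) | (
                matrix.values[m_cols] > expr_threshold
            ).all(axis=1)
        elif expression_rule == "two_samples":
            gate = (expr > expr_threshold).sum(axis=1) >= 2
        else:
            raise ValidationError("expression_rule must be 'all_one_sex' or 'two_samples'")
        called = sig_inter & (np.abs(fc[:, j]) > lfc_cut) & gate.to_numpy()
        interaction[t] = table.index[called].tolist()
    return sex_genes, interaction
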