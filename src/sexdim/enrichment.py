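"""Gene-set enrichment: pre-ranked GSEA and hypergeometric over-representation.

The pre-ranked test scores a gene set against a list ranked by a per-gene
statistic (here the paired t statistic of the female-male comparison) with
the weighted Kolmogorov-Smirnov running sum: each hit advances the walk by
|score|^p normalized over hits, each miss retreats by 1/(N - N_hits); the
enrichment score (ES) is the signed maximum deviation from zero. Nulls come
from random gene sets of matching size drawn from the ranked universe, the
normalized ES (NES) divides by the mean same-sign null magnitude, and the
FDR q follows the original sign-stratified pooling scheme.

Over-representation of a called gene list in a pathway uses the upper-tail
hypergeometric probability against a fixed expressed-gene background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from sexdim.io_formats import GeneSetCollection, ValidationError

__all__ = [
    "GseaResult",
    "enrichment_score",
    "gsea_preranked",
    "hypergeom_overlap",
    "hypergeom_overlap_counts",
]


@dataclass
class GseaResult:
    """Per-set enrichment summary.

    ``table`` columns: size, ES, NES, p, q, significant; ``leading_edges``
    maps set name to its leading-edge gene list; ``excluded`` maps skipped
    sets to the reason (size limits or empty intersection).
    """

    table: pd.DataFrame
    leading_edges: dict[str, list[str]] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)


def enrichment_score(
    ranked_genes,
    scores,
    gene_set,
    weight: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score of a gene set on a ranked list.

    ``ranked_genes``/``scores`` must be sorted by score descending. Returns
    (ES, running sum over positions, leading-edge genes).
    """
    genes = list(ranked_genes)
    scores = np.asarray(scores, dtype=float)
    if len(genes) != scores.size:
        raise ValidationError("ranked_genes and scores must align")
    if np.any(np.diff(scores) > 1e-12):
        raise ValidationError("ranked list must be sorted by score descending")
    hit = np.isin(genes, list(gene_set))
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValidationError("gene set does not intersect the ranked list")
    if n_hits == len(genes):
        raise ValidationError("gene set covers the whole ranked list")
    weighted = np.abs(scores) ** weight
    hit_weights = np.where(hit, weighted, 0.0)
    total = hit_weights.sum()
    if total == 0:  # all hit scores are exactly zero: fall back to unweighted
        hit_weights = hit.astype(float)
        total = hit_weights.sum()
    steps = hit_weights / total - (~hit) / (len(genes) - n_hits)
    running = np.cumsum(steps)
    # earliest peak wins; magnitude ties within 1e-9 count as equal
    magnitude = np.abs(running)
    peak = int(np.argmax(magnitude > magnitude.max() - 1e-9))
    es = float(running[peak])
    if es >= 0:
        leading = [g for g, h in zip(genes[: peak + 1], hit[: peak + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[peak:], hit[peak:]) if h]
    return es, running, leading


def gsea_preranked(
    ranked_genes,
    scores,
    collection: GeneSetCollection,
    weight: float = 1.0,
    B: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 500,
    q_threshold: float = 0.25,
    fdr_scheme: str = "gsea",
) -> GseaResult:
    """Pre-ranked GSEA over a gene-set collection.

    The null for each set is B random same-size gene sets drawn from the
    ranked universe. ``fdr_scheme='gsea'`` applies the original
    sign-stratified pooled-null FDR; ``'bh'`` applies Benjamini-Hochberg
    to the nominal p-values instead.
    """
    if B < 100:
        raise ValidationError("B must be >= 100")
    genes = list(ranked_genes)
    scores = np.asarray(scores, dtype=float)
    universe = set(genes)
    rng = np.random.default_rng(seed)

    rows = []
    excluded: dict[str, str] = {}
    leading_edges: dict[str, list[str]] = {}
    null_es: dict[str, np.ndarray] = {}
    sizes_needed: dict[int, int] = {}
    restricted: dict[str, list[str]] = {}
    for name, members in collection.sets.items():
        inside = [g for g in members if g in universe]
        if not inside:
            excluded[name] = "no overlap with ranked list"
            continue
        if len(inside) < min_size:
            excluded[name] = f"size {len(inside)} < min_size {min_size}"
            continue
        if len(inside) > max_size:
            excluded[name] = f"size {len(inside)} > max_size {max_size}"
            continue
        restricted[name] = inside
        sizes_needed[len(inside)] = sizes_needed.get(len(inside), 0) + 1

    # one shared null per distinct set size
    size_nulls: dict[int, np.ndarray] = {}
    gene_arr = np.array(genes)
    for size in sorted(sizes_needed):
        nulls = np.empty(B)
        for b in range(B):
            sample = gene_arr[rng.choice(len(gene_arr), size=size, replace=False)]
            nulls[b], _, _ = enrichment_score(genes, scores, sample, weight=weight)
        size_nulls[size] = nulls

    for name, inside in restricted.items():
        es, _, leading = enrichment_score(genes, scores, inside, weight=weight)
        nulls = size_nulls[len(inside)]
        same_sign = nulls[nulls >= 0] if es >= 0 else nulls[nulls < 0]
        if same_sign.size == 0:
            p = 1.0 / (B + 1)
            mean_mag = np.abs(nulls).mean()
        else:
            p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
            mean_mag = np.abs(same_sign).mean()
        nes = es / mean_mag if mean_mag > 0 else 0.0
        rows.append({"name": name, "size": len(inside), "ES": es, "NES": nes, "p": p})
        leading_edges[name] = leading
        null_es[name] = nulls

    if not rows:
        table = pd.DataFrame(columns=["size", "ES", "NES", "p", "q", "significant"])
        return GseaResult(table, leading_edges, excluded)

    table = pd.DataFrame(rows).set_index("name")
    if fdr_scheme == "bh":
        from sexdim.differential import bh_adjust

        table["q"] = bh_adjust(table["p"].to_numpy())
    elif fdr_scheme == "gsea":
        table["q"] = _gsea_fdr(table, null_es)
    else:
        raise ValidationError("fdr_scheme must be 'gsea' or 'bh'")
    table["significant"] = table["q"] < q_threshold
    return GseaResult(table, leading_edges, excluded)


def _gsea_fdr(table: pd.DataFrame, null_es: dict[str, np.ndarray]) -> np.ndarray:
    """Sign-stratified pooled-null FDR of the original pre-ranked method."""
    pooled_nes = []
    for name in table.index:
        nulls = null_es[name]
        pos = nulls[nulls >= 0]
        neg = nulls[nulls < 0]
        normed = np.empty_like(nulls)
        normed[nulls >= 0] = pos / pos.mean() if pos.size else 0.0
        normed[nulls < 0] = -neg / neg.mean() if neg.size else 0.0
        pooled_nes.append(normed)
    pooled = np.concatenate(pooled_nes)
    obs = table["NES"].to_numpy()
    q = np.empty(obs.size)
    for i, nes in enumerate(obs):
        if nes >= 0:
            null_frac_all = np.mean(pooled >= 0)
            null_frac = np.mean(pooled >= nes) / null_frac_all if null_frac_all > 0 else 1.0
            obs_pos = obs[obs >= 0]
            obs_frac = np.mean(obs_pos >= nes) if obs_pos.size else 1.0
        else:
            null_frac_all = np.mean(pooled < 0)
            null_frac = np.mean(pooled <= nes) / null_frac_all if null_frac_all > 0 else 1.0
            obs_neg = obs[obs < 0]
            obs_frac = np.mean(obs_neg <= nes) if obs_neg.size else 1.0
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    return q


def hypergeom_overlap(hits, gene_set, background_size: int) -> float:
    """Upper-tail hypergeometric p for the overlap of two gene lists.

    ``P(X >= |hits ∩ set|)`` with X ~ Hypergeometric(background_size,
    |set|, |hits|). Duplicates are ignored; if a list exceeds the
    background it is clamped with a warning.
    """
    hits = set(hits)
    members = set(gene_set)
    overlap = len(hits & members)
    return hypergeom_overlap_counts(overlap, len(hits), len(members), background_size)


def hypergeom_overlap_counts(
    n_overlap: int, n_hits: int, n_set: int, background_size: int
) -> float:
    """Upper-tail hypergeometric p from counts: P(X >= n_overlap)."""
    if n_hits > background_size or n_set > background_size:
        warnings.warn(
            "list larger than background; clamping to background size", stacklevel=2
        )
        n_hits = min(n_hits, background_size)
        n_set = min(n_set, background_size)
    if n_overlap > min(n_hits, n_set):
        raise ValidationError("overlap exceeds list sizes")
    if n_overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(n_overlap - 1, background_size, n_set, n_hits))
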