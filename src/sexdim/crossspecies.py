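"""Human-mouse comparison of sex-biased expression.

Human differential-expression summaries (per-gene female-minus-male log2
fold change and FDR q-value, e.g. from a monocyte or CD4 T-cell cohort)
are joined to mouse fold changes through a one-to-one ortholog map, gated
on human significance (q < 0.05) and mouse expression, and tested for
direction consistency: at each fold-change threshold, does the set of
human female-higher (or male-higher) genes overlap the mouse same-direction
set more than chance? The overlap p is an upper-tail hypergeometric over
the joined gene universe; a binomial sign test is available as an
alternative parameterization.

Also here: the gene-level expression filter used for human microarray
cohorts (drop genes below the per-sample 10% quantile in more than 2/3 of
males AND more than 2/3 of females).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from sexdim.io_formats import ExpressionMatrix, SampleMetadata, ValidationError
from sexdim.enrichment import hypergeom_overlap_counts

__all__ = [
    "HumanDETable",
    "OrthologMap",
    "immvar_gene_filter",
    "map_orthologs",
    "direction_consistency_test",
]


@dataclass
class HumanDETable:
    """Per-human-gene DE summary: symbol-indexed log2fc (F-M) and qFDR."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"log2fc", "qFDR"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"human DE table missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate human gene symbols")
        q = self.table["qFDR"].to_numpy()
        if np.any((q < 0) | (q > 1)):
            raise ValidationError("qFDR values must lie in [0, 1]")


@dataclass
class OrthologMap:
    """One-to-one human-to-mouse symbol map after ambiguity resolution.

    Many-to-many input rows are resolved by keeping, per human symbol,
    the single highest-confidence pairing; rows whose mouse symbol would
    be claimed by two human symbols are dropped. Dropped symbols are
    reported in ``ambiguous``.
    """

    mapping: dict[str, str]
    ambiguous: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        mouse = list(self.mapping.values())
        if len(mouse) != len(set(mouse)):
            raise ValidationError("a mouse symbol is mapped from two human symbols")

    @classmethod
    def from_pairs(cls, pairs, confidence=None) -> "OrthologMap":
        """Build from (human, mouse) pairs, optionally with confidences.

        Per human symbol the highest-confidence pair wins (first pair on
        ties); mouse symbols claimed by multiple human symbols keep only
        the highest-confidence claim.
        """
        pairs = list(pairs)
        conf = list(confidence) if confidence is not None else [0.0] * len(pairs)
        best: dict[str, tuple[str, float]] = {}
        ambiguous: set[str] = set()
        for (h, m), c in zip(pairs, conf):
            if h not in best or c > best[h][1]:
                if h in best:
                    ambiguous.add(h)
                best[h] = (m, c)
            elif best[h][0] != m:
                ambiguous.add(h)
        by_mouse: dict[str, tuple[str, float]] = {}
        for h, (m, c) in best.items():
            if m not in by_mouse or c > by_mouse[m][1]:
                if m in by_mouse:
                    ambiguous.add(by_mouse[m][0])
                by_mouse[m] = (h, c)
            else:
                ambiguous.add(h)
        mapping = {h: m for m, (h, _) in by_mouse.items()}
        return cls(mapping=mapping, ambiguous=sorted(ambiguous - set(mapping)))


def immvar_gene_filter(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    quantile: float = 0.10,
    fraction: float = 2 / 3,
) -> tuple[list[str], list[str]]:
    """Low-expression gene filter for a human cohort matrix.

    A gene is removed iff it lies below the per-sample ``quantile``
    expression cutoff in more than ``fraction`` of the males AND more
    than ``fraction`` of the females. Returns (kept, removed).
    """
    meta = metadata.subset(matrix.sample_ids).table
    values = matrix.values
    cutoffs = values.quantile(quantile, axis=0)  # per-sample cutoff
    below = values.lt(cutoffs, axis=1)
    removed_mask = pd.Series(True, index=values.index)
    for sex in ("F", "M"):
        ids = meta.index[meta["sex"] == sex]
        if len(ids) == 0:
            raise ValidationError(f"no {sex} samples in metadata")
        frac_below = below[ids].sum(axis=1) / len(ids)
        removed_mask &= frac_below > fraction
    kept = values.index[~removed_mask].tolist()
    removed = values.index[removed_mask].tolist()
    return kept, removed


def map_orthologs(
    human: HumanDETable,
    orthologs: OrthologMap,
    mouse_matrix: ExpressionMatrix,
    mouse_fc: pd.Series,
    q_threshold: float = 0.05,
    min_expressed: int = 3,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Join human DE genes to mouse fold changes through the ortholog map.

    Keeps human genes with qFDR < ``q_threshold`` that have a mouse
    ortholog expressed (> 0) in at least ``min_expressed`` mouse samples.
    Returns the joined table (index human symbol; columns mouse_symbol,
    human_log2fc, mouse_log2fc) and an exclusion report.
    """
    report: dict[str, list[str]] = {"not_significant": [], "no_ortholog": [], "not_expressed": []}
    expressed_counts = (mouse_matrix.values > 0).sum(axis=1)
    rows = []
    for symbol, row in human.table.iterrows():
        if row["qFDR"] >= q_threshold:
            report["not_significant"].append(symbol)
            continue
        mouse_symbol = orthologs.mapping.get(symbol)
        if mouse_symbol is None or mouse_symbol not in mouse_fc.index:
            report["no_ortholog"].append(symbol)
            continue
        if (
            mouse_symbol not in expressed_counts.index
            or expressed_counts[mouse_symbol] < min_expressed
        ):
            report["not_expressed"].append(symbol)
            continue
        rows.append(
            {
                "human_symbol": symbol,
                "mouse_symbol": mouse_symbol,
                "human_log2fc": float(row["log2fc"]),
                "mouse_log2fc": float(mouse_fc[mouse_symbol]),
            }
        )
    if not rows:
        raise ValidationError("ortholog join is empty after filtering")
    joined = pd.DataFrame(rows).set_index("human_symbol")
    return joined, report


def direction_consistency_test(
    joined: pd.DataFrame,
    thresholds=(0.0, 0.1, 0.2),
    side: str = "female",
    method: str = "hypergeometric",
) -> pd.DataFrame:
    """Test human-mouse fold-change direction consistency per threshold.

    At threshold t, H = human genes with the side's direction and
    |log2fc| > t (strict), M = mouse genes likewise; the overlap is
    tested with an upper-tail hypergeometric over the joined universe
    (population = all joined genes, successes = |M|, draws = |H|).
    ``method='binomial'`` instead tests the overlap fraction of H against
    a fair sign null.
    """
    if joined.empty:
        raise ValidationError("joined table is empty")
    if side not in ("female", "male"):
        raise ValidationError("side must be 'female' or 'male'")
    sign = 1.0 if side == "female" else -1.0
    h_fc = sign * joined["human_log2fc"].to_numpy()
    m_fc = sign * joined["mouse_log2fc"].to_numpy()
    n_total = len(joined)
    rows = []
    for t in thresholds:
        H = h_fc > t
        M = m_fc > t
        overlap = int((H & M).sum())
        if method == "hypergeometric":
            p = hypergeom_overlap_counts(overlap, int(H.sum()), int(M.sum()), n_total)
        elif method == "binomial":
            p = float(stats.binomtest(overlap, int(H.sum()), 0.5, alternative="greater").pvalue) if H.sum() else 1.0
        else:
            raise ValidationError("method must be 'hypergeometric' or 'binomial'")
        rows.append(
            {
                "threshold": float(t),
                "n_human": int(H.sum()),
                "n_mouse": int(M.sum()),
                "n_overlap": overlap,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("threshold")
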