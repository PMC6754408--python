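"""Permutation nulls for the differential and shift statistics.

Two designs are supported, mirroring the two randomizations a paired
sex-comparison admits:

* ``within_pair_flip`` — keep each female/male pair intact and swap its
  labels with probability 1/2 (the null for paired t statistics; it
  preserves cell-type, dataset and age confounding structure);
* ``group_label_shuffle`` — reassign group labels uniformly at random
  subject to the group sizes (the null for unpaired statistics).

When the design space is small (at most 2**14 assignments) the null is
enumerated exhaustively instead of sampled. Monte-Carlo p-values use the
add-one convention (r+1)/(B+1), which is never zero; the raw exceedance
count is kept so "p < 1/B" phrasing stays recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from math import comb
from typing import Callable

import numpy as np

from sexdim.io_formats import ValidationError

__all__ = [
    "EXHAUSTIVE_LIMIT",
    "PermutationResult",
    "WithinPairFlip",
    "GroupLabelShuffle",
    "permute_within_pairs",
    "permute_group_labels",
    "permutation_pvalue",
    "paired_t_signflip_pvalues",
]

#: Enumerate the full assignment space when it has at most this many members.
EXHAUSTIVE_LIMIT = 2**14


@dataclass(frozen=True)
class WithinPairFlip:
    """Sign-flip design over ``n_pairs`` female/male pairs."""

    n_pairs: int

    @property
    def space_size(self) -> int:
        return 2**self.n_pairs

    def identity(self) -> np.ndarray:
        return np.ones(self.n_pairs, dtype=np.int8)


@dataclass(frozen=True)
class GroupLabelShuffle:
    """Label shuffle over ``n_total`` samples with ``n_group_a`` in group A."""

    n_total: int
    n_group_a: int

    @property
    def space_size(self) -> int:
        return comb(self.n_total, self.n_group_a)

    def identity(self) -> np.ndarray:
        mask = np.zeros(self.n_total, dtype=bool)
        mask[: self.n_group_a] = True
        return mask


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the permutation p."""

    observed: float
    null: np.ndarray
    p: float
    exceedances: int
    B: int
    design: str
    seed: int
    exhaustive: bool
    tail: str


def permute_within_pairs(
    design: WithinPairFlip | int,
    seed: int = 0,
    B: int = 1000,
    exhaustive: bool | None = None,
) -> tuple[np.ndarray, bool]:
    """Draw B sign vectors over pairs (+1 keep, -1 swap).

    Returns (assignments, exhaustive_flag); in exhaustive mode all 2**n
    distinct vectors are returned exactly once.
    """
    if isinstance(design, int):
        design = WithinPairFlip(design)
    if design.n_pairs < 1:
        raise ValidationError("need at least one pair")
    if exhaustive is None:
        exhaustive = design.space_size <= EXHAUSTIVE_LIMIT
    if exhaustive:
        signs = np.array(list(product((1, -1), repeat=design.n_pairs)), dtype=np.int8)
        return signs, True
    rng = np.random.default_rng(seed)
    signs = rng.choice(np.array([1, -1], dtype=np.int8), size=(B, design.n_pairs))
    return signs, False


def permute_group_labels(
    design: GroupLabelShuffle | tuple[int, int],
    seed: int = 0,
    B: int = 1000,
    exhaustive: bool | None = None,
) -> tuple[np.ndarray, bool]:
    """Draw B boolean group-A membership masks preserving group sizes."""
    if not isinstance(design, GroupLabelShuffle):
        n_total, n_a = design
        design = GroupLabelShuffle(n_total, n_a)
    if not 0 < design.n_group_a < design.n_total:
        raise ValidationError("group sizes must both be positive")
    if exhaustive is None:
        exhaustive = design.space_size <= EXHAUSTIVE_LIMIT
    if exhaustive:
        masks = np.zeros((design.space_size, design.n_total), dtype=bool)
        for i, idx in enumerate(combinations(range(design.n_total), design.n_group_a)):
            masks[i, list(idx)] = True
        return masks, True
    rng = np.random.default_rng(seed)
    masks = np.zeros((B, design.n_total), dtype=bool)
    for b in range(B):
        masks[b, rng.choice(design.n_total, size=design.n_group_a, replace=False)] = True
    return masks, False


def permutation_pvalue(
    statistic_fn: Callable,
    data,
    design: WithinPairFlip | GroupLabelShuffle,
    B: int = 1000,
    seed: int = 0,
    tail: str = "two",
    exhaustive: bool | None = None,
) -> PermutationResult:
    """Permutation p-value of ``statistic_fn(data, assignment)``.

    The observed statistic is computed under the identity assignment.
    ``tail``: ``two`` compares |statistic|, ``greater``/``less`` compare
    signed values (use for intrinsically one-sided statistics such as
    SDEG counts). Monte-Carlo p = (r+1)/(B+1); exhaustive p = r/N over
    the full space, which contains the identity, so p > 0 always.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if tail not in ("two", "greater", "less"):
        raise ValidationError("tail must be 'two', 'greater' or 'less'")
    if isinstance(design, WithinPairFlip):
        assignments, was_exhaustive = permute_within_pairs(design, seed=seed, B=B, exhaustive=exhaustive)
        design_name = "within_pair_flip"
    elif isinstance(design, GroupLabelShuffle):
        assignments, was_exhaustive = permute_group_labels(design, seed=seed, B=B, exhaustive=exhaustive)
        design_name = "group_label_shuffle"
    else:
        raise ValidationError(f"unknown design {design!r}")

    observed = float(statistic_fn(data, design.identity()))
    null = np.array([statistic_fn(data, a) for a in assignments], dtype=float)
    if tail == "two":
        exceed = int(np.sum(np.abs(null) >= np.abs(observed)))
    elif tail == "greater":
        exceed = int(np.sum(null >= observed))
    else:
        exceed = int(np.sum(null <= observed))
    if was_exhaustive:
        p = exceed / null.size
    else:
        p = (exceed + 1) / (null.size + 1)
    return PermutationResult(
        observed=observed,
        null=null,
        p=float(p),
        exceedances=exceed,
        B=int(null.size),
        design=design_name,
        seed=seed,
        exhaustive=was_exhaustive,
        tail=tail,
    )


def paired_t_signflip_pvalues(
    diffs: np.ndarray,
    seed: int = 0,
    B: int = 1000,
    exhaustive: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene sign-flip permutation p for the paired t statistic, vectorized.

    ``diffs`` is genes x pairs of within-pair (F-M) differences. The
    permutation statistic is |t|; exhaustive enumeration (automatic for
    small pair counts) divides by the full space size, Monte-Carlo uses
    the add-one convention. Returns (p per gene, observed t per gene);
    genes with zero difference variance get t = 0, p = 1.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 2:
        raise ValidationError("diffs must be genes x pairs")
    n = diffs.shape[1]
    signs, was_exhaustive = permute_within_pairs(WithinPairFlip(n), seed=seed, B=B, exhaustive=exhaustive)
    sumsq = (diffs**2).sum(axis=1)

    def t_for(mean_b: np.ndarray) -> np.ndarray:
        var = (sumsq[:, None] - n * mean_b**2) / (n - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean_b / np.sqrt(var / n)
        return np.where(var == 0, 0.0, t)

    t_all = t_for(diffs @ signs.T.astype(float) / n)  # genes x assignments
    t_obs = t_for(diffs.mean(axis=1, keepdims=True))[:, 0]
    exceed = (np.abs(t_all) >= np.abs(t_obs)[:, None] - 1e-12).sum(axis=1)
    if was_exhaustive:
        p = exceed / signs.shape[0]
    else:
        p = (exceed + 1) / (signs.shape[0] + 1)
    return p, t_obs
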