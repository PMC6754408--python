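"""Synthetic immune expression and accessibility data with known truth.

The generator reproduces the statistical structure the analysis modules
assume, so every downstream stage is testable without external downloads:

* dominant cell-type effects (the largest source of variance, SD ~2 log2
  units), with smaller dataset-batch and age effects layered on top;
* small sex effects concentrated on sex-chromosome genes plus a handful of
  macrophage-specific autosomal genes;
* an interferon-stimulated-gene (ISG) module with a small female-upward
  baseline shift that is amplified by IFN stimulation;
* open-chromatin intensities whose replicate SD decreases with mean
  intensity (halving per +2 log2 by default);
* human/mouse ortholog tables with a controllable direction-concordance.

Everything is simulated directly on the log2 scale and floored at 0
(mirroring floor-at-1-then-log2 preprocessing); a negative-binomial count
mode exists only to exercise the count-normalization path. All outputs are
deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sexdim.crossspecies import HumanDETable, OrthologMap
from sexdim.io_formats import (
    ExpressionMatrix,
    OcrTable,
    SampleMetadata,
    ValidationError,
)

__all__ = [
    "IMMUNE_CELL_TYPES",
    "SexEffect",
    "IsgModule",
    "SimConfig",
    "simulate_immune_expression",
    "simulate_ifn_response",
    "simulate_ocr_accessibility",
    "simulate_ortholog_tables",
    "simulate_counts",
    "default_atac_sd",
]

#: The 11 immune cell types of the profiling design.
IMMUNE_CELL_TYPES = ("GN", "DC", "MF", "B", "B1a", "T4", "T8", "Treg", "NK", "NKT", "Tgd")


@dataclass(frozen=True)
class SexEffect:
    """A planted female-minus-male log2 effect on one gene.

    ``scope`` is either ``"all"`` (pan-immune) or a cell-type name
    (cell-type-specific, e.g. ``"MF"``).
    """

    gene_index: int
    scope: str
    log2fc: float


@dataclass(frozen=True)
class IsgModule:
    """An interferon-stimulated gene module.

    ``baseline_shift`` is the female-upward log2 shift present without
    stimulation; ``induction_mean`` the mean log2 induction upon IFN;
    ``ifn_shift`` the extra female-specific induction (the sex-by-IFN
    interaction).
    """

    gene_indices: tuple[int, ...]
    baseline_shift: float = 0.15
    induction_mean: float = 3.0
    ifn_shift: float = 0.30


@dataclass
class SimConfig:
    """Configuration of the expression simulator.

    Defaults emulate a two-dataset (A, B) design with three female and
    three male replicates per cell type and dataset — six pairs per cell
    type after pairing — cell-type effects dominating (SD 2.0), modest
    batch and age effects, and residual noise SD 0.3.
    """

    n_genes: int = 1000
    cell_types: tuple[str, ...] = IMMUNE_CELL_TYPES
    datasets: dict[str, float] = field(default_factory=lambda: {"A": 0.4, "B": 0.4})
    n_replicates: int = 3
    age_groups: tuple[str, ...] = ("young", "adult")
    age_effect_sd: float = 0.2
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    cell_type_sd: float = 2.0
    residual_sd: float = 0.3
    sex_effects: tuple[SexEffect, ...] = ()
    isg_module: IsgModule | None = None
    x_gene_indices: tuple[int, ...] = ()
    y_gene_indices: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.residual_sd <= 0 or self.cell_type_sd <= 0:
            raise ValidationError("all SDs must be > 0")
        if any(sd <= 0 for sd in self.datasets.values()):
            raise ValidationError("dataset batch SDs must be > 0")
        for eff in self.sex_effects:
            if eff.scope != "all" and eff.scope not in self.cell_types:
                raise ValidationError(f"sex-effect scope {eff.scope!r} is not a cell type")
            if not 0 <= eff.gene_index < self.n_genes:
                raise ValidationError(f"sex-effect gene index {eff.gene_index} out of range")
        if self.isg_module is not None:
            bad = [i for i in self.isg_module.gene_indices if not 0 <= i < self.n_genes]
            if bad:
                raise ValidationError(f"ISG indices out of range: {bad}")


def _gene_ids(n: int) -> list[str]:
    return [f"gene{i:05d}" for i in range(n)]


def _chromosomes(config: SimConfig) -> pd.Series:
    chrom = np.full(config.n_genes, "1", dtype=object)
    chrom[list(config.x_gene_indices)] = "X"
    chrom[list(config.y_gene_indices)] = "Y"
    return pd.Series(chrom, index=_gene_ids(config.n_genes), name="chromosome")


def _truth_table(config: SimConfig) -> pd.DataFrame:
    ids = _gene_ids(config.n_genes)
    truth = pd.DataFrame(index=pd.Index(ids, name="gene_id"))
    truth["chromosome"] = _chromosomes(config).to_numpy()
    truth["isg"] = False
    truth["module"] = ""
    if config.isg_module is not None:
        truth.iloc[list(config.isg_module.gene_indices), truth.columns.get_loc("isg")] = True
    for ct in config.cell_types:
        truth[f"effect_{ct}"] = 0.0
    for eff in config.sex_effects:
        scopes = config.cell_types if eff.scope == "all" else (eff.scope,)
        for ct in scopes:
            truth.iloc[eff.gene_index, truth.columns.get_loc(f"effect_{ct}")] += eff.log2fc
    if config.isg_module is not None and config.isg_module.baseline_shift != 0:
        for ct in config.cell_types:
            col = truth.columns.get_loc(f"effect_{ct}")
            for i in config.isg_module.gene_indices:
                truth.iloc[i, col] += config.isg_module.baseline_shift
    return truth


def simulate_immune_expression(
    config: SimConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, pd.DataFrame]:
    """Simulate log2 expression for the full factorial design of the config.

    Per sample: value = gene baseline + cell-type effect + dataset batch
    + age effect + sex effect (female +d/2, male -d/2) + N(0, sigma),
    floored at 0. Age groups alternate across replicates so pairing on
    (cell_type, dataset, age_group) always finds a same-age partner.
    Returns (matrix, metadata, truth table).
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=G)
    ct_effect = {
        ct: rng.normal(0.0, config.cell_type_sd, size=G) for ct in config.cell_types
    }
    batch_effect = {
        ds: rng.normal(0.0, sd, size=G) for ds, sd in config.datasets.items()
    }
    age_effect = {
        ag: rng.normal(0.0, config.age_effect_sd, size=G) for ag in config.age_groups
    }
    truth = _truth_table(config)

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for ds in config.datasets:
        for ct in config.cell_types:
            half_effect = truth[f"effect_{ct}"].to_numpy() / 2.0
            for sex, sign in (("F", 1.0), ("M", -1.0)):
                for rep in range(1, config.n_replicates + 1):
                    age = config.age_groups[(rep - 1) % len(config.age_groups)]
                    sample_id = f"{ds}_{ct}_{sex}_{rep}"
                    mean = (
                        baseline
                        + ct_effect[ct]
                        + batch_effect[ds]
                        + age_effect[age]
                        + sign * half_effect
                    )
                    value = mean + rng.normal(0.0, config.residual_sd, size=G)
                    columns[sample_id] = np.maximum(value, 0.0)
                    meta_rows.append(
                        {
                            "sample_id": sample_id,
                            "sex": sex,
                            "cell_type": ct,
                            "dataset": ds,
                            "age_group": age,
                            "tissue": "",
                            "stimulation": "none",
                            "replicate": rep,
                        }
                    )
    ids = _gene_ids(G)
    matrix = ExpressionMatrix(
        pd.DataFrame(columns, index=pd.Index(ids, name="gene_id")),
        scale="log2",
        gene_symbols=pd.Series(ids, index=ids, name="symbol"),
        gene_chromosome=_chromosomes(config),
    )
    metadata = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return matrix, metadata, truth


def simulate_ifn_response(
    config: SimConfig,
    base: ExpressionMatrix,
    metadata: SampleMetadata,
    truth: pd.DataFrame,
    stim_cell_types: tuple[str, ...] = ("B", "GN", "MF"),
    stim_dataset: str = "B",
    induction_sd: float = 0.5,
) -> tuple[ExpressionMatrix, SampleMetadata, pd.DataFrame]:
    """Append IFN-stimulated counterparts of selected unstimulated samples.

    ISG genes gain a per-gene induction (mean ``induction_mean``) in both
    sexes plus the female-specific ``ifn_shift``; non-ISG genes change
    only by residual noise in expectation. Returns the extended
    (matrix, metadata, truth); truth gains ``ifn_induction`` and
    ``ifn_effect_<ct>`` columns.
    """
    if config.isg_module is None:
        raise ValidationError("config has no isg_module")
    rng = np.random.default_rng(config.seed + 1)
    isg_idx = np.array(config.isg_module.gene_indices, dtype=int)
    G = base.n_genes
    induction = np.zeros(G)
    induction[isg_idx] = rng.normal(
        config.isg_module.induction_mean, induction_sd, size=isg_idx.size
    )

    meta = metadata.table
    stim_sources = meta.index[
        meta["cell_type"].isin(stim_cell_types) & (meta["dataset"] == stim_dataset)
    ]
    if len(stim_sources) == 0:
        raise ValidationError("no samples match the stimulation arm")
    new_cols: dict[str, np.ndarray] = {}
    new_meta = []
    for sample_id in stim_sources:
        row = meta.loc[sample_id]
        extra = induction.copy()
        if row["sex"] == "F":
            extra[isg_idx] += config.isg_module.ifn_shift
        value = (
            base.values[sample_id].to_numpy()
            + extra
            + rng.normal(0.0, config.residual_sd, size=G)
        )
        stim_id = f"{sample_id}_IFN"
        new_cols[stim_id] = np.maximum(value, 0.0)
        new_meta.append(
            {
                "sample_id": stim_id,
                "sex": row["sex"],
                "cell_type": row["cell_type"],
                "dataset": row["dataset"],
                "age_group": row["age_group"],
                "tissue": row["tissue"],
                "stimulation": "IFN",
                "replicate": row["replicate"],
            }
        )
    combined = pd.concat(
        [base.values, pd.DataFrame(new_cols, index=base.values.index)], axis=1
    )
    matrix = ExpressionMatrix(
        combined,
        scale="log2",
        gene_symbols=base.gene_symbols,
        gene_chromosome=base.gene_chromosome,
    )
    meta_out = pd.concat([meta, pd.DataFrame(new_meta).set_index("sample_id")])
    truth = truth.copy()
    truth["ifn_induction"] = induction
    for ct in stim_cell_types:
        truth[f"ifn_effect_{ct}"] = 0.0
        truth.loc[truth["isg"], f"ifn_effect_{ct}"] = config.isg_module.ifn_shift
    return matrix, SampleMetadata(meta_out), truth


def default_atac_sd(mean_intensity: np.ndarray, sd_at_low: float = 0.5, low: float = 6.0) -> np.ndarray:
    """Replicate SD halving per +2 log2 units of mean intensity."""
    return sd_at_low * 2.0 ** (-(np.asarray(mean_intensity, dtype=float) - low) / 2.0)


def simulate_ocr_accessibility(
    n_ocrs: int,
    intensity_range: tuple[float, float] = (6.0, 12.0),
    variance_fn=default_atac_sd,
    planted_dos: dict[int, float] | None = None,
    n_replicates: int = 2,
    class_cycle: tuple[str, ...] = ("TSS", "gene_body", "distal_enhancer"),
    seed: int = 0,
) -> tuple[OcrTable, SampleMetadata, pd.DataFrame]:
    """Simulate an OCR accessibility table with intensity-dependent noise.

    Each OCR draws a mean log2 intensity uniformly from
    ``intensity_range``; female and male replicate values are normal
    around mean +/- half the planted effect with SD ``variance_fn(mean)``.
    Annotation classes cycle through ``class_cycle``; each OCR is
    associated with its own gene symbol.
    """
    planted_dos = planted_dos or {}
    bad = [i for i in planted_dos if not 0 <= i < n_ocrs]
    if bad:
        raise ValidationError(f"planted effects on nonexistent OCRs: {bad}")
    rng = np.random.default_rng(seed)
    lo, hi = intensity_range
    means = rng.uniform(lo, hi, size=n_ocrs)
    sds = np.asarray(variance_fn(means), dtype=float)
    effects = np.zeros(n_ocrs)
    for i, eff in planted_dos.items():
        effects[i] = eff

    ids = [f"ocr{i:06d}" for i in range(n_ocrs)]
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for sex, sign in (("F", 1.0), ("M", -1.0)):
        for rep in range(1, n_replicates + 1):
            sample_id = f"ATAC_{sex}_{rep}"
            cols[sample_id] = rng.normal(means + sign * effects / 2.0, sds)
            meta_rows.append({"sample_id": sample_id, "sex": sex, "replicate": rep})
    annotation = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_ocrs) * 1000,
            "end": np.arange(n_ocrs) * 1000 + 500,
            "annotation_class": [class_cycle[i % len(class_cycle)] for i in range(n_ocrs)],
            "associated_gene": [f"gene{i:06d}" for i in range(n_ocrs)],
        },
        index=pd.Index(ids, name="ocr_id"),
    )
    values = pd.DataFrame(cols, index=annotation.index)
    truth = pd.DataFrame(
        {"mean_intensity": means, "sd": sds, "true_effect": effects},
        index=annotation.index,
    )
    metadata = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return OcrTable(annotation, values), metadata, truth


def simulate_ortholog_tables(
    n_genes: int,
    n_human_de: int,
    concordance: float,
    seed: int = 0,
    n_mouse_samples: int = 6,
    unmapped_fraction: float = 0.0,
    human_fc_scale: float = 0.3,
    mouse_fc_scale: float = 0.25,
) -> tuple[HumanDETable, OrthologMap, pd.Series, ExpressionMatrix]:
    """Simulate matched human DE, ortholog-map and mouse fold-change tables.

    A fraction ``concordance`` of the human significant genes get a mouse
    fold change of the same sign (magnitude folded normal); the rest get
    the opposite sign. Returns (human table, ortholog map, mouse fold
    changes, mouse expression matrix for the expression gate).
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValidationError("concordance must lie in [0, 1]")
    if n_human_de > n_genes:
        raise ValidationError("n_human_de cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    human_symbols = [f"HG{i:05d}" for i in range(n_genes)]
    mouse_symbols = [f"Mg{i:05d}" for i in range(n_genes)]

    q = rng.uniform(0.05, 1.0, size=n_genes)
    de_idx = rng.choice(n_genes, size=n_human_de, replace=False)
    q[de_idx] = rng.uniform(0.0, 0.05, size=n_human_de)
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    human_fc = signs * np.abs(rng.normal(0.0, human_fc_scale, size=n_genes))

    mouse_signs = signs.copy()
    flip = rng.random(n_genes) >= concordance
    mouse_signs[flip] *= -1.0
    mouse_fc_values = mouse_signs * np.abs(rng.normal(0.0, mouse_fc_scale, size=n_genes))

    n_unmapped = int(round(unmapped_fraction * n_genes))
    unmapped = set(rng.choice(n_genes, size=n_unmapped, replace=False).tolist())
    mapping = {
        human_symbols[i]: mouse_symbols[i] for i in range(n_genes) if i not in unmapped
    }

    human = HumanDETable(
        pd.DataFrame(
            {"log2fc": human_fc, "qFDR": q},
            index=pd.Index(human_symbols, name="symbol"),
        )
    )
    mouse_fc = pd.Series(mouse_fc_values, index=mouse_symbols, name="log2fc")
    mouse_values = np.maximum(
        rng.normal(7.0, 1.5, size=(n_genes, n_mouse_samples)), 0.0
    )
    mouse_matrix = ExpressionMatrix(
        pd.DataFrame(
            mouse_values,
            index=pd.Index(mouse_symbols, name="gene_id"),
            columns=[f"mm{i}" for i in range(n_mouse_samples)],
        ),
        scale="log2",
    )
    return human, OrthologMap(mapping), mouse_fc, mouse_matrix


def simulate_counts(
    n_genes: int,
    n_samples: int,
    seed: int = 0,
    mean_log: float = 5.0,
    dispersion: float = 0.1,
    size_factor_range: tuple[float, float] = (0.5, 2.0),
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Negative-binomial count matrix with known sample size factors.

    Exists to exercise the median-of-ratios normalization path; returns
    (counts matrix, true size factors).
    """
    rng = np.random.default_rng(seed)
    base_mean = rng.lognormal(mean_log * np.log(2) / 2, 1.0, size=n_genes)
    factors = rng.uniform(*size_factor_range, size=n_samples)
    mu = base_mean[:, None] * factors[None, :]
    # NB with mean mu and dispersion alpha: var = mu + alpha mu^2
    r = 1.0 / dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    matrix = ExpressionMatrix(
        pd.DataFrame(
            counts.astype(float),
            index=pd.Index(_gene_ids(n_genes), name="gene_id"),
            columns=[f"s{j}" for j in range(n_samples)],
        ),
        scale="counts",
    )
    return matrix, factors
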