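"""Tabular containers and readers/writers for the pipeline's standard inputs.

All on-disk formats are plain tab-delimited text with a single header line;
lines starting with ``#`` are treated as provenance comments and skipped.
Genomic coordinates are 0-based half-open (BED convention) throughout.

Schema invariants (unique identifiers, canonical factor levels, finite
values on the log2 scale) are enforced here, at the boundary, so that the
statistical modules can assume clean inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ExpressionMatrix",
    "SampleMetadata",
    "GeneSetCollection",
    "OcrTable",
    "read_expression_table",
    "write_expression_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_gmt",
    "write_gmt",
    "read_ocr_table",
    "write_ocr_table",
]

#: Expression-value scales an ExpressionMatrix may carry.
SCALES = ("counts", "linear", "log2")

#: Recognized OCR annotation classes; anything else maps to "other".
OCR_CLASSES = ("TSS", "gene_body", "distal_enhancer", "other")

_SEX_ALIASES = {"f": "F", "female": "F", "m": "M", "male": "M"}


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(ValueError):
    """Parsed content violates a schema invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-gene annotation.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    scale
        One of ``counts``, ``linear`` or ``log2``. Values must be finite
        when ``log2`` and non-negative otherwise.
    gene_symbols, gene_chromosome
        Optional per-gene annotation aligned to ``values.index``. The
        chromosome is an autosome name, ``"X"``, ``"Y"`` or ``""``.
    """

    values: pd.DataFrame
    scale: str = "log2"
    gene_symbols: pd.Series | None = None
    gene_chromosome: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise ValidationError("expression values must be numeric")
            if self.scale == "log2" and not np.isfinite(arr).all():
                raise ValidationError("log2-scale values must be finite")
            if self.scale in ("counts", "linear") and np.nanmin(arr) < 0:
                raise ValidationError(f"{self.scale}-scale values must be non-negative")
        for name in ("gene_symbols", "gene_chromosome"):
            ann = getattr(self, name)
            if ann is not None and not ann.index.equals(self.values.index):
                raise ValidationError(f"{name} index must match gene ids")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        return ExpressionMatrix(
            self.values.loc[gene_ids],
            scale=self.scale,
            gene_symbols=None if self.gene_symbols is None else self.gene_symbols.loc[gene_ids],
            gene_chromosome=(
                None if self.gene_chromosome is None else self.gene_chromosome.loc[gene_ids]
            ),
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)],
            scale=self.scale,
            gene_symbols=self.gene_symbols,
            gene_chromosome=self.gene_chromosome,
        )


@dataclass
class SampleMetadata:
    """Per-sample experimental factors.

    The backing frame is indexed by ``sample_id`` and always carries a
    ``sex`` column with canonical levels ``F``/``M``. Optional factor
    columns (``cell_type``, ``dataset``, ``age_group``, ``tissue``,
    ``stimulation``, ``replicate``) are preserved as given; unknown extra
    columns pass through as opaque text.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "sex" not in self.table.columns:
            raise ValidationError("metadata requires a 'sex' column")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        sex = self.table["sex"].astype(str)
        canonical = sex.str.lower().map(_SEX_ALIASES)
        if canonical.isna().any():
            bad = sex[canonical.isna()].unique().tolist()
            raise ValidationError(f"unrecognized sex values: {bad}")
        self.table = self.table.copy()
        self.table["sex"] = canonical.values

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)])

    def require_samples(self, sample_ids) -> None:
        """Check every sample of an associated matrix is described here."""
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")


@dataclass
class GeneSetCollection:
    """Named gene sets (MSigDB GMT dialect) with one description per set."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


@dataclass
class OcrTable:
    """Open chromatin regions x samples, with genomic annotation.

    ``annotation`` holds chrom/start/end (0-based half-open),
    ``annotation_class`` in :data:`OCR_CLASSES` and ``associated_gene``
    (symbol or empty string), indexed by ocr_id; ``values`` holds the
    normalized log2 accessibility matrix with the same index.
    """

    annotation: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.annotation.index.has_duplicates:
            dups = self.annotation.index[self.annotation.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OCR ids: {dups}")
        if not self.annotation.index.equals(self.values.index):
            raise ValidationError("annotation and values must share the OCR index")
        required = {"chrom", "start", "end", "annotation_class", "associated_gene"}
        missing = required - set(self.annotation.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        bad = self.annotation.index[
            self.annotation["start"].to_numpy() >= self.annotation["end"].to_numpy()
        ].tolist()
        if bad:
            raise ValidationError(f"start >= end for OCRs: {bad}")
        if self.values.size and not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("accessibility values must be finite")
        unknown = ~self.annotation["annotation_class"].isin(OCR_CLASSES)
        if unknown.any():
            warnings.warn(
                "unknown annotation classes mapped to 'other': "
                f"{sorted(self.annotation.loc[unknown, 'annotation_class'].unique())}",
                stacklevel=2,
            )
            self.annotation = self.annotation.copy()
            self.annotation.loc[unknown, "annotation_class"] = "other"

    @property
    def ocr_ids(self) -> list[str]:
        return self.annotation.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def subset_class(self, annotation_class: str) -> "OcrTable":
        keep = self.annotation["annotation_class"] == annotation_class
        return OcrTable(self.annotation[keep], self.values[keep])


def _read_table(path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    except pd.errors.EmptyDataError as err:
        raise FormatError(f"{path}: empty file or missing header") from err
    if frame.columns.size == 0:
        raise FormatError(f"{path}: missing header")
    return frame


def _to_numeric(frame: pd.DataFrame, path) -> pd.DataFrame:
    out = frame.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & frame.notna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {frame.iat[row, col]!r} "
            f"at row {frame.index[row]!r}, column {frame.columns[col]!r}"
        )
    if out.isna().to_numpy().any():
        raise FormatError(f"{path}: missing values are not allowed")
    return out


def read_expression_table(path, scale: str = "log2") -> ExpressionMatrix:
    """Read a genes x samples expression table.

    Layout: first column gene id; optional ``symbol`` and ``chromosome``
    annotation columns; every remaining column one sample.
    """
    frame = _read_table(path)
    frame = frame.set_index(frame.columns[0])
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene ids {dups}")
    symbols = chroms = None
    if "symbol" in frame.columns:
        symbols = frame.pop("symbol")
    if "chromosome" in frame.columns:
        chroms = frame.pop("chromosome").fillna("")
    values = _to_numeric(frame, path)
    return ExpressionMatrix(values, scale=scale, gene_symbols=symbols, gene_chromosome=chroms)


def write_expression_table(matrix: ExpressionMatrix, path, comments: list[str] | None = None) -> None:
    out = matrix.values.copy()
    if matrix.gene_chromosome is not None:
        out.insert(0, "chromosome", matrix.gene_chromosome)
    if matrix.gene_symbols is not None:
        out.insert(0, "symbol", matrix.gene_symbols)
    out.index.name = "gene_id"
    _write_with_comments(out, path, comments, index=True)


def read_sample_metadata(path) -> SampleMetadata:
    """Read per-sample factors; requires ``sample_id`` and ``sex`` columns."""
    frame = _read_table(path)
    if "sample_id" not in frame.columns or "sex" not in frame.columns:
        raise FormatError(f"{path}: metadata requires 'sample_id' and 'sex' columns")
    if frame["sample_id"].duplicated().any():
        dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dups}")
    frame = frame.set_index("sample_id")
    if "replicate" in frame.columns:
        frame["replicate"] = pd.to_numeric(frame["replicate"], errors="coerce").astype("Int64")
    return SampleMetadata(frame)


def write_sample_metadata(metadata: SampleMetadata, path, comments: list[str] | None = None) -> None:
    out = metadata.table.copy()
    out.index.name = "sample_id"
    _write_with_comments(out, path, comments, index=True)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: name TAB description TAB gene1 TAB gene2 ..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            # drop trailing empty fields (common in exported GMTs)
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, description, *genes = fields
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for name, genes in collection.sets.items():
            description = collection.descriptions.get(name, "na")
            handle.write("\t".join([name, description, *genes]) + "\n")


def read_ocr_table(path) -> OcrTable:
    """Read a BED-like OCR table.

    Leading columns: chrom, start, end, ocr_id, annotation_class,
    associated_gene; remaining columns are per-sample accessibility values.
    """
    frame = _read_table(path)
    lead = ["chrom", "start", "end", "ocr_id", "annotation_class", "associated_gene"]
    if list(frame.columns[:6]) != lead:
        raise FormatError(f"{path}: expected leading columns {lead}, got {list(frame.columns[:6])}")
    annotation = frame[lead].copy()
    annotation["start"] = pd.to_numeric(annotation["start"]).astype(int)
    annotation["end"] = pd.to_numeric(annotation["end"]).astype(int)
    annotation["associated_gene"] = annotation["associated_gene"].fillna("")
    annotation = annotation.set_index("ocr_id")
    values = _to_numeric(frame[frame.columns[6:]], path)
    values.index = annotation.index
    return OcrTable(annotation, values)


def write_ocr_table(ocr: OcrTable, path, comments: list[str] | None = None) -> None:
    out = ocr.annotation[["chrom", "start", "end"]].copy()
    out["ocr_id"] = ocr.annotation.index
    out["annotation_class"] = ocr.annotation["annotation_class"]
    out["associated_gene"] = ocr.annotation["associated_gene"]
    out = pd.concat([out.reset_index(drop=True), ocr.values.reset_index(drop=True)], axis=1)
    _write_with_comments(out, path, comments, index=False)


def _write_with_comments(frame: pd.DataFrame, path, comments, index: bool) -> None:
    with open(path, "w") as handle:
        for comment in comments or []:
            handle.write(f"# {comment}\n")
        frame.to_csv(handle, sep="\t", index=index, lineterminator="\n")
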