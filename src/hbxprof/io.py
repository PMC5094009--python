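"""Reading, validation and alignment of expression matrices and annotations.

All tabular inputs are plain TSV/CSV. The expression matrix has genes in
rows (first column = gene identifier) and samples in columns (header row);
cells are non-negative FPKM-equivalent values. Gene annotations map each
gene to one of the 11 evolutionary homeobox classes; sample annotations
record a category (adult tissue, developmental stage or cell type), a free
group label (e.g. ``neural``) and, for staged series, a temporal rank.

Identifiers are case-sensitive and never normalised: human (LEUTX) and
mouse (Cphx1) gene symbols differ only by case convention. Missing cells
are an error, not an implicit zero — silence must be a measured value.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("hbxprof")

#: The 11 evolutionary homeobox gene classes.
HBX_CLASSES = (
    "ANTP", "PRD", "LIM", "POU", "HNF", "SINE",
    "TALE", "CUT", "PROS", "ZF", "CERS",
)

SAMPLE_CATEGORIES = ("adult_tissue", "developmental_stage", "cell_type")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _resolve_sep(path, sep=None):
    if sep is not None:
        return sep
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    return "\t"


def _first_duplicate(items):
    seen = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None


def read_matrix(path, sep=None):
    """Read a genes x samples expression matrix from a delimited text file.

    Parameters
    ----------
    path : path-like
        File with gene identifiers in the first column and sample
        identifiers in the header row.
    sep : str, optional
        Field delimiter. Auto-detected from the extension when omitted
        (``.csv`` -> comma, anything else -> tab).

    Returns
    -------
    pandas.DataFrame
        Validated matrix, row/column order preserved from the file.

    Raises
    ------
    ValidationError
        On duplicate identifiers, or negative / non-numeric / missing
        values (the error message names the offending coordinates).
    """
    sep = _resolve_sep(path, sep)
    with open(path, newline="") as handle:
        header = next(csv.reader(handle, delimiter=sep))
    sample_ids = header[1:]
    dup = _first_duplicate(sample_ids)
    if dup is not None:
        raise ValidationError(f"duplicate sample identifier {dup!r} in {path}")
    raw = pd.read_csv(path, sep=sep, index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = [str(c) for c in sample_ids]
    dup = _first_duplicate(list(raw.index))
    if dup is not None:
        raise ValidationError(f"duplicate gene identifier {dup!r} in {path}")
    return validate_matrix(raw, source=str(path))


def validate_matrix(matrix, source="matrix"):
    """Validate an in-memory matrix: finite, numeric, non-negative, no NA."""
    dup = _first_duplicate(list(matrix.index))
    if dup is not None:
        raise ValidationError(f"duplicate gene identifier {dup!r} in {source}")
    dup = _first_duplicate(list(matrix.columns))
    if dup is not None:
        raise ValidationError(f"duplicate sample identifier {dup!r} in {source}")
    out = {}
    for col in matrix.columns:
        coerced = pd.to_numeric(matrix[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            gene = bad.idxmax()
            value = matrix.at[gene, col]
            if pd.isna(value):
                raise ValidationError(
                    f"missing value at gene {gene!r}, sample {col!r} in {source}"
                )
            raise ValidationError(
                f"non-numeric value {value!r} at gene {gene!r}, sample {col!r} "
                f"in {source}"
            )
        values = coerced.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            gene = matrix.index[int(np.argmin(np.isfinite(values)))]
            raise ValidationError(
                f"non-finite value at gene {gene!r}, sample {col!r} in {source}"
            )
        if (values < 0).any():
            gene = matrix.index[int(np.argmax(values < 0))]
            raise ValidationError(
                f"negative value {values[values < 0][0]} at gene {gene!r}, "
                f"sample {col!r} in {source}"
            )
        out[col] = values
    return pd.DataFrame(out, index=matrix.index.copy())


def write_matrix(matrix, path, sep=None):
    """Write a matrix as delimited text (inverse of :func:`read_matrix`)."""
    sep = _resolve_sep(path, sep)
    df = matrix.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep)


def read_gene_annotations(path, sep=None):
    """Read and validate a gene annotation table.

    Required columns: ``gene_id``, ``hbx_class``; optional ``subclass``.
    ``hbx_class`` must be one of the 11 classes in :data:`HBX_CLASSES`.
    """
    sep = _resolve_sep(path, sep)
    table = pd.read_csv(path, sep=sep, dtype=str)
    return validate_gene_annotations(table, source=str(path))


def validate_gene_annotations(table, source="gene annotation"):
    for col in ("gene_id", "hbx_class"):
        if col not in table.columns:
            raise ValidationError(f"{source}: missing required column {col!r}")
    dup = _first_duplicate(list(table["gene_id"]))
    if dup is not None:
        raise ValidationError(f"{source}: duplicate gene_id {dup!r}")
    unknown = set(table["hbx_class"]) - set(HBX_CLASSES)
    if unknown:
        label = sorted(unknown)[0]
        raise ValidationError(
            f"{source}: hbx_class {label!r} is not one of the 11 homeobox "
            f"classes {HBX_CLASSES}"
        )
    out = table.copy()
    if "subclass" not in out.columns:
        out["subclass"] = pd.NA
    out = out[["gene_id", "hbx_class", "subclass"]].set_index("gene_id")
    return out


def read_sample_annotations(path, sep=None):
    """Read and validate a sample annotation table.

    Required columns: ``sample_id``, ``category``, ``group``; optional
    ``temporal_rank`` (non-negative integer, unique among samples that
    carry one — staged series are strictly ordered).
    """
    sep = _resolve_sep(path, sep)
    table = pd.read_csv(path, sep=sep, dtype=str)
    return validate_sample_annotations(table, source=str(path))


def validate_sample_annotations(table, source="sample annotation"):
    for col in ("sample_id", "category", "group"):
        if col not in table.columns:
            raise ValidationError(f"{source}: missing required column {col!r}")
    dup = _first_duplicate(list(table["sample_id"]))
    if dup is not None:
        raise ValidationError(f"{source}: duplicate sample_id {dup!r}")
    unknown = set(table["category"]) - set(SAMPLE_CATEGORIES)
    if unknown:
        label = sorted(unknown)[0]
        raise ValidationError(
            f"{source}: category {label!r} is not one of {SAMPLE_CATEGORIES}"
        )
    out = table.copy()
    if "temporal_rank" not in out.columns:
        out["temporal_rank"] = pd.NA
    ranks = pd.to_numeric(out["temporal_rank"], errors="coerce")
    raw_present = out["temporal_rank"].notna() & (out["temporal_rank"] != "")
    if (ranks.isna() & raw_present).any():
        sample = out.loc[ranks.isna() & raw_present, "sample_id"].iloc[0]
        raise ValidationError(
            f"{source}: non-numeric temporal_rank for sample {sample!r}"
        )
    present = ranks.dropna()
    if ((present < 0) | (present != present.round())).any():
        raise ValidationError(f"{source}: temporal_rank must be a non-negative integer")
    if present.duplicated().any():
        value = int(present[present.duplicated()].iloc[0])
        raise ValidationError(
            f"{source}: temporal_rank {value} assigned to more than one sample "
            "(ranks must form a strict total order)"
        )
    out["temporal_rank"] = ranks.astype("Int64")
    out = out[["sample_id", "category", "group", "temporal_rank"]].set_index("sample_id")
    return out


def read_annotations(gene_path, sample_path, sep=None):
    """Read both annotation tables; see the per-table readers for schemas."""
    return read_gene_annotations(gene_path, sep=sep), read_sample_annotations(
        sample_path, sep=sep
    )


@dataclass(frozen=True)
class AnalysisBundle:
    """A matrix restricted to annotated genes/samples, with its annotations.

    ``dropped_genes`` / ``dropped_samples`` record identifiers present in
    exactly one of matrix and annotation (they are excluded from analysis).
    """

    matrix: pd.DataFrame
    gene_ann: pd.DataFrame
    sample_ann: pd.DataFrame
    dropped_genes: tuple = field(default_factory=tuple)
    dropped_samples: tuple = field(default_factory=tuple)


def align(matrix, gene_ann, sample_ann):
    """Restrict matrix and annotations to their common genes and samples.

    Row/column order follows the matrix; annotation row order is
    irrelevant. Dropped identifiers (on either side) are reported via a
    warning log and in the returned bundle. The operation is idempotent.

    Raises
    ------
    ValidationError
        If the gene or sample intersection is empty.
    """
    genes = [g for g in matrix.index if g in gene_ann.index]
    samples = [s for s in matrix.columns if s in sample_ann.index]
    if not genes:
        raise ValidationError("no genes shared between matrix and gene annotation")
    if not samples:
        raise ValidationError("no samples shared between matrix and sample annotation")
    dropped_genes = tuple(
        [g for g in matrix.index if g not in gene_ann.index]
        + [g for g in gene_ann.index if g not in matrix.index]
    )
    dropped_samples = tuple(
        [s for s in matrix.columns if s not in sample_ann.index]
        + [s for s in sample_ann.index if s not in matrix.columns]
    )
    if dropped_genes:
        logger.warning("align: dropped %d gene(s): %s", len(dropped_genes), list(dropped_genes))
    if dropped_samples:
        logger.warning(
            "align: dropped %d sample(s): %s", len(dropped_samples), list(dropped_samples)
        )
    return AnalysisBundle(
        matrix=matrix.loc[genes, samples],
        gene_ann=gene_ann.loc[genes],
        sample_ann=sample_ann.loc[samples],
        dropped_genes=dropped_genes,
        dropped_samples=dropped_samples,
    )
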