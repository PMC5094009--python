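"""Threshold-based expression calling and per-gene max-normalization.

Bulk FPKM values below a small threshold are dominated by spurious or
background read counts; the calling step therefore zeroes every value
below 2 FPKM by default, and all downstream expressed/not-expressed logic
is defined on the called matrix. Profiles are then normalised per gene to
the gene's maximum, mapping every row into [0, 1] so that genes with very
different absolute expression can be clustered by shape.
"""

from __future__ import annotations

import pandas as pd


def call_expression(matrix, threshold=2.0, cmp="ge"):
    """Zero sub-threshold values; keep the rest unchanged.

    A gene is called expressed in a sample iff its value compares
    favourably with ``threshold`` under ``cmp``: ``"ge"`` (default) keeps
    values >= threshold, ``"gt"`` keeps values strictly greater. With the
    default an FPKM of exactly 2.0 counts as expressed.

    Idempotent, and monotone in the threshold: raising it never adds
    expressed calls.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if cmp not in ("ge", "gt"):
        raise ValueError(f"cmp must be 'ge' or 'gt', got {cmp!r}")
    mask = matrix >= threshold if cmp == "ge" else matrix > threshold
    return matrix.where(mask, 0.0)


def normalize_to_max(called):
    """Divide each gene's row by its maximum; all-zero rows stay all-zero.

    Every non-silent row of the result has maximum exactly 1.
    """
    row_max = called.max(axis=1)
    divisor = row_max.where(row_max > 0, 1.0)
    return called.div(divisor, axis=0)


def expressed_set(called, sample_id):
    """Genes called expressed (value > 0) in one sample, as a frozenset."""
    if sample_id not in called.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    column = called[sample_id]
    return frozenset(column.index[column > 0])
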