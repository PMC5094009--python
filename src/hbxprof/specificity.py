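"""Expression breadth, class-level specificity summaries, widespread genes.

Breadth — the number of samples in which a gene is called expressed — is
the specificity statistic: low breadth means high tissue specificity.
Class summaries are Tukey five-number summaries (hinges, whiskers at the
furthest point within 1.5 x IQR of the hinges, outliers beyond), the
convention of R's ``boxplot``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def breadth(called, sample_subset=None):
    """Per-gene count of samples with a positive called value.

    ``sample_subset`` restricts the count to those samples (e.g. adult
    tissues only); by default every sample in the matrix counts. Breadth
    is invariant under per-gene max-normalization and under sample
    permutation. The returned Series carries ``attrs['n_samples']``, the
    size of the sample universe counted over.
    """
    if sample_subset is not None:
        subset = list(sample_subset)
        unknown = [s for s in subset if s not in called.columns]
        if unknown:
            raise KeyError(f"unknown sample(s) in subset: {unknown}")
        sub = called[[c for c in called.columns if c in set(subset)]]
    else:
        sub = called
    counts = sub.gt(0).sum(axis=1).astype(int)
    counts.name = "breadth"
    counts.attrs["n_samples"] = sub.shape[1]
    return counts


def tukey_summary(values):
    """Tukey five-number summary with 1.5 x IQR whiskers.

    Hinges are medians of the lower/upper half of the sorted data, each
    half including the overall median when n is odd; whiskers extend to
    the furthest observation within 1.5 x (upper hinge - lower hinge) of
    the hinges; observations beyond the whiskers are outliers.

    Returns a dict with keys ``whisker_lo``, ``lower_hinge``, ``median``,
    ``upper_hinge``, ``whisker_hi`` and ``outlier_mask`` (boolean array
    aligned with the input order).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty data")
    order = np.sort(x)
    n = x.size
    half = (n + 1) // 2
    lower_hinge = float(np.median(order[:half]))
    upper_hinge = float(np.median(order[n - half:]))
    med = float(np.median(order))
    iqr = upper_hinge - lower_hinge
    lo_fence = lower_hinge - 1.5 * iqr
    hi_fence = upper_hinge + 1.5 * iqr
    inside = (x >= lo_fence) & (x <= hi_fence)
    whisker_lo = float(x[inside].min())
    whisker_hi = float(x[inside].max())
    return {
        "whisker_lo": whisker_lo,
        "lower_hinge": lower_hinge,
        "median": med,
        "upper_hinge": upper_hinge,
        "whisker_hi": whisker_hi,
        "outlier_mask": ~inside,
    }


def class_summary(breadth_table, gene_ann):
    """Five-number breadth summary per homeobox class.

    Every gene in the breadth table must be annotated. Classes with no
    genes are omitted with a warning. Outlier gene identifiers (beyond
    the whiskers) are listed per class.

    Returns a DataFrame indexed by class with columns ``n_genes``,
    ``whisker_lo``, ``lower_hinge``, ``median``, ``upper_hinge``,
    ``whisker_hi``, ``outliers`` (tuple of gene ids).
    """
    missing = [g for g in breadth_table.index if g not in gene_ann.index]
    if missing:
        raise KeyError(f"unannotated gene(s): {missing[:5]}")
    classes = gene_ann.loc[breadth_table.index, "hbx_class"]
    rows = {}
    for cls in classes.unique():
        members = breadth_table[classes == cls]
        if members.empty:
            warnings.warn(f"class {cls} has no genes; omitted from summary")
            continue
        summary = tukey_summary(members.to_numpy())
        outliers = tuple(members.index[summary.pop("outlier_mask")])
        rows[cls] = {"n_genes": int(members.size), **summary, "outliers": outliers}
    if not rows:
        warnings.warn("no class had any genes; summary is empty")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "hbx_class"
    return out


@dataclass(frozen=True)
class WidespreadResult:
    """Widespread genes with the route that produced them recorded."""

    genes: frozenset
    route: str  # "cluster" or "threshold"
    min_fraction: float | None = None


def classify_widespread(breadth_table=None, min_fraction=0.9, n_samples=None, groups=None):
    """Identify genes with widespread expression.

    Two routes:

    - *cluster route* (preferred when ``groups`` is supplied and contains
      a group labelled ``widespread``): the members of that cluster, the
      faithful analogue of reading the widespread block off the clustered
      heatmap;
    - *threshold route*: genes with breadth >= ``min_fraction`` x
      ``n_samples`` (``n_samples`` defaults to the universe recorded on
      the breadth table).
    """
    if groups is not None:
        widespread_labels = [lab for lab in groups.labels if lab.split("_")[0] == "widespread"]
        if widespread_labels:
            genes = frozenset(
                g for lab in widespread_labels for g in groups.members(lab)
            )
            return WidespreadResult(genes=genes, route="cluster")
    if breadth_table is None:
        raise ValueError("need a breadth table when no widespread cluster is available")
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if n_samples is None:
        n_samples = breadth_table.attrs.get("n_samples")
    if n_samples is None:
        raise ValueError("n_samples not given and not recorded on the breadth table")
    cutoff = min_fraction * n_samples
    genes = frozenset(breadth_table.index[breadth_table >= cutoff])
    return WidespreadResult(genes=genes, route="threshold", min_fraction=min_fraction)


def genes_per_sample(called):
    """Per-sample count of expressed genes (column-wise dual of breadth).

    Summed over samples it equals breadth summed over genes — each
    expressed (gene, sample) pair is counted exactly once either way.
    """
    counts = called.gt(0).sum(axis=0).astype(int)
    counts.name = "n_genes_expressed"
    return counts
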