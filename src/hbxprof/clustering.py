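"""Hierarchical clustering of normalized gene profiles into expression groups.

Genes are clustered by profile shape (Pearson-correlation distance on
max-normalized rows by default, average linkage), the dendrogram is cut
into a fixed number of groups, and each group is labelled from the sample
annotation: a cluster of broadly expressed genes is labelled
``widespread``, a cluster of silent genes ``no_expression``, and any other
cluster takes the dominant annotation group among its members' sites of
maximal expression (``neural``, ``immune``, ...).

Correlation distance is undefined on constant rows; pairs involving a
constant row fall back to the maximal distance (2.0) unless the two rows
are identical, in which case the distance is 0 — so silent genes cluster
together and apart from everything else, deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform


@dataclass(frozen=True)
class GeneDendrogram:
    """A gene merge tree: scipy linkage matrix plus identifier bookkeeping."""

    linkage: np.ndarray
    gene_ids: tuple
    leaf_order: tuple  # gene ids in dendrogram leaf order
    distance: str = "correlation"
    method: str = "average"

    @property
    def n_genes(self):
        return len(self.gene_ids)


@dataclass(frozen=True)
class ExpressionGroup:
    label: str
    genes: tuple
    ambiguous: bool = False


@dataclass(frozen=True)
class ExpressionGroupSet:
    """A labelled partition of the gene set into expression groups."""

    groups: tuple

    def __len__(self):
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)

    @property
    def labels(self):
        return tuple(g.label for g in self.groups)

    def members(self, label):
        for g in self.groups:
            if g.label == label:
                return g.genes
        raise KeyError(f"no group labelled {label!r}")

    def as_series(self):
        """gene_id -> group label, in group order."""
        index, values = [], []
        for g in self.groups:
            index.extend(g.genes)
            values.extend([g.label] * len(g.genes))
        return pd.Series(values, index=index, name="group")

    def validate_partition(self, gene_ids):
        members = [g for grp in self.groups for g in grp.genes]
        if len(members) != len(set(members)) or set(members) != set(gene_ids):
            raise ValueError("groups do not partition the gene set")


def _correlation_distances(X):
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.all():
        raise ValueError(
            "correlation distance is undefined on an all-constant matrix "
            "(e.g. all rows zero); use distance='euclidean'"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        D = squareform(pdist(X, metric="correlation"))
    if constant.any():
        nan = np.isnan(D)
        D[nan] = 2.0
        const_idx = np.flatnonzero(constant)
        for i in const_idx:
            equal = (X == X[i]).all(axis=1)
            D[i, equal] = 0.0
            D[equal, i] = 0.0
    np.fill_diagonal(D, 0.0)
    return squareform(D, checks=False)


def cluster_genes(norm, distance="correlation", linkage="average"):
    """Agglomeratively cluster gene rows of a normalized matrix.

    Parameters
    ----------
    norm : pandas.DataFrame
        Genes x samples matrix (normally the max-normalized profiles).
    distance : {"correlation", "euclidean"}
    linkage : {"average", "complete", "ward"}

    Returns
    -------
    GeneDendrogram
        Deterministic for given inputs; merge ties are resolved by
        scipy's ordering, which follows input gene order.
    """
    if len(norm.index) < 2:
        raise ValueError("clustering requires at least 2 genes")
    if distance not in ("correlation", "euclidean"):
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in ("average", "complete", "ward"):
        raise ValueError(f"unknown linkage {linkage!r}")
    X = norm.to_numpy(dtype=float)
    if distance == "correlation":
        condensed = _correlation_distances(X)
    else:
        condensed = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(condensed, method=linkage)
    leaves = hierarchy.leaves_list(Z)
    gene_ids = tuple(norm.index)
    return GeneDendrogram(
        linkage=Z,
        gene_ids=gene_ids,
        leaf_order=tuple(gene_ids[i] for i in leaves),
        distance=distance,
        method=linkage,
    )


def cut_groups(dend, k=None, height=None):
    """Cut a dendrogram into groups, by count or by merge height.

    Exactly one of ``k`` (number of groups, 1..n_genes) and ``height``
    (undo all merges above this height) must be given. Groups are ordered
    and provisionally labelled ``group_1`` .. ``group_k`` by first member
    appearance in input gene order; :func:`label_groups` assigns meaning.
    """
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k and height")
    n = dend.n_genes
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        labels = hierarchy.cut_tree(dend.linkage, n_clusters=k).ravel()
    else:
        if height < 0:
            raise ValueError(f"height must be >= 0, got {height}")
        labels = hierarchy.fcluster(dend.linkage, t=height, criterion="distance")
    order, members = [], {}
    for gene, lab in zip(dend.gene_ids, labels):
        if lab not in members:
            members[lab] = []
            order.append(lab)
        members[lab].append(gene)
    groups = tuple(
        ExpressionGroup(label=f"group_{i + 1}", genes=tuple(members[lab]))
        for i, lab in enumerate(order)
    )
    return ExpressionGroupSet(groups=groups)


def label_groups(groups, called, sample_ann, widespread_fraction=0.9):
    """Assign biological labels to expression groups.

    Rules, in order of precedence per group:

    1. every member row is all-zero -> ``no_expression``;
    2. median member breadth >= ``widespread_fraction`` of samples ->
       ``widespread``;
    3. otherwise the dominant sample-annotation ``group`` among the
       members' sites of maximal expression; a tie is broken by the
       lexicographically first label and flagged ``ambiguous``.

    Duplicate labels across clusters are suffixed ``_2``, ``_3``, ...
    """
    groups.validate_partition(called.index)
    n_samples = called.shape[1]
    sample_group = sample_ann["group"]
    labelled = []
    seen = {}
    for grp in groups:
        sub = called.loc[list(grp.genes)]
        nonzero = sub.gt(0)
        ambiguous = False
        if not nonzero.to_numpy().any():
            label = "no_expression"
        else:
            breadth = nonzero.sum(axis=1)
            if float(breadth.median()) >= widespread_fraction * n_samples:
                label = "widespread"
            else:
                active = sub[breadth > 0]
                peaks = active.idxmax(axis=1)
                counts = peaks.map(sample_group).value_counts()
                top = counts.max()
                dominant = sorted(counts.index[counts == top])
                label = dominant[0]
                ambiguous = len(dominant) > 1
        seen[label] = seen.get(label, 0) + 1
        if seen[label] > 1:
            label = f"{label}_{seen[label]}"
        labelled.append(ExpressionGroup(label=label, genes=grp.genes, ambiguous=ambiguous))
    return ExpressionGroupSet(groups=tuple(labelled))


def export_heatmap(norm, dend, matrix_path=None, image_path=None, cmap="RdBu_r"):
    """Write the leaf-ordered normalized matrix and/or a heatmap image.

    The TSV rows appear in dendrogram leaf order (the row order of the
    published-style heatmap); the image uses a blue (low) to red (high)
    palette over [0, 1] and its pixel dimensions scale with matrix shape.

    Returns the leaf-ordered matrix.
    """
    ordered = norm.loc[list(dend.leaf_order)]
    if matrix_path is not None:
        out = ordered.copy()
        out.index.name = "gene_id"
        out.to_csv(matrix_path, sep="\t")
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n_genes, n_samples = ordered.shape
        fig_w = max(4.0, 0.18 * n_samples)
        fig_h = max(3.0, 0.035 * n_genes)
        fig, ax = plt.subplots(figsize=(fig_w, fig_h))
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap=cmap, vmin=0.0, vmax=1.0)
        ax.set_xticks(range(n_samples))
        ax.set_xticklabels(ordered.columns, rotation=90, fontsize=5)
        ax.set_yticks([])
        ax.set_ylabel(f"{n_genes} genes (dendrogram leaf order)")
        fig.colorbar(im, ax=ax, label="expression / per-gene maximum")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return ordered
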