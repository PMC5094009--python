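"""Phase segmentation of stage-ordered developmental expression series.

Staged whole-embryo series (e.g. oocyte through mid-gestation) show
discrete "gear changes": positions between consecutive stages where the
set of expressed genes turns over sharply, separating phases of
comparatively stable gene activity. Turnover between consecutive stages
is quantified as the Jaccard distance between their expressed-gene sets —
threshold-consistent with the calling module — and the phase boundaries
are the positions with the largest turnover.

Boundary *position* convention: position ``p`` denotes the gap between
the stages of temporal rank order ``p`` and ``p + 1`` (``p`` ranges over
``0 .. n_stages - 2``). ``n_boundaries`` boundaries define
``n_boundaries + 1`` phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import expressed_set
from .clustering import cluster_genes, cut_groups


def stage_order(sample_ann, samples=None):
    """Sample ids sorted by temporal rank; every sample must be ranked."""
    ann = sample_ann if samples is None else sample_ann.loc[list(samples)]
    ranks = ann["temporal_rank"]
    unranked = list(ranks.index[ranks.isna()])
    if unranked:
        raise ValueError(f"sample(s) without temporal_rank: {unranked}")
    return list(ranks.sort_values().index)


def jaccard_distance(a, b):
    """1 - |a ∩ b| / |a ∪ b|; defined as 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def stage_turnover(called, sample_ann):
    """Jaccard turnover of the expressed-gene set between consecutive stages.

    Returns a DataFrame with one row per boundary position: ``position``,
    ``left_stage``, ``right_stage``, ``turnover`` (in [0, 1]). Genes
    never expressed in the series contribute to no expressed set and so
    never to turnover.
    """
    stages = stage_order(sample_ann, samples=called.columns)
    if len(stages) < 2:
        raise ValueError("turnover requires at least 2 ranked stages")
    sets = [expressed_set(called, s) for s in stages]
    rows = [
        {
            "position": p,
            "left_stage": stages[p],
            "right_stage": stages[p + 1],
            "turnover": jaccard_distance(sets[p], sets[p + 1]),
        }
        for p in range(len(stages) - 1)
    ]
    return pd.DataFrame(rows)


def detect_boundaries(turnover, n_boundaries):
    """Positions of the ``n_boundaries`` largest turnover scores.

    ``turnover`` is the DataFrame from :func:`stage_turnover` or a plain
    score sequence. Ties are broken toward the earlier position; the
    result is sorted ascending.
    """
    if isinstance(turnover, pd.DataFrame):
        scores = turnover["turnover"].to_numpy(dtype=float)
        positions = turnover["position"].to_numpy(dtype=int)
    else:
        scores = np.asarray(turnover, dtype=float)
        positions = np.arange(scores.size)
    n_stages = scores.size + 1
    if not 1 <= n_boundaries < n_stages:
        raise ValueError(
            f"n_boundaries must be in [1, {n_stages - 1}], got {n_boundaries}"
        )
    order = np.argsort(-scores, kind="stable")  # stable: ties -> earlier position
    chosen = sorted(int(positions[i]) for i in order[:n_boundaries])
    return tuple(chosen)


@dataclass(frozen=True)
class PhaseAssignment:
    """Detected phase boundaries plus per-gene temporal groups.

    ``groups`` is indexed by gene with columns ``group`` (temporal group
    id, ``silent`` for genes never expressed in the series),
    ``onset_rank`` and ``offset_rank`` (first/last expressed temporal
    rank; NaN for silent genes).
    """

    boundaries: tuple
    turnover: pd.DataFrame
    groups: pd.DataFrame

    @property
    def n_phases(self):
        return len(self.boundaries) + 1


def _onset_offset(row_positive, rank_of_position):
    hits = np.flatnonzero(row_positive)
    if hits.size == 0:
        return (np.nan, np.nan)
    return (rank_of_position[hits[0]], rank_of_position[hits[-1]])


def assign_temporal_groups(norm, sample_ann, k, distance="correlation", linkage="average"):
    """Cluster stage-ordered profiles into k temporal groups.

    Delegates to the profile-clustering module on the stage-ordered
    matrix; genes never expressed in the series form a reserved
    ``silent`` group outside the k clusters. Groups are numbered
    ``temporal_1`` .. ``temporal_k`` by median onset rank, and each gene
    is summarised by onset (first expressed rank) and offset (last
    expressed rank); onset <= offset for every expressed gene.
    """
    stages = stage_order(sample_ann, samples=norm.columns)
    ordered = norm[stages]
    ranks = sample_ann.loc[stages, "temporal_rank"].astype(int).to_numpy()
    positive = ordered.gt(0)
    silent_mask = ~positive.any(axis=1)
    active = ordered[~silent_mask]
    out = pd.DataFrame(
        index=ordered.index, columns=["group", "onset_rank", "offset_rank"]
    )
    out["group"] = "silent"
    out["onset_rank"] = np.nan
    out["offset_rank"] = np.nan
    for gene in active.index:
        onset, offset = _onset_offset(positive.loc[gene].to_numpy(), ranks)
        out.at[gene, "onset_rank"] = onset
        out.at[gene, "offset_rank"] = offset
    if len(active.index) == 0:
        return out
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    k_eff = min(k, len(active.index))
    if len(active.index) == 1:
        out.loc[active.index, "group"] = "temporal_1"
        return out
    dend = cluster_genes(active, distance=distance, linkage=linkage)
    raw_groups = cut_groups(dend, k=k_eff)
    onsets = out["onset_rank"]
    keyed = sorted(
        raw_groups,
        key=lambda g: (float(onsets.loc[list(g.genes)].median()), g.label),
    )
    for i, grp in enumerate(keyed, start=1):
        out.loc[list(grp.genes), "group"] = f"temporal_{i}"
    return out


def segment_phases(called, norm, sample_ann, n_boundaries=3, k=None):
    """Full phase segmentation: turnover, boundaries, temporal groups.

    ``k`` defaults to ``n_boundaries + 1``, one temporal group per phase.
    """
    turnover = stage_turnover(called, sample_ann)
    boundaries = detect_boundaries(turnover, n_boundaries)
    if k is None:
        k = n_boundaries + 1
    groups = assign_temporal_groups(norm, sample_ann, k=k)
    return PhaseAssignment(boundaries=boundaries, turnover=turnover, groups=groups)
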