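"""Tissue-set exclusivity: genes expressed only in a designated sample set.

The filter is deterministic: a gene is exclusive to a target set iff it is
called expressed in at least one target sample and called zero in every
non-target sample. For each exclusive gene the peak sample (site of
maximal called expression within the targets) is recorded, so that genes
whose peak falls in a given developmental window (e.g. 8-cell to morula)
can be pulled out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger("hbxprof")


@dataclass(frozen=True)
class ExclusivityResult:
    """Exclusive genes with per-gene peak sample and value.

    ``table`` is indexed by gene with columns ``peak_stage``,
    ``peak_value`` and ``peak_tied`` (True when the maximum is attained
    at more than one target sample; the reported peak is then the
    earliest by temporal rank, or by matrix column order for unranked
    samples).
    """

    target_samples: frozenset
    table: pd.DataFrame

    @property
    def exclusive_genes(self):
        return tuple(self.table.index)


def _ordered_targets(called, target_samples, sample_ann=None):
    targets = [c for c in called.columns if c in target_samples]
    if sample_ann is None:
        return targets
    ranks = sample_ann["temporal_rank"]

    def key(sample):
        position = targets.index(sample)
        rank = ranks.get(sample, pd.NA) if sample in ranks.index else pd.NA
        if pd.isna(rank):
            return (1, position)
        return (0, int(rank), position)

    return sorted(targets, key=key)


def exclusive_to(called, target_samples, sample_ann=None):
    """Genes expressed in >= 1 target sample and silent in all others.

    Parameters
    ----------
    called : pandas.DataFrame
        Called matrix (sub-threshold values already zeroed).
    target_samples : iterable of sample ids
        Non-empty proper subset of the matrix samples.
    sample_ann : pandas.DataFrame, optional
        When given, peak ties are resolved to the earliest temporal
        rank; otherwise to the first target in matrix column order.
    """
    targets = frozenset(target_samples)
    unknown = [s for s in targets if s not in called.columns]
    if unknown:
        raise KeyError(f"unknown target sample(s): {sorted(unknown)}")
    if not targets:
        raise ValueError("target set must not be empty")
    if len(targets) == len(called.columns):
        raise ValueError("target set must be a proper subset of the matrix samples")
    target_cols = _ordered_targets(called, targets, sample_ann)
    other_cols = [c for c in called.columns if c not in targets]
    T = called[target_cols]
    N = called[other_cols]
    mask = T.gt(0).any(axis=1) & N.eq(0).all(axis=1)
    sub = T[mask]
    peak_value = sub.max(axis=1)
    peak_stage = sub.idxmax(axis=1)  # first (earliest-ordered) maximum
    peak_tied = sub.eq(peak_value, axis=0).sum(axis=1) > 1
    table = pd.DataFrame(
        {"peak_stage": peak_stage, "peak_value": peak_value, "peak_tied": peak_tied}
    )
    return ExclusivityResult(target_samples=targets, table=table)


def peak_in_window(result, sample_ann, window):
    """Exclusive genes whose peak sample's temporal rank lies in a window.

    ``window`` is an inclusive ``(rank_lo, rank_hi)`` pair of temporal
    ranks. Genes peaking at unranked samples (e.g. adult tissues inside
    the target set) are never in the window. Returns a frozenset.
    """
    rank_lo, rank_hi = window
    ranks = sample_ann["temporal_rank"].dropna()
    if ranks.empty:
        raise ValueError("no sample carries a temporal_rank")
    lo_bound, hi_bound = int(ranks.min()), int(ranks.max())
    if rank_lo > rank_hi:
        raise ValueError(f"window lower bound {rank_lo} exceeds upper bound {rank_hi}")
    if rank_lo < lo_bound or rank_hi > hi_bound:
        raise ValueError(
            f"window [{rank_lo}, {rank_hi}] outside the ranked range "
            f"[{lo_bound}, {hi_bound}]"
        )
    peak_rank = result.table["peak_stage"].map(lambda s: ranks.get(s, pd.NA))
    in_window = peak_rank.map(
        lambda r: (not pd.isna(r)) and rank_lo <= int(r) <= rank_hi
    )
    return frozenset(result.table.index[in_window])


def augment_target_set(target_samples, extra_samples, all_samples):
    """Union a target set with manual additions, validating membership.

    Mirrors curation steps where a biologically related sample that did
    not co-cluster with the target group (e.g. ovary) is added by hand;
    additions are logged for provenance.
    """
    universe = set(all_samples)
    extras = list(extra_samples)
    unknown = [s for s in extras if s not in universe]
    if unknown:
        raise KeyError(f"unknown sample(s): {unknown}")
    base = frozenset(target_samples)
    added = [s for s in extras if s not in base]
    if added:
        logger.info("augment_target_set: manually added %s", added)
    return base | frozenset(extras)
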