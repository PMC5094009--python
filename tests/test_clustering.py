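import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from hbxprof import (
    cluster_genes,
    cut_groups,
    export_heatmap,
    label_groups,
    normalize_to_max,
)


def profile_matrix(rows, genes=None, samples=None):
    arr = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        arr,
        index=genes or [f"g{i}" for i in range(arr.shape[0])],
        columns=samples or [f"s{j}" for j in range(arr.shape[1])],
    )


def two_block_matrix(n_per_block=10, n_samples=8, seed=0):
    """Two gene blocks expressed in disjoint sample halves, zero noise."""
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    left = rng.uniform(2, 20, size=half)
    right = rng.uniform(2, 20, size=n_samples - half)
    rows = []
    for i in range(n_per_block):
        rows.append(np.concatenate([left * (1 + 0.01 * i), np.zeros(n_samples - half)]))
    for i in range(n_per_block):
        rows.append(np.concatenate([np.zeros(half), right * (1 + 0.01 * i)]))
    return profile_matrix(rows), ["A"] * n_per_block + ["B"] * n_per_block


def test_identical_profiles_merge_first_at_height_zero():
    m = profile_matrix([[1, 0, 2], [1, 0, 2], [0, 5, 1]])
    dend = cluster_genes(normalize_to_max(m), distance="euclidean")
    first = dend.linkage[0]
    assert {int(first[0]), int(first[1])} == {0, 1}
    assert first[2] == 0.0


def test_hand_computed_first_merge_euclidean_average():
    # d(g0,g1)=0 < d(g0,g2)=d(g1,g2)=sqrt(2): first merge is g0,g1
    m = profile_matrix([[1, 0], [1, 0], [0, 1]])
    dend = cluster_genes(m, distance="euclidean", linkage="average")
    first = dend.linkage[0]
    assert {int(first[0]), int(first[1])} == {0, 1}
    np.testing.assert_allclose(dend.linkage[1][2], np.sqrt(2), rtol=1e-12)


def test_linkage_heights_non_decreasing(norm_panel):
    dend = cluster_genes(norm_panel)
    heights = dend.linkage[:, 2]
    assert (np.diff(heights) >= -1e-12).all()


def test_all_zero_matrix_with_correlation_is_an_error():
    m = profile_matrix(np.zeros((3, 4)))
    with pytest.raises(ValueError, match="euclidean"):
        cluster_genes(m, distance="correlation")


class TestCutGroups:
    def test_planted_two_block_recovery(self):
        m, truth = two_block_matrix()
        dend = cluster_genes(normalize_to_max(m))
        groups = cut_groups(dend, k=2)
        pred = groups.as_series().loc[m.index]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_extreme_k_values(self):
        m, _ = two_block_matrix(n_per_block=3)
        dend = cluster_genes(normalize_to_max(m))
        singletons = cut_groups(dend, k=len(m.index))
        assert all(len(g.genes) == 1 for g in singletons)
        everything = cut_groups(dend, k=1)
        assert len(everything) == 1 and set(everything.groups[0].genes) == set(m.index)
        with pytest.raises(ValueError):
            cut_groups(dend, k=0)

    def test_cuts_are_nested_refinements(self, norm_panel):
        dend = cluster_genes(norm_panel)
        coarse = cut_groups(dend, k=4).as_series()
        fine = cut_groups(dend, k=5).as_series()
        # every fine group maps into exactly one coarse group
        mapping = pd.DataFrame({"fine": fine, "coarse": coarse.loc[fine.index]})
        assert (mapping.groupby("fine")["coarse"].nunique() == 1).all()

    def test_row_permutation_invariance_up_to_relabelling(self):
        m, _ = two_block_matrix(seed=5)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(m.index))
        shuffled = m.iloc[perm]
        a = cut_groups(cluster_genes(normalize_to_max(m)), k=2).as_series()
        b = cut_groups(cluster_genes(normalize_to_max(shuffled)), k=2).as_series()
        joined = pd.concat([a, b.loc[a.index]], axis=1, keys=["a", "b"])
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0


class TestLabelGroups:
    def _sample_ann(self, samples, groups):
        return pd.DataFrame(
            {
                "sample_id": samples,
                "category": "adult_tissue",
                "group": groups,
                "temporal_rank": pd.NA,
            }
        ).set_index("sample_id")

    def test_dominant_peak_group_silent_and_tie(self):
        samples = ["n1", "n2", "i1", "i2"]
        ann = self._sample_ann(samples, ["neural", "neural", "immune", "immune"])
        called = profile_matrix(
            [
                [9, 5, 0, 0],   # peaks neural
                [5, 8, 2, 0],   # peaks neural
                [0, 0, 0, 0],   # silent
                [6, 0, 5, 0],   # neural peak (tie group below)
                [5, 0, 6, 0],   # immune peak
            ],
            samples=samples,
        )
        dend = cluster_genes(normalize_to_max(called), distance="euclidean")
        groups = cut_groups(dend, k=3)
        labelled = label_groups(groups, called, ann)
        by_label = {lab: set(labelled.members(lab)) for lab in labelled.labels}
        assert by_label["neural"] == {"g0", "g1"}
        assert by_label["no_expression"] == {"g2"}
        # g3 peaks neural, g4 peaks immune: one of each -> tie, lexicographic
        tie_group = [g for g in labelled if set(g.genes) == {"g3", "g4"}][0]
        assert tie_group.label.startswith("immune")
        assert tie_group.ambiguous

    def test_broad_cluster_labelled_widespread(self):
        samples = ["a", "b", "c", "d"]
        ann = self._sample_ann(samples, ["organ", "organ", "neural", "immune"])
        called = profile_matrix(
            [[4, 5, 6, 7], [7, 6, 5, 4], [0, 0, 9, 0], [0, 0, 8, 0]],
            samples=samples,
        )
        dend = cluster_genes(normalize_to_max(called), distance="euclidean")
        labelled = label_groups(cut_groups(dend, k=2), called, ann)
        assert set(labelled.members("widespread")) == {"g0", "g1"}


class TestExportHeatmap:
    def test_tsv_rows_in_leaf_order_and_deterministic(self, tmp_path):
        m, _ = two_block_matrix(n_per_block=3)
        norm = normalize_to_max(m)
        dend = cluster_genes(norm)
        first = tmp_path / "a.tsv"
        second = tmp_path / "b.tsv"
        export_heatmap(norm, dend, matrix_path=first)
        export_heatmap(norm, dend, matrix_path=second)
        ordered = pd.read_csv(first, sep="\t", index_col=0)
        assert list(ordered.index) == list(dend.leaf_order)
        assert first.read_bytes() == second.read_bytes()

    def test_image_dimensions_scale_with_matrix_shape(self, tmp_path):
        from PIL import Image

        small, _ = two_block_matrix(n_per_block=3, n_samples=6)
        big, _ = two_block_matrix(n_per_block=80, n_samples=30)
        sizes = {}
        for name, m in (("small", small), ("big", big)):
            norm = normalize_to_max(m)
            dend = cluster_genes(norm)
            path = tmp_path / f"{name}.png"
            export_heatmap(norm, dend, image_path=path)
            with Image.open(path) as img:
                sizes[name] = img.size
        assert sizes["big"][0] > sizes["small"][0]
        assert sizes["big"][1] > sizes["small"][1]
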