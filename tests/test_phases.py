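import numpy as np
import pandas as pd
import pytest

from hbxprof import (
    call_expression,
    corrupt,
    detect_boundaries,
    generate_staged_series,
    jaccard_distance,
    normalize_to_max,
    segment_phases,
    stage_turnover,
)


def staged_ann(n):
    return pd.DataFrame(
        {
            "sample_id": [f"st{i}" for i in range(n)],
            "category": "developmental_stage",
            "group": "embryo",
            "temporal_rank": pd.array(range(n), dtype="Int64"),
        }
    ).set_index("sample_id")


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ({"A", "B"}, {"A", "B"}, 0.0),
        ({"A"}, {"B"}, 1.0),
        ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),  # 1 - 2/4
        (set(), set(), 0.0),
        (set(), {"A"}, 1.0),
    ],
)
def test_jaccard_distance_hand_values(a, b, expected):
    assert jaccard_distance(a, b) == expected


def test_turnover_scores_per_consecutive_stage_pair():
    ann = staged_ann(3)
    called = pd.DataFrame(
        [[3, 3, 0], [4, 4, 0], [5, 5, 5], [0, 4, 4]],
        index=["gA", "gB", "gC", "gD"],
        columns=ann.index,
        dtype=float,
    )
    turnover = stage_turnover(called, ann)
    # st0={A,B,C} vs st1={A,B,C,D}: 1-3/4; st1 vs st2={C,D}: 1-2/4
    np.testing.assert_allclose(turnover["turnover"], [0.25, 0.5])
    assert list(turnover["position"]) == [0, 1]


def test_turnover_requires_ranked_samples():
    ann = staged_ann(3)
    ann.loc["st1", "temporal_rank"] = pd.NA
    called = pd.DataFrame(
        np.ones((2, 3)) * 3, index=["gA", "gB"], columns=ann.index
    )
    with pytest.raises(ValueError, match="temporal_rank"):
        stage_turnover(called, ann)


def test_turnover_reverses_with_stage_order(mouse_series):
    called = call_expression(mouse_series.matrix)
    forward = stage_turnover(called, mouse_series.sample_ann)
    ann_rev = mouse_series.sample_ann.copy()
    n = len(ann_rev)
    ann_rev["temporal_rank"] = pd.array(
        [n - 1 - int(r) for r in ann_rev["temporal_rank"]], dtype="Int64"
    )
    backward = stage_turnover(called, ann_rev)
    np.testing.assert_allclose(
        forward["turnover"].to_numpy(), backward["turnover"].to_numpy()[::-1]
    )
    assert (forward["turnover"] >= 0).all() and (forward["turnover"] <= 1).all()


class TestDetectBoundaries:
    def test_argmax_and_tie_rules(self):
        assert detect_boundaries([0.1, 0.9, 0.2], 1) == (1,)
        # tie broken toward the earlier position
        assert detect_boundaries([0.5, 0.9, 0.9], 1) == (1,)
        assert detect_boundaries([0.9, 0.1, 0.9], 2) == (0, 2)

    def test_every_gap_when_n_is_maximal(self):
        assert detect_boundaries([0.3, 0.1, 0.2], 3) == (0, 1, 2)

    def test_out_of_range_n(self):
        with pytest.raises(ValueError):
            detect_boundaries([0.3, 0.1], 0)
        with pytest.raises(ValueError):
            detect_boundaries([0.3, 0.1], 3)

    def test_planted_boundaries_recovered_at_zero_noise(self):
        series = generate_staged_series(boundaries=(2, 5, 9), seed=13)
        called = call_expression(series.matrix)
        turnover = stage_turnover(called, series.sample_ann)
        assert detect_boundaries(turnover, 3) == (2, 5, 9)


class TestTemporalGroups:
    def test_onset_offset_and_silent_group(self, mouse_series):
        called = call_expression(mouse_series.matrix)
        norm = normalize_to_max(called)
        assignment = segment_phases(called, norm, mouse_series.sample_ann, n_boundaries=3)
        groups = assignment.groups
        truth = mouse_series.truth
        # maternal archetype spans ranks 0-1, the EGA burst exactly rank 2
        maternal = truth.index[truth.archetype == "maternal"]
        assert (groups.loc[maternal, "onset_rank"] == 0).all()
        assert (groups.loc[maternal, "offset_rank"] == 1).all()
        burst = truth.index[truth.archetype == "ega_burst"]
        assert (groups.loc[burst, "onset_rank"] == 2).all()
        assert (groups.loc[burst, "offset_rank"] == 2).all()
        late = truth.index[truth.archetype == "postimplantation"]
        assert (groups.loc[late, "onset_rank"] == 7).all()
        silent = truth.index[truth.archetype == "silent"]
        assert (groups.loc[silent, "group"] == "silent").all()
        # onset <= offset for every expressed gene
        expressed = groups["group"] != "silent"
        assert (
            groups.loc[expressed, "onset_rank"] <= groups.loc[expressed, "offset_rank"]
        ).all()
        assert assignment.boundaries == mouse_series.boundaries
        assert assignment.n_phases == 4

    def test_temporal_groups_match_planted_phases(self, mouse_series):
        called = call_expression(mouse_series.matrix)
        norm = normalize_to_max(called)
        assignment = segment_phases(called, norm, mouse_series.sample_ann, n_boundaries=3)
        groups = assignment.groups
        truth = mouse_series.truth
        active = truth[truth.archetype != "silent"]
        # one temporal group per planted phase, numbered by onset
        expected = {
            "maternal": "temporal_1",
            "ega_burst": "temporal_2",
            "cleavage_blastocyst": "temporal_3",
            "postimplantation": "temporal_4",
        }
        for archetype, group_id in expected.items():
            members = active.index[active.archetype == archetype]
            assert (groups.loc[members, "group"] == group_id).all()


def test_boundary_recovery_degrades_gracefully_under_noise():
    """With 5% dropout and multiplicative noise, >= 2 of 3 planted
    boundaries are still found in >= 95% of replicates."""
    n_reps = 200
    hits = 0
    for rep in range(n_reps):
        series = generate_staged_series(seed=5000 + rep)
        noisy = corrupt(series.matrix, dropout_rate=0.05, noise_scale=0.3,
                        seed=9000 + rep)
        called = call_expression(noisy)
        turnover = stage_turnover(called, series.sample_ann)
        found = detect_boundaries(turnover, 3)
        if len(set(found) & set(series.boundaries)) >= 2:
            hits += 1
    assert hits / n_reps >= 0.95
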