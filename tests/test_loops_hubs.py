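"""Loop merging, shuffling, hub calling, and hub label definitions."""

import numpy as np
import pandas as pd
import pytest

from topodyn.loops_hubs import (
    call_hubs,
    classify_hub_dynamics,
    classify_hub_pc1_trend,
    hub_feature_overlap,
    merge_loops_across_timepoints,
    shuffle_loops,
)
from topodyn.genome_model import IntervalSet, LoopSet

from conftest import make_intervals, make_loops

CHROMS = {"chr1": 1_000_000}


class TestMergeLoops:
    def test_identical_loop_in_all_sets(self):
        loop = [("chr1", 100_000, 110_000, 500_000, 510_000)]
        sets = {f"t{k}": make_loops(loop) for k in range(4)}
        union, hist = merge_loops_across_timepoints(sets, 10_000)
        assert len(union) == 1
        assert union.iloc[0]["n_timepoints"] == 4
        assert hist.to_dict() == {4: 1}

    def test_unique_loop(self):
        sets = {
            "a": make_loops([("chr1", 100_000, 110_000, 500_000, 510_000)]),
            "b": make_loops([("chr1", 300_000, 310_000, 700_000, 710_000)]),
        }
        union, hist = merge_loops_across_timepoints(sets, 10_000)
        assert len(union) == 2 and hist.to_dict() == {1: 2}

    def test_two_bin_offset_not_merged(self):
        sets = {
            "a": make_loops([("chr1", 100_000, 110_000, 500_000, 510_000)]),
            "b": make_loops([("chr1", 120_000, 130_000, 500_000, 510_000)]),
        }
        union, _ = merge_loops_across_timepoints(sets, 10_000, anchor_tolerance=1)
        assert len(union) == 2

    def test_one_bin_offset_merged(self):
        sets = {
            "a": make_loops([("chr1", 100_000, 110_000, 500_000, 510_000)]),
            "b": make_loops([("chr1", 110_000, 120_000, 510_000, 520_000)]),
        }
        union, _ = merge_loops_across_timepoints(sets, 10_000, anchor_tolerance=1)
        assert len(union) == 1


class TestShuffleLoops:
    def _loops(self):
        return make_loops(
            [
                ("chr1", 100_000, 110_000, 500_000, 515_000),
                ("chr1", 0, 5_000, 900_000, 910_000),
            ]
        )

    def test_widths_and_spans_preserved(self):
        loops = self._loops()
        orig = loops.df
        def shape_multiset(df):
            return sorted(
                zip(df["endA"] - df["startA"], df["startB"] - df["startA"],
                    df["endB"] - df["startB"])
            )

        for null in shuffle_loops(loops, CHROMS, n=10, seed=0):
            df = null.df
            assert shape_multiset(df) == shape_multiset(orig)
            assert (df["endB"] <= CHROMS["chr1"]).all()
            assert (df["startA"] >= 0).all()

    def test_seed_determinism(self):
        a = shuffle_loops(self._loops(), CHROMS, n=5, seed=9)
        b = shuffle_loops(self._loops(), CHROMS, n=5, seed=9)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.df, y.df)

    def test_overlong_loop_dropped(self):
        loops = make_loops([("chr1", 0, 10_000, 995_000, 1_000_000)])
        with pytest.warns(UserWarning, match="dropped"):
            nulls = shuffle_loops(loops, {"chr1": 900_000}, n=2, seed=0)
        assert all(len(n) == 0 for n in nulls)

    def test_midpoints_roughly_uniform(self):
        """Over many nulls the placements cover the chromosome uniformly."""
        loops = make_loops([("chr1", 100_000, 101_000, 200_000, 201_000)])
        starts = [
            n.df.iloc[0]["startA"] for n in shuffle_loops(loops, CHROMS, n=300, seed=4)
        ]
        from scipy import stats

        placeable = CHROMS["chr1"] - 101_000
        p = stats.kstest(np.array(starts) / placeable, "uniform").pvalue
        assert p > 0.001


def _loops_with_feet(feet_positions, partner=700_000, width=1_000):
    rows = [
        ("chr1", p, p + width, partner + 40_000 * i, partner + 40_000 * i + width)
        for i, p in enumerate(feet_positions)
    ]
    return make_loops(rows)


class TestCallHubs:
    def test_five_feet_within_30kb_is_a_hub(self):
        loops = _loops_with_feet([100_000, 105_000, 110_000, 115_000, 120_000])
        hubs = call_hubs({"t0": loops}, CHROMS)
        covering = hubs[(hubs["start"] <= 100_000) & (hubs["end"] >= 121_000)]
        assert len(covering) == 1
        assert covering.iloc[0]["present_t0"]

    def test_four_feet_is_not_a_hub(self):
        loops = _loops_with_feet([100_000, 105_000, 110_000, 115_000])
        hubs = call_hubs({"t0": loops}, {"chr1": 500_000})
        # partner feet are isolated too, so nothing anywhere reaches 5
        assert len(hubs) == 0

    def test_gap_above_stitch_limit_keeps_hubs_apart(self):
        left = [100_000 + i * 5_000 for i in range(5)]
        right = [100_000 + 121_000 + 30_001 + i * 5_000 for i in range(5)]
        loops = _loops_with_feet(left + right)
        hubs = call_hubs({"t0": loops}, CHROMS)
        assert (hubs["present_t0"]).sum() == 2

    def test_translation_equivariance(self):
        feet = [100_000, 105_000, 110_000, 115_000, 120_000]
        step = 3_000
        h1 = call_hubs({"t0": _loops_with_feet(feet)}, CHROMS)
        h2 = call_hubs(
            {"t0": _loops_with_feet([p + step for p in feet], partner=700_000 + step)},
            CHROMS,
        )
        np.testing.assert_array_equal(
            h2["start"].to_numpy(), h1["start"].to_numpy() + step
        )
        np.testing.assert_array_equal(h2["end"].to_numpy(), h1["end"].to_numpy() + step)


class TestHubDynamics:
    @pytest.mark.parametrize(
        "presence,label",
        [
            ([1, 1, 1, 1], "stable"),
            ([0, 0, 1, 1], "gained"),
            ([0, 1, 1, 1], "gained"),
            ([1, 1, 0, 0], "lost"),
            ([1, 0, 0, 0], "lost"),
            ([1, 0, 1, 1], "other"),
            ([0, 1, 0, 1], "other"),
            ([0, 0, 0, 0], "other"),
        ],
    )
    def test_definitions(self, presence, label):
        assert classify_hub_dynamics(presence) == label


class TestPc1Trend:
    @pytest.mark.parametrize(
        "means,label",
        [
            ([-0.2, 0.0, 0.1, 0.1, 0.3], "stable_increase"),
            ([0.3, 0.2, 0.1, 0.1, -0.2], "stable_decrease"),
            ([0.1, 0.1, 0.1, 0.1, 0.1], "other"),  # last not strictly above first
            ([0.3, 0.1, 0.2, 0.2, 0.4], "other"),  # dip breaks monotonicity
        ],
    )
    def test_definitions(self, means, label):
        assert classify_hub_pc1_trend(means) == label

    def test_missing_mean_unlabeled(self):
        assert classify_hub_pc1_trend([0.1, np.nan, 0.3]) is None


class TestHubFeatureOverlap:
    def test_identical_features_fully_overlapped(self):
        hubs = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100_000], "end": [200_000], "present_t0": [True]}
        )
        feats = IntervalSet(
            pd.DataFrame(
                {"chrom": ["chr1"] * 4, "start": [100_000] * 4, "end": [200_000] * 4,
                 "score": [1.0, 2.0, 3.0, 4.0]}
            )
        )
        out = hub_feature_overlap(hubs, feats, ["t0"])
        assert (out["fraction_overlapped"] == 1.0).all()

    def test_disjoint_features_zero(self):
        hubs = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100_000], "end": [200_000], "present_t0": [True]}
        )
        feats = IntervalSet(
            pd.DataFrame({"chrom": ["chr1"] * 4, "start": [300_000] * 4,
                          "end": [310_000] * 4, "score": [1.0, 2.0, 3.0, 4.0]})
        )
        out = hub_feature_overlap(hubs, feats, ["t0"])
        assert (out["fraction_overlapped"] == 0.0).all()
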