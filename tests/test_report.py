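"""Factor ranking, level assignment and the assembled report."""

import json

import numpy as np
import pandas as pd
import pytest

from attnquality import (
    assess_cohort,
    assign_levels,
    expert_threshold_labels,
    rank_factor_labels,
)

#: 3-dim centroids of the four canonical quality groups (W, H, E)
CANONICAL_CENTROIDS = np.array([
    [0.2714, 0.6032, 0.0510],
    [0.5789, 0.6675, 0.0680],
    [0.3980, 0.6683, 0.5880],
    [0.6590, 0.6490, 0.8619],
])

EXPECTED_LABELS = pd.DataFrame(
    {
        "span": ["Bottom", "Moderate", "Low", "High"],
        "stability": ["Bottom", "Moderate", "High", "Low"],
        "distribution_shift": ["High", "Moderate", "Low", "Bottom"],
    },
    index=pd.Index(range(4), name="cluster"),
)


class TestFactorLabels:
    def test_canonical_centroids_reproduce_expected_grid(self):
        labels = rank_factor_labels(CANONICAL_CENTROIDS).labels
        pd.testing.assert_frame_equal(labels, EXPECTED_LABELS)

    def test_permutation_equivariance(self):
        perm = [2, 0, 3, 1]
        permuted = rank_factor_labels(CANONICAL_CENTROIDS[perm]).labels
        expected = EXPECTED_LABELS.iloc[perm].reset_index(drop=True)
        expected.index = pd.Index(range(4), name="cluster")
        pd.testing.assert_frame_equal(permuted, expected)

    def test_each_factor_is_a_permutation_of_the_four_names(self):
        labels = rank_factor_labels(CANONICAL_CENTROIDS).labels
        for col in labels:
            assert sorted(labels[col]) == sorted(
                ["High", "Moderate", "Low", "Bottom"])

    def test_identical_centroids_flag_ties(self):
        with pytest.warns(UserWarning, match="ties"):
            out = rank_factor_labels(np.tile([0.5, 0.5, 0.5], (4, 1)))
        assert out.ties
        # index order breaks the ties deterministically
        assert list(out.ranks["span"]) == [1, 2, 3, 4]

    def test_non_four_k_gives_numeric_ranks_only(self):
        out = rank_factor_labels(CANONICAL_CENTROIDS[:3])
        assert out.labels is None
        assert set(out.ranks["span"]) == {1, 2, 3}


class TestLevels:
    def test_rank_sums_and_ordering(self):
        fl = rank_factor_labels(CANONICAL_CENTROIDS)
        levels = assign_levels(fl, CANONICAL_CENTROIDS)
        assert sorted(levels.scores) == [6, 7, 8, 9]
        # the moderate-W / low-E cluster is the best overall
        assert levels.levels[1] == 1
        assert levels.names[1] == "Excellent"
        assert levels.levels[0] == 4  # bottom span, bottom stability

    def test_levels_are_a_bijection(self):
        fl = rank_factor_labels(CANONICAL_CENTROIDS)
        levels = assign_levels(fl, CANONICAL_CENTROIDS)
        assert sorted(levels.levels) == [1, 2, 3, 4]

    def test_all_high_cluster_takes_level_one(self):
        centroids = np.array([
            [0.9, 0.9, 0.05],   # best on every factor
            [0.5, 0.5, 0.50],
            [0.3, 0.6, 0.30],
            [0.1, 0.2, 0.90],
        ])
        fl = rank_factor_labels(centroids)
        levels = assign_levels(fl, centroids)
        assert levels.levels[0] == 1

    def test_score_ties_broken_by_error_rate(self):
        centroids = np.array([
            [0.9, 0.1, 0.5],
            [0.1, 0.9, 0.4],   # same rank-sum, lower E -> better level
            [0.5, 0.5, 0.1],
            [0.4, 0.4, 0.9],
        ])
        fl = rank_factor_labels(centroids)
        levels = assign_levels(fl, centroids)
        tied = levels.scores[levels.scores == levels.scores[0]]
        if len(tied) > 1:
            e = centroids[tied.index, 2]
            lv = levels.levels[tied.index].to_numpy()
            assert np.all(np.diff(e[np.argsort(lv)]) >= 0)

    def test_invariant_to_cluster_relabeling(self):
        perm = [3, 1, 0, 2]
        fl = rank_factor_labels(CANONICAL_CENTROIDS[perm])
        levels = assign_levels(fl, CANONICAL_CENTROIDS[perm])
        base = assign_levels(rank_factor_labels(CANONICAL_CENTROIDS),
                             CANONICAL_CENTROIDS)
        np.testing.assert_array_equal(levels.levels.to_numpy(),
                                      base.levels.to_numpy()[perm])


class TestExpertBands:
    def test_band_membership(self):
        f = pd.DataFrame({"W": [0.1, 0.5, 0.9], "H": [0.2, 0.5, 0.8],
                          "E": [0.05, 0.4, 0.9]})
        bands = expert_threshold_labels(
            f, thresholds={"W": (0.3, 0.7), "H": (0.3, 0.7), "E": (0.3, 0.7)})
        assert bands.loc[0, "W"] == "Narrow"
        assert bands.loc[2, "W"] == "Wide"
        assert bands.loc[2, "E"] == "Slow & Inaccurate"  # high error, inverted
        assert bands.loc[0, "E"] == "Rapid & Exact"

    def test_non_monotone_cuts_rejected(self):
        f = pd.DataFrame({"W": [0.1, 0.9]})
        with pytest.raises(ValueError, match="non-monotone"):
            expert_threshold_labels(f, thresholds={"W": (0.7, 0.3)})

    def test_default_terciles_split_a_uniform_cohort_in_thirds(self):
        rng = np.random.default_rng(0)
        f = pd.DataFrame({"W": rng.uniform(size=300)})
        bands = expert_threshold_labels(f)
        counts = bands["W"].value_counts(normalize=True)
        assert all(abs(counts[name] - 1 / 3) < 0.05
                   for name in ("Narrow", "Medium", "Wide"))


class TestBuildReport:
    def test_end_to_end_report_is_complete(self, synthetic_cohort, tmp_path):
        cohort, _ = synthetic_cohort
        report = assess_cohort(cohort, dim=3, k=4, seed=0,
                               out_dir=tmp_path / "r")
        assert report["K"] == 4
        assert len(report["clusters"]) == 4
        for c in report["clusters"].values():
            assert {"unnormalized", "per_dimension"} <= set(c["itm"])
        assert "factor_labels" in report and "levels" in report
        assert (tmp_path / "r" / "report.json").exists()
        assert (tmp_path / "r" / "centroids.csv").exists()

    def test_rerun_same_seed_byte_identical(self, synthetic_cohort, tmp_path):
        cohort, _ = synthetic_cohort
        assess_cohort(cohort, dim=3, k=4, seed=1, out_dir=tmp_path / "a")
        assess_cohort(cohort, dim=3, k=4, seed=1, out_dir=tmp_path / "b")
        assert ((tmp_path / "a" / "report.json").read_bytes()
                == (tmp_path / "b" / "report.json").read_bytes())

    def test_report_json_round_trips(self, synthetic_cohort, tmp_path):
        cohort, _ = synthetic_cohort
        report = assess_cohort(cohort, dim=2, k=4, seed=0,
                               out_dir=tmp_path / "r2")
        loaded = json.loads((tmp_path / "r2" / "report.json").read_text())
        assert loaded["sse_total"] == pytest.approx(report["sse_total"])
        assert "factor_labels" not in loaded  # 2-dim run has no E ranking
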