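"""Distance trajectories: baselines, grouping, summary statistics."""

import numpy as np
import pandas as pd
import pytest

from mbresil import (
    Trajectory,
    TrajectoryError,
    TrajectorySet,
    aitchison_distance,
    build_trajectories,
    group_mean_se,
    overall_mean_distance,
    subset_and_reclose,
    validate_metadata,
)
from .conftest import make_table

SQRT2_LOG4 = np.sqrt(2) * np.log(4)


def meta_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "condition", "time_h", "is_baseline"]
    )


@pytest.fixture
def tiny_study():
    table = make_table(
        [[0.8, 0.2], [0.2, 0.8], [0.5, 0.5]],
        sample_ids=["pre", "t3", "t6"],
    )
    meta = meta_frame(
        [
            ("pre", "d1", "run", 0.0, True),
            ("t3", "d1", "run", 3.0, False),
            ("t6", "d1", "run", 6.0, False),
        ]
    )
    return table, meta


class TestValidateMetadata:
    def test_missing_column(self):
        with pytest.raises(TrajectoryError, match="missing required column"):
            validate_metadata(pd.DataFrame({"sample_id": ["a"]}))

    def test_boolean_parsing_case_insensitive(self):
        meta = meta_frame([("a", "s", "c", 0.0, "TRUE"), ("b", "s", "c", 1.0, "no")])
        out = validate_metadata(meta)
        assert out["is_baseline"].tolist() == [True, False]

    def test_duplicate_sample_id(self):
        meta = meta_frame([("a", "s", "c", 0.0, True), ("a", "s", "c", 1.0, False)])
        with pytest.raises(TrajectoryError, match="duplicate sample id"):
            validate_metadata(meta)

    def test_duplicate_subject_condition_time(self):
        meta = meta_frame([("a", "s", "c", 1.0, False), ("b", "s", "c", 1.0, False)])
        with pytest.raises(TrajectoryError, match=r"duplicate \(subject"):
            validate_metadata(meta)

    def test_negative_time_rejected(self):
        meta = meta_frame([("a", "s", "c", -1.0, True)])
        with pytest.raises(TrajectoryError, match="negative or non-finite"):
            validate_metadata(meta)


class TestBuildTrajectories:
    def test_distances_and_anchor(self, tiny_study):
        table, meta = tiny_study
        ts = build_trajectories(table, meta)
        (tr,) = ts.trajectories
        np.testing.assert_allclose(tr.times, [0.0, 3.0, 6.0])
        assert tr.distances[0] == 0.0  # baseline anchor
        assert tr.distances[1] == pytest.approx(SQRT2_LOG4, abs=1e-9)
        assert tr.distances[2] == pytest.approx(
            aitchison_distance([0.8, 0.2], [0.5, 0.5]), abs=1e-12
        )
        assert tr.baseline_time == 0.0

    def test_without_t0_anchor(self, tiny_study):
        table, meta = tiny_study
        ts = build_trajectories(table, meta, include_t0=False)
        (tr,) = ts.trajectories
        np.testing.assert_allclose(tr.times, [3.0, 6.0])
        assert tr.baseline_time is None

    def test_missing_baseline_names_group(self, tiny_study):
        table, meta = tiny_study
        meta = meta.assign(is_baseline=False)
        with pytest.raises(TrajectoryError, match=r"subject=d1.*condition=run"):
            build_trajectories(table, meta)

    def test_sample_absent_from_table(self, tiny_study):
        table, meta = tiny_study
        meta.loc[len(meta)] = ("ghost", "d1", "run", 24.0, False)
        with pytest.raises(TrajectoryError, match="ghost"):
            build_trajectories(table, meta)

    def test_fixed_baseline_must_exist(self, tiny_study):
        table, meta = tiny_study
        with pytest.raises(TrajectoryError, match="nope"):
            build_trajectories(table, meta, baseline_mode="fixed_sample", fixed_baseline="nope")

    def test_fixed_sample_mode_uses_one_reference(self, tiny_study):
        table, meta = tiny_study
        ts = build_trajectories(
            table, meta, baseline_mode="fixed_sample", fixed_baseline="t6"
        )
        (tr,) = ts.trajectories
        # all points measured against sample t6 = (0.5, 0.5); the group's own
        # pre sample becomes an ordinary observation and the reference sample
        # contributes the zero anchor at its own time
        np.testing.assert_allclose(tr.times, [0.0, 3.0, 6.0])
        assert tr.distances[0] == pytest.approx(
            aitchison_distance([0.8, 0.2], [0.5, 0.5]), abs=1e-12
        )
        assert tr.distances[2] == 0.0
        assert tr.baseline_time == 6.0

    def test_zeros_must_be_replaced_first(self, tiny_study):
        _, meta = tiny_study
        table = make_table(
            [[1.0, 0.0], [0.2, 0.8], [0.5, 0.5]], sample_ids=["pre", "t3", "t6"]
        )
        with pytest.raises(Exception, match="replace_zeros"):
            build_trajectories(table, meta)

    def test_row_scaling_leaves_trajectories_unchanged(self, tiny_study):
        table, meta = tiny_study
        scaled = make_table(table.values * np.array([[7.0], [1.0], [30.0]]),
                            sample_ids=table.sample_ids)
        d0 = build_trajectories(table, meta).trajectories[0].distances
        d1 = build_trajectories(scaled, meta).trajectories[0].distances
        np.testing.assert_allclose(d0, d1, atol=1e-10)

    def test_subset_consistency_with_reclosed_subcomposition(self, rng):
        # restricting the table then building == distances on re-closed parts
        vals = rng.uniform(0.05, 3.0, size=(4, 6))
        table = make_table(vals, sample_ids=["pre", "a", "b", "c"])
        meta = meta_frame(
            [
                ("pre", "s", "c", 0.0, True),
                ("a", "s", "c", 3.0, False),
                ("b", "s", "c", 6.0, False),
                ("c", "s", "c", 24.0, False),
            ]
        )
        keep = table.taxon_ids[:3]
        sub = subset_and_reclose(table, keep)
        ts = build_trajectories(sub, meta)
        manual = [
            aitchison_distance(sub.values[0], sub.values[i]) for i in (1, 2, 3)
        ]
        np.testing.assert_allclose(ts.trajectories[0].distances[1:], manual, atol=1e-10)

    def test_interpolation_fills_common_grid(self):
        table = make_table(
            [[0.8, 0.2], [0.2, 0.8], [0.7, 0.3], [0.6, 0.4], [0.3, 0.7]],
            sample_ids=["p1", "a1", "b1", "p2", "a2"],
        )
        meta = meta_frame(
            [
                ("p1", "s1", "c", 0.0, True),
                ("a1", "s1", "c", 3.0, False),
                ("b1", "s1", "c", 6.0, False),
                ("p2", "s2", "c", 0.0, True),
                ("a2", "s2", "c", 6.0, False),  # s2 skips t=3
            ]
        )
        ts = build_trajectories(table, meta, missing="interpolate")
        X = ts.curve_matrix()
        assert X.shape == (2, 3)
        # s2 at t=3 is the linear interpolant between its t=0 and t=6 values
        assert X[1, 1] == pytest.approx(X[1, 2] / 2, abs=1e-12)


class TestSummaries:
    def test_identical_trajectories_have_zero_se(self):
        trs = [
            Trajectory(f"s{i}", "c", [0.0, 3.0], [0.0, 2.0]) for i in range(2)
        ]
        out = group_mean_se(TrajectorySet(trs))
        assert (out["se"] == 0.0).all()

    def test_mean_and_se_hand_example(self):
        trs = [
            Trajectory("s1", "c", [3.0], [1.0]),
            Trajectory("s2", "c", [3.0], [3.0]),
        ]
        out = group_mean_se(TrajectorySet(trs))
        assert out.loc[0, "mean"] == 2.0
        assert out.loc[0, "se"] == pytest.approx(1.0)  # sd=sqrt(2), /sqrt(2)

    def test_single_trajectory_se_missing(self):
        out = group_mean_se(TrajectorySet([Trajectory("s", "c", [3.0], [1.5])]))
        assert out.loc[0, "mean"] == 1.5
        assert np.isnan(out.loc[0, "se"])

    def test_empty_set_rejected(self):
        with pytest.raises(TrajectoryError, match="empty"):
            group_mean_se(TrajectorySet([]))

    def test_overall_mean_excludes_anchor(self):
        tr = Trajectory("s", "c", [0.0, 3.0, 6.0], [0.0, 0.0, 2.0], baseline_time=0.0)
        mean, se = overall_mean_distance(TrajectorySet([tr]))
        assert mean == 1.0  # pools {0, 2}, not the anchor
        assert se == pytest.approx(1.0)

    def test_constant_distances_zero_se(self):
        trs = [Trajectory(f"s{i}", "c", [3.0, 6.0], [2.0, 2.0]) for i in range(3)]
        mean, se = overall_mean_distance(TrajectorySet(trs))
        assert (mean, se) == (2.0, 0.0)

    def test_no_points_rejected(self):
        tr = Trajectory("s", "c", [0.0], [0.0], baseline_time=0.0)
        with pytest.raises(TrajectoryError, match="no non-baseline"):
            overall_mean_distance(TrajectorySet([tr]))
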