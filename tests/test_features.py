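"""Preprocessing: encoding primitives and the feature-table builder."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phenorec import (
    CohortConfig,
    ConfigError,
    FeatureSpec,
    build_feature_table,
    default_decision_tree,
    default_feature_schema,
    generate_cohort,
    min_max_scale,
    one_hot_encode,
    quantile_discretize,
    simulate_sessions,
)
from phenorec.cohort import InteractionEvent, cohort_frame
from phenorec.features import (
    AGE_BIN_LABELS,
    AGE_BIN_UPPER,
    EncodingError,
    FeatureTableBuilder,
    aggregate_interactions,
)


class TestOneHot:
    def test_gender_example(self):
        out = one_hot_encode(["female"], ["female", "male", "non-binary"])
        assert out.iloc[0].tolist() == [1.0, 0.0, 0.0]

    def test_single_category_constant(self):
        out = one_hot_encode(["a", "a"], ["a"])
        assert (out.to_numpy() == 1.0).all()

    def test_unknown_value_named_in_error(self):
        with pytest.raises(EncodingError, match="purple"):
            one_hot_encode(["purple"], ["red", "blue"])

    @given(st.lists(st.sampled_from(["a", "b", "c"]), min_size=1, max_size=30))
    def test_rows_sum_to_one(self, values):
        out = one_hot_encode(values, ["a", "b", "c"])
        assert (out.sum(axis=1) == 1.0).all()


class TestQuantileDiscretize:
    @pytest.mark.parametrize(
        "age,expected_bin", [(21, "20-22"), (40, "33+"), (16, "16-19"), (19, "16-19")]
    )
    def test_study_age_bins(self, age, expected_bin):
        out, _ = quantile_discretize([age], 5, edges=AGE_BIN_UPPER, labels=AGE_BIN_LABELS)
        assert out.columns[out.iloc[0].astype(bool)].tolist() == [expected_bin]

    def test_median_split(self):
        out, edges = quantile_discretize([1, 2, 3, 4], 2)
        assert edges.tolist() == [2.5]
        assert out.iloc[:, 0].tolist() == [1, 1, 0, 0]
        assert out.iloc[:, 1].tolist() == [0, 0, 1, 1]

    def test_constant_column_single_bin_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            out, _ = quantile_discretize([7, 7, 7], 3)
        assert out.shape[1] == 1
        assert (out.to_numpy() == 1.0).all()

    @given(
        st.lists(st.floats(-50, 50, allow_nan=False), min_size=4, max_size=40),
        st.integers(2, 5),
    )
    def test_each_value_in_exactly_one_bin(self, values, n_bins):
        out, _ = quantile_discretize(values, n_bins)
        assert (out.sum(axis=1) == 1.0).all()


class TestAggregateInteractions:
    def _spec(self, aggregation):
        return FeatureSpec(
            "usefulness_mean", "interaction_aggregate", aggregation=aggregation,
            event_kind="exercise_feedback", event_field="usefulness", fill=0.0,
        )

    def test_mean_of_two_ratings(self):
        events = [
            InteractionEvent("P1", "t", "exercise_feedback", exercise_id=1, usefulness=3),
            InteractionEvent("P1", "t", "exercise_feedback", exercise_id=2, usefulness=4),
        ]
        out = aggregate_interactions(events, self._spec("mean"), ["P1"])
        assert out["P1"] == 3.5

    def test_fill_value_for_no_events(self):
        out = aggregate_interactions([], self._spec("mean"), ["P1"])
        assert out["P1"] == 0.0

    def test_count_full_response(self):
        cfg = CohortConfig(
            n_participants=1, profile_sizes=(1, 0, 0, 0), response_rate=1.0, seed=7
        )
        cohort = generate_cohort(cfg)
        events = simulate_sessions(cohort, default_decision_tree(), cfg, seed=7)
        spec = FeatureSpec(
            "n_responses", "interaction_aggregate", aggregation="count",
            event_kind="ema_response",
        )
        out = aggregate_interactions(events, spec, [cohort[0].participant_id])
        assert out.iloc[0] == 60.0

    def test_unknown_aggregation_rejected(self):
        with pytest.raises(ConfigError, match="aggregation"):
            FeatureSpec(
                "x", "interaction_aggregate", aggregation="max", event_kind="e"
            ).validate()


class TestMinMaxScale:
    @pytest.mark.parametrize(
        "col,expected",
        [([2, 4, 6], [0, 0.5, 1]), ([5, 5, 5], [0, 0, 0]), ([0, 1], [0, 1])],
    )
    def test_examples(self, col, expected):
        scaled, _ = min_max_scale(col)
        assert scaled.tolist() == expected


class TestBuildFeatureTable:
    def test_default_cohort_gives_81_by_130(self, default_table):
        assert default_table.values.shape == (81, 130)

    def test_values_within_unit_interval(self, default_table):
        vals = default_table.values
        assert np.isfinite(vals).all()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_zero_weight_features_dropped(self, default_cohort):
        schema = [
            FeatureSpec("insomnia", "ordinal", weight=1.0),
            FeatureSpec("bad_mood", "ordinal", weight=0.0),
        ]
        table = build_feature_table(cohort_frame(default_cohort), [], schema)
        assert table.column_names == ["insomnia"]

    def test_indicator_blocks_row_sum_one(self, default_table):
        for name in ("gender", "age", "occupation"):
            block = default_table.values[:, default_table.groups[name]]
            assert np.allclose(block.sum(axis=1), 1.0)

    def test_column_order_deterministic(self, default_cohort, default_events):
        t1 = build_feature_table(cohort_frame(default_cohort), default_events)
        t2 = build_feature_table(cohort_frame(default_cohort), default_events)
        assert t1.column_names == t2.column_names
        assert np.array_equal(t1.values, t2.values)

    def test_event_for_unknown_participant_rejected(self, default_cohort):
        rogue = [InteractionEvent("GHOST", "t", "ema_prompt")]
        with pytest.raises(ConfigError, match="GHOST"):
            build_feature_table(cohort_frame(default_cohort), rogue)

    def test_weights_aligned_and_nonnegative(self, default_table):
        assert len(default_table.weights) == 130
        assert (default_table.weights >= 0).all()

    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 2.0))
    def test_invariants_over_random_cohorts(self, seed, noise):
        cfg = CohortConfig(
            n_participants=8, profile_sizes=(2, 2, 2, 2), trial_days=2,
            seed=seed, noise_sd=noise,
        )
        cohort = generate_cohort(cfg)
        events = simulate_sessions(cohort, default_decision_tree(), cfg, seed=seed)
        table = build_feature_table(cohort_frame(cohort), events)
        table.check()
        vals = table.values
        assert vals.shape == (8, 130)
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_round_trip_through_sidecar(self, tmp_path, default_table):
        from phenorec.features import FeatureTable

        csv, sidecar = tmp_path / "f.csv", tmp_path / "f.json"
        default_table.write(csv, sidecar)
        back = FeatureTable.read(csv, sidecar)
        assert back.column_names == default_table.column_names
        assert np.allclose(back.values, default_table.values)
        assert np.allclose(back.weights, default_table.weights)

    def test_transform_embeds_test_participant_consistently(
        self, default_cohort, default_events
    ):
        builder = FeatureTableBuilder().fit(cohort_frame(default_cohort), default_events)
        full = builder.transform(cohort_frame(default_cohort), default_events)
        solo = builder.transform(cohort_frame(default_cohort[:1]), [
            e for e in default_events
            if e.participant_id == default_cohort[0].participant_id
        ])
        assert np.allclose(solo.values[0], full.values[0])
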