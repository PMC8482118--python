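"""Feature extraction: cycle metrics, the mean+2SD threshold, predictors."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sartkit
from sartkit import protocol
from sartkit.features import (
    InsufficientDataError,
    SARTFormatError,
    SARTValidationError,
    ThresholdResult,
    compute_threshold,
    cycle_metrics,
    features_table,
    parse_raw_sart,
    participant_features,
    pooled_cycle_metrics,
    write_raw_sart,
)

from conftest import (
    brute_force_cycle_counts,
    brute_force_threshold,
    make_stream,
    random_stream,
)


class TestCycleMetrics:
    def test_perfect_cycle(self):
        m = cycle_metrics(make_stream())
        assert len(m) == protocol.N_CYCLES
        assert (m["n_mistakes"] == 0).all()
        assert (m["error_fraction"] == 0).all()
        assert m["plottable"].all()
        assert (m["mean_rt_correct_ms"] == 400.0).all()

    def test_no_press_cycle_is_eight_omissions_unplottable(self):
        # withholding on the 3 is correct, so a silent cycle has 8 mistakes
        m = cycle_metrics(make_stream(cycles=[{"omit": [1, 2, 4, 5, 6, 7, 8, 9]}]))
        row = m.iloc[0]
        assert row["n_omissions"] == 8
        assert row["n_commissions"] == 0
        assert row["n_mistakes"] == 8
        assert np.isnan(row["mean_rt_correct_ms"])
        assert not row["plottable"]

    def test_eight_mistakes_with_one_press_keeps_position(self):
        # 7 omissions + 1 commission + 1 correct press at 400 ms: the worst
        # cycle that can still be placed in the graph
        m = cycle_metrics(
            make_stream(cycles=[{"omit": [1, 2, 4, 5, 6, 7, 8], "commit": True}])
        )
        row = m.iloc[0]
        assert row["n_mistakes"] == 8
        assert row["n_correct_actions"] == 1
        assert row["mean_rt_correct_ms"] == 400.0
        assert row["plottable"]

    def test_missing_rt_makes_cycle_unplottable_but_mistakes_count(self):
        m = cycle_metrics(make_stream(cycles=[{"omit": [5], "missing_rt": [2]}]))
        row = m.iloc[0]
        assert row["n_mistakes"] == 1
        assert not row["plottable"]
        assert np.isnan(row["mean_rt_correct_ms"])

    def test_commission_rt_excluded_from_mean(self):
        s = make_stream(cycles=[{"commit": True}])
        i = protocol.NOGO_DIGIT - 1
        s.rt_ms[i] = 9999.0  # commission RT must never enter the average
        assert cycle_metrics(s).iloc[0]["mean_rt_correct_ms"] == 400.0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_matches_presentation_by_presentation_count(self, seed):
        s = random_stream(np.random.default_rng(seed))
        got = cycle_metrics(s)
        for i, exp in enumerate(brute_force_cycle_counts(s)):
            row = got.iloc[i]
            for key in ("n_omissions", "n_commissions", "n_mistakes", "n_correct_actions", "plottable"):
                assert row[key] == exp[key], key
            if exp["plottable"]:
                assert row["mean_rt_correct_ms"] == pytest.approx(exp["mean_rt_correct_ms"])

    def test_pooled_equals_per_stream(self):
        streams = [random_stream(np.random.default_rng(i), f"P{i}") for i in range(5)]
        pooled = pooled_cycle_metrics(streams)
        per = pd.concat(
            [cycle_metrics(s).assign(participant_id=s.participant_id) for s in streams],
            ignore_index=True,
        )
        pd.testing.assert_frame_equal(
            pooled.reset_index(drop=True)[per.columns], per, check_dtype=False
        )


class TestThreshold:
    def test_identical_fractions_give_zero_big_spots(self):
        # SD = 0, cutoff = mean, strict inequality: nothing exceeds it
        m = pd.DataFrame(
            {
                "participant_id": ["a"] * 10,
                "n_mistakes": [3] * 10,
                "error_fraction": [3 / 9] * 10,
                "plottable": [True] * 10,
            }
        )
        t = compute_threshold(m)
        assert t.size_sd == pytest.approx(0, abs=1e-12)
        assert t.cutoff == pytest.approx(3 / 9)
        assert t.mistake_threshold == 4
        assert t.n_big_spots == 0

    def test_hand_built_cycles_match_brute_force(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 9, size=100)
        m = pd.DataFrame(
            {
                "participant_id": [f"p{i % 13}" for i in range(100)],
                "n_mistakes": counts,
                "error_fraction": counts / 9,
                "plottable": True,
            }
        )
        t = compute_threshold(m)
        cutoff, k = brute_force_threshold(list(counts / 9))
        assert t.cutoff == pytest.approx(cutoff)
        assert t.mistake_threshold == k

    def test_unplottable_cycles_excluded_from_estimate(self):
        m = pd.DataFrame(
            {
                "participant_id": ["a"] * 6,
                "n_mistakes": [0, 0, 0, 0, 8, 8],
                "error_fraction": [0, 0, 0, 0, 8 / 9, 8 / 9],
                "plottable": [True, True, True, True, False, False],
            }
        )
        t = compute_threshold(m)
        assert t.size_mean == 0 and t.size_sd == 0
        assert t.mistake_threshold == 1

    def test_too_few_plottable_cycles(self):
        m = pd.DataFrame(
            {"participant_id": ["a"], "n_mistakes": [1], "error_fraction": [1 / 9], "plottable": [True]}
        )
        with pytest.raises(InsufficientDataError):
            compute_threshold(m)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6), st.floats(1.01, 3.0))
    def test_scaling_fractions_up_never_lowers_cutoff(self, seed, c):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 9, size=50)
        base = pd.DataFrame(
            {
                "participant_id": "x",
                "n_mistakes": counts,
                "error_fraction": counts / 9,
                "plottable": True,
            }
        )
        scaled = base.assign(error_fraction=base["error_fraction"] * c)
        assert compute_threshold(scaled).cutoff >= compute_threshold(base).cutoff - 1e-12


class TestParticipantFeatures:
    def test_error_free_stream(self):
        f = participant_features(make_stream(), ThresholdResult.pinned(4))
        assert f.total_mistakes == 0
        assert f.bad_performances == 0
        assert f.mistakes_in_good_performances == 0
        assert f.n_unplottable_cycles == 0
        assert f.mean_rt_ms == 400.0
        assert f.sd_rt_ms == 0.0

    def test_split_around_threshold(self):
        # cycles with 5 and 3 mistakes at threshold 4: one bad performance,
        # the 3 leftover mistakes stay in the good-performance pool
        s = make_stream(
            cycles=[{"omit": [1, 2, 4, 5, 6]}, {"omit": [7, 8, 9]}]
        )
        f = participant_features(s, ThresholdResult.pinned(4))
        assert f.total_mistakes == 8
        assert f.bad_performances == 1
        assert f.mistakes_in_good_performances == 3

    def test_threshold_ten_means_no_bad_performances(self):
        s = make_stream(cycles=[{"omit": [1, 2, 4, 5, 6, 7, 8], "commit": True}])
        f = participant_features(s, ThresholdResult.pinned(10))
        assert f.bad_performances == 0
        assert f.mistakes_in_good_performances == f.total_mistakes == 8

    def test_unplottable_bad_cycle_policies(self):
        s = make_stream(cycles=[{"omit": [1, 2, 4, 5, 6, 7, 8, 9]}])  # silent cycle
        inclusive = participant_features(s, ThresholdResult.pinned(4))
        strict = participant_features(s, ThresholdResult.pinned(4), bad_perf_plottable_only=True)
        assert inclusive.bad_performances == 1
        assert strict.bad_performances == 0
        assert strict.mistakes_in_good_performances == 8

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6), st.integers(1, 10))
    def test_mistake_decomposition_identity(self, seed, k):
        # conservation: total = in-good + in-bad, against the brute-force count
        s = random_stream(np.random.default_rng(seed))
        thr = ThresholdResult.pinned(k)
        f = participant_features(s, thr)
        brute = brute_force_cycle_counts(s)
        total = sum(c["n_mistakes"] for c in brute)
        bad = sum(c["n_mistakes"] for c in brute if c["n_mistakes"] >= k)
        assert f.total_mistakes == total
        assert f.mistakes_in_good_performances == total - bad
        assert f.bad_performances == sum(c["n_mistakes"] >= k for c in brute)

    def test_batch_table_equals_per_stream(self):
        streams = [random_stream(np.random.default_rng(i), f"P{i}") for i in range(8)]
        thr = ThresholdResult.pinned(4)
        batch = features_table(streams, thr)
        for i, s in enumerate(streams):
            ref = participant_features(s, thr)
            row = batch.iloc[i]
            for field in ("total_mistakes", "bad_performances",
                          "mistakes_in_good_performances", "n_unplottable_cycles"):
                assert row[field] == getattr(ref, field)
            assert row["mean_rt_ms"] == pytest.approx(ref.mean_rt_ms, nan_ok=True)
            assert row["sd_rt_ms"] == pytest.approx(ref.sd_rt_ms, nan_ok=True)


class TestRawIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        streams = [random_stream(rng, f"P{i}") for i in range(4)]
        path = tmp_path / "raw.csv"
        write_raw_sart(streams, path)
        back = parse_raw_sart(path)
        assert [s.participant_id for s in back] == [s.participant_id for s in streams]
        for a, b in zip(streams, back):
            np.testing.assert_array_equal(a.pressed, b.pressed)
            np.testing.assert_array_equal(a.digit, b.digit)
            np.testing.assert_allclose(a.rt_ms, b.rt_ms, equal_nan=True)

    def test_truncated_participant_rejected(self, tmp_path):
        write_raw_sart([make_stream()], tmp_path / "raw.csv")
        df = pd.read_csv(tmp_path / "raw.csv").iloc[:-1]
        df.to_csv(tmp_path / "short.csv", index=False)
        with pytest.raises(SARTValidationError, match="206 rows"):
            parse_raw_sart(tmp_path / "short.csv")

    def test_bad_digit_sequence_names_participant_and_index(self, tmp_path):
        write_raw_sart([make_stream(pid="PX")], tmp_path / "raw.csv")
        df = pd.read_csv(tmp_path / "raw.csv")
        df.loc[10, "digit"] = 7
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(SARTValidationError, match=r"PX.*11"):
            parse_raw_sart(tmp_path / "bad.csv")

    def test_missing_column(self, tmp_path):
        p = tmp_path / "cols.csv"
        p.write_text("participant_id,digit\n")
        with pytest.raises(SARTFormatError, match="missing required column"):
            parse_raw_sart(p)

    def test_empty_file_warns_and_returns_nothing(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            assert parse_raw_sart(p) == []
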