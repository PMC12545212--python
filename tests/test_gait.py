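"""Stride segmentation and gait statistics on exactly enumerable inputs."""
import numpy as np
import pytest

from octokin import GaitSimConfig, simulate_gait
from octokin.containers import AIR, ARM_ORDER, CONTACT, UNKNOWN, PhaseTable
from octokin.gait import (
    Stride,
    bilateral_fraction,
    contact_count_series,
    gait_stats,
    segment_strides,
    transition_matrix,
)


def phase_from_column(col, arm="L1", fps=60.0):
    codes = np.zeros((len(col), 8), dtype=np.int8)
    codes[:, ARM_ORDER.index(arm)] = col
    return PhaseTable(codes, fps)


def square_wave(on, off, cycles, lead_air=5):
    col = [AIR] * lead_air
    for _ in range(cycles):
        col += [CONTACT] * on + [AIR] * off
    return np.array(col, dtype=np.int8)


class TestSegmentStrides:
    def test_square_wave_cycle_and_contact(self):
        phase = phase_from_column(square_wave(72, 48, 5))
        strides = segment_strides(phase, "L1")
        assert len(strides) == 4  # trailing incomplete stride dropped
        assert all(s.cycle_frames == 120 for s in strides)
        assert all(s.contact_frames == 72 for s in strides)

    def test_contact_throughout_gives_no_stride(self):
        phase = phase_from_column(np.full(500, CONTACT, dtype=np.int8))
        assert segment_strides(phase, "L1") == []

    def test_left_censored_first_run_dropped(self):
        col = square_wave(60, 60, 3, lead_air=0)
        phase = phase_from_column(col)
        strides = segment_strides(phase, "L1")
        assert all(s.touch_on > 0 for s in strides)

    def test_unknown_block_excludes_only_affected_stride(self):
        col = square_wave(60, 60, 3)
        col[200:220] = UNKNOWN  # inside the second cycle
        phase = phase_from_column(col)
        strides = segment_strides(phase, "L1")
        onsets = [s.touch_on for s in strides]
        # three cycles -> two complete strides; the one overlapping the
        # unknown block is excluded, its neighbour kept
        all_strides = segment_strides(phase, "L1", exclude_unknown=False)
        assert len(all_strides) == 2
        assert len(strides) == 1

    def test_tolerated_unknown_frames_option(self):
        col = square_wave(60, 60, 3)
        col[200:203] = UNKNOWN
        phase = phase_from_column(col)
        assert len(segment_strides(phase, "L1")) == 1
        assert len(segment_strides(phase, "L1", max_unknown_frames=5)) == 2

    def test_other_arms_untouched(self, simple_gait):
        _, phase, truth = simple_gait
        for arm in ARM_ORDER:
            strides = segment_strides(phase, arm)
            assert all(s.arm == arm for s in strides)


class TestGaitStats:
    def test_duration_and_duty_arithmetic(self):
        s = Stride("L1", 100, 172, 220)
        stats = gait_stats([s], fps=60.0)
        row = stats.per_stride.iloc[0]
        assert row["cycle_s"] == pytest.approx(2.0)
        assert row["duty_pct"] == pytest.approx(60.0)

    def test_identical_strides_have_zero_iqr(self):
        strides = [Stride("R2", 120 * k, 120 * k + 72, 120 * (k + 1)) for k in range(5)]
        stats = gait_stats(strides, 60.0)
        for _, row in stats.by_pair.iterrows():
            assert row["iqr"] == 0.0
            assert row["whisker_lo"] == row["median"] == row["whisker_hi"]

    def test_empty_stride_list_gives_empty_tables(self):
        stats = gait_stats([], 60.0)
        assert stats.per_stride.empty and stats.by_pair.empty

    def test_invalid_stride_rejected(self):
        with pytest.raises(ValueError):
            Stride("L1", 10, 10, 20)

    def test_synthetic_duty_and_period_recovered_exactly(self):
        duties = [0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.9]
        periods = [20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0, 60.0]
        cfg = GaitSimConfig(
            period_s=periods, duty=duties,
            phase=[0.0, 0.3, 0.6, 0.1, 0.4, 0.7, 0.2, 0.5],
            duration_s=600.0, fps=60.0,
        )
        phase, truth = simulate_gait(cfg)
        for arm, period, duty in zip(ARM_ORDER, periods, duties):
            strides = segment_strides(phase, arm)
            assert strides
            for s in strides:
                assert abs(s.cycle_frames - period * 60) <= 1
                assert abs(s.contact_frames - duty * period * 60) <= 1


class TestContactCounts:
    def test_constant_three_arms(self):
        codes = np.zeros((700, 8), dtype=np.int8)
        codes[:, [1, 3, 6]] = CONTACT
        df = contact_count_series(PhaseTable(codes, 60.0))
        assert np.all(df["count"] == 3)
        assert np.allclose(df["trend"], 3.0, atol=1e-6)
        assert np.all(df["trend_lo"] <= df["trend"])

    def test_alternating_pattern_mean(self):
        codes = np.zeros((400, 8), dtype=np.int8)
        codes[::2, :2] = CONTACT
        codes[1::2, :4] = CONTACT
        df = contact_count_series(PhaseTable(codes, 60.0), smooth=False)
        assert df["count"].mean() == pytest.approx(3.0)

    def test_all_unknown_frame_excluded(self):
        codes = np.zeros((300, 8), dtype=np.int8)
        codes[:, 0] = CONTACT
        codes[150] = UNKNOWN
        df = contact_count_series(PhaseTable(codes, 60.0), smooth=False)
        assert np.isnan(df.loc[150, "count"])
        assert df.loc[150, "n_unknown"] == 8

    def test_duty_sum_sets_long_run_mean(self):
        cfg = GaitSimConfig(
            period_s=[20, 25, 30, 35, 40, 45, 50, 60],
            duty=0.375, duration_s=600.0, fps=60.0,
            phase=[0.0, 0.6, 0.25, 0.8, 0.45, 0.1, 0.7, 0.35],
        )
        phase, _ = simulate_gait(cfg)
        df = contact_count_series(phase, smooth=False)
        assert abs(df["count"].mean() - 3.0) < 0.05


class TestBilateral:
    def test_only_left_contacts(self):
        codes = np.zeros((50, 8), dtype=np.int8)
        codes[:, 0] = CONTACT
        assert bilateral_fraction(PhaseTable(codes, 60.0)) == 0.0

    def test_l3_r3_always(self):
        codes = np.zeros((50, 8), dtype=np.int8)
        codes[:, ARM_ORDER.index("L3")] = CONTACT
        codes[:, ARM_ORDER.index("R3")] = CONTACT
        assert bilateral_fraction(PhaseTable(codes, 60.0)) == 100.0

    def test_hand_enumerated_toy_table(self):
        codes = np.zeros((10, 8), dtype=np.int8)
        codes[:7, ARM_ORDER.index("L2")] = CONTACT
        codes[:7, ARM_ORDER.index("R4")] = CONTACT
        # frames 7-9: left contact only, all right arms known-air
        codes[7:, ARM_ORDER.index("L2")] = CONTACT
        assert bilateral_fraction(PhaseTable(codes, 60.0)) == pytest.approx(70.0)

    def test_indeterminate_frames_excluded(self):
        codes = np.zeros((4, 8), dtype=np.int8)
        codes[:, 0] = CONTACT  # L1 contact
        codes[0, 4:] = UNKNOWN  # right side unknown: indeterminate
        codes[1, 4] = CONTACT  # bilateral
        # frames 2, 3: right all air -> determinate, not bilateral
        assert bilateral_fraction(PhaseTable(codes, 60.0)) == pytest.approx(100.0 / 3)


class TestTransitionMatrix:
    def test_deterministic_cycle(self):
        # L4 -> L3 -> L2, repeated 10x, 30 frames apart
        codes = np.zeros((30 * 30 + 10, 8), dtype=np.int8)
        seq = ["L4", "L3", "L2"]
        t = 5
        order = []
        for k in range(10):
            for arm in seq:
                codes[t : t + 10, ARM_ORDER.index(arm)] = CONTACT
                order.append((t, arm))
                t += 30
        tm = transition_matrix(PhaseTable(codes, 60.0))
        assert tm.loc["L3", "L4"] == 10
        assert tm.loc["L2", "L3"] == 10
        assert tm.loc["L4", "L2"] == 9  # wrap-truncated
        assert tm.to_numpy().sum() == 29

    def test_single_arm_alone_diagonal(self):
        phase = phase_from_column(square_wave(30, 30, 5), arm="R2")
        tm = transition_matrix(phase)
        nz = np.argwhere(tm.to_numpy() > 0)
        assert nz.tolist() == [[ARM_ORDER.index("R2"), ARM_ORDER.index("R2")]]

    def test_empty_phase_zero_matrix(self):
        codes = np.zeros((100, 8), dtype=np.int8)
        tm = transition_matrix(PhaseTable(codes, 60.0))
        assert tm.to_numpy().sum() == 0

    def test_total_counts_onsets_minus_one(self, simple_gait):
        _, phase, _ = simple_gait
        tm = transition_matrix(phase)
        n_onsets = 0
        for arm in ARM_ORDER:
            col = phase.column(arm)
            onsets = np.flatnonzero((col[1:] == CONTACT) & (col[:-1] == AIR)) + 1
            n_onsets += onsets.size
        assert tm.to_numpy().sum() == n_onsets - 1
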