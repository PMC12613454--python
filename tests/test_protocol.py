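"""Targets, scoring and the two-session protocol schedule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hapticlearn.pendulum import PendulumParams, PendulumState
from hapticlearn.protocol import (
    ProtocolConfig,
    build_protocol,
    error_at_crossing,
    generate_wall_schedule,
    mirror,
    score,
    set_score,
)


class TestScore:
    @pytest.mark.parametrize("err,expected", [
        (0.0, 100.0), (0.2, 0.0), (0.1, 50.0), (0.5, 0.0), (0.02, 90.0),
    ])
    def test_values(self, err, expected):
        assert score(err) == pytest.approx(expected)

    def test_negative_error_rejected(self):
        with pytest.raises(ValueError):
            score(-0.01)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_non_increasing(self, a, b):
        lo, hi = sorted((a, b))
        assert score(hi) <= score(lo)

    def test_continuous_at_cutoff(self):
        eps = 1e-9
        assert abs(score(0.2 - eps) - score(0.2 + eps)) < 1e-5


class TestSetScore:
    def test_means(self):
        assert set_score([100.0] * 20) == 100.0
        assert set_score([0.0] * 20) == 0.0
        assert set_score([100.0] * 10 + [0.0] * 10) == 50.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            set_score([50.0] * 19)


class TestWallSchedule:
    def test_crossing_interval_exactly_one_second(self):
        rng = np.random.default_rng(0)
        sched = generate_wall_schedule(rng, wall_spacing=1.0, wall_speed=1.0)
        assert np.all(np.diff(sched.crossing_times) == 1.0)

    def test_deterministic_under_seed(self):
        a = generate_wall_schedule(np.random.default_rng(5))
        b = generate_wall_schedule(np.random.default_rng(5))
        assert np.array_equal(a.offsets, b.offsets)

    def test_offsets_uniform(self):
        rng = np.random.default_rng(1)
        sched = generate_wall_schedule(rng, n_walls=10000)
        for v in (-0.12, 0.0, 0.12):
            frac = np.mean(sched.offsets == v)
            assert abs(frac - 1 / 3) < 0.02

    def test_empty_offsets_rejected(self):
        with pytest.raises(ValueError):
            generate_wall_schedule(np.random.default_rng(0), offsets=())


class TestMirror:
    def test_negates_offsets_preserves_times(self):
        rng = np.random.default_rng(2)
        sched = generate_wall_schedule(rng)
        m = mirror(sched)
        assert np.array_equal(m.offsets, -sched.offsets)
        assert np.array_equal(m.crossing_times, sched.crossing_times)

    def test_involution(self):
        sched = generate_wall_schedule(np.random.default_rng(3))
        assert np.array_equal(mirror(mirror(sched)).offsets, sched.offsets)

    def test_center_only_schedule_fixed(self):
        sched = generate_wall_schedule(np.random.default_rng(0), offsets=(0.0,))
        assert np.array_equal(mirror(sched).offsets, sched.offsets)


class TestErrorAtCrossing:
    def test_geometry(self):
        params = PendulumParams()
        sched = generate_wall_schedule(np.random.default_rng(0))
        tgt = sched.targets[0]
        hang = PendulumState(pivot_y=tgt.offset_b)  # mass directly below pivot
        assert error_at_crossing(hang, tgt, params) == pytest.approx(0.0)
        center = PendulumState(pivot_y=0.0)
        off = error_at_crossing(center, tgt, params)
        assert off == pytest.approx(abs(tgt.offset_b))


class TestBuildProtocol:
    @pytest.fixture(scope="class")
    def plans(self):
        cfg = ProtocolConfig()
        return {
            g: build_protocol(g, np.random.default_rng(7), cfg)
            for g in ("Control", "Experimental")
        }

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            build_protocol("Sham", np.random.default_rng(0))

    def test_set_counts(self, plans):
        plan = plans["Control"]
        counts = {}
        for e in plan:
            counts[e.stage] = counts.get(e.stage, 0) + 1
        assert counts == {"FAM": 1, "BL": 6, "TR": 30, "WASHOUT": 1,
                          "STR": 6, "LTR": 6}
        assert all(not e.analysis for e in plan.stage_entries("FAM"))

    def test_control_never_guided(self, plans):
        assert not any(e.guidance_on for e in plans["Control"])

    def test_experimental_guided_in_24_training_sets(self, plans):
        guided = [e for e in plans["Experimental"] if e.guidance_on]
        assert len(guided) == 24
        assert all(e.stage == "TR" and not e.schedule.catch for e in guided)

    def test_retention_blocks_structurally_identical(self, plans):
        plan = plans["Control"]
        for stage in ("STR", "LTR"):
            bl = plan.stage_entries("BL")
            other = plan.stage_entries(stage)
            assert [(e.task, e.s_index, e.rod_scale) for e in bl] == \
                [(e.task, e.s_index, e.rod_scale) for e in other]
            for a, b in zip(bl, other):
                assert np.array_equal(a.schedule.offsets, b.schedule.offsets)

    def test_main_task_sequence_reused_except_mirrored(self, plans):
        plan = plans["Experimental"]
        base = plan.stage_entries("BL")[0].schedule.offsets
        for e in plan:
            if e.task != "mn" or e.stage == "FAM":
                continue
            if e.schedule.mirrored:
                assert np.array_equal(e.schedule.offsets, -base)
            else:
                assert np.array_equal(e.schedule.offsets, base)

    def test_t2_reuses_main_offsets_with_short_rod(self, plans):
        plan = plans["Control"]
        base = plan.stage_entries("BL")[0].schedule.offsets
        t2 = [e for e in plan if e.task == "t2"]
        assert all(np.array_equal(e.schedule.offsets, base) for e in t2)
        assert all(e.rod_scale == 0.7 for e in t2)

    def test_t1_fresh_sequences_with_wall_identity(self, plans):
        plan = plans["Control"]
        base = plan.stage_entries("BL")[0].schedule.offsets
        t1 = [e for e in plan if e.task == "t1"]
        assert any(not np.array_equal(e.schedule.offsets, base) for e in t1)
        nw = np.concatenate([e.schedule.new_walls for e in plan.stage_entries("BL")
                             if e.task == "t1"])
        assert sorted(nw) == list(range(1, 41))
        mn_nw = np.concatenate([e.schedule.new_walls for e in plan
                                if e.task != "t1"])
        assert np.all(mn_nw == 0)

    def test_catch_and_mirrored_disjoint_validated(self):
        cfg = ProtocolConfig(catch_sets=(1, 3), mirrored_sets=(3,))
        with pytest.raises(ValueError):
            build_protocol("Control", np.random.default_rng(0), cfg)
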