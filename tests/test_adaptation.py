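"""Adaptation engine: buffered averaging, rule table, modulation, closed loop."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from biocyber.adaptation import (
    AdaptiveRule,
    ModulationDecision,
    PerformanceRecord,
    SessionProtocol,
    alpha_rule_variant,
    apply_modulation,
    biofeedback_metrics,
    buffered_average,
    evaluate_rule,
    run_closed_loop,
    shooting_performance,
)
from biocyber.difficulty import PRESETS, RANGES, DifficultyConfig
from biocyber.synthetic import PlantParams, hr_setpoint


class TestBufferedAverage:
    def test_constant_stream(self):
        np.testing.assert_allclose(buffered_average([5.0] * 10, 4), np.full(7, 5.0))

    def test_window_mean(self):
        np.testing.assert_allclose(buffered_average([100, 110, 120], 3), [110.0])

    def test_alternating(self):
        out = buffered_average([0, 1] * 5, 2)
        np.testing.assert_allclose(out, np.full(9, 0.5))

    def test_partial_buffer_no_emission(self):
        assert buffered_average([1.0, 2.0], 5).size == 0


class TestRule:
    rule = AdaptiveRule()

    def test_below_zone_focused_increases(self):
        d = evaluate_rule(self.rule, hr_avg=85.0, theta_avg=1.8)
        assert d.direction == "increase"

    def test_below_zone_gated_holds(self):
        d = evaluate_rule(self.rule, hr_avg=85.0, theta_avg=1.2)
        assert d.direction == "hold" and "gated" in d.tags

    def test_inside_zone_holds_with_zero_step(self):
        d = evaluate_rule(self.rule, hr_avg=107.0, theta_avg=1.8)
        assert d.direction == "hold" and not d.step

    def test_above_zone_decreases(self):
        d = evaluate_rule(self.rule, hr_avg=125.0, theta_avg=1.8)
        assert d.direction == "decrease"

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_rule(self.rule, float("nan"), 1.5)

    def test_alpha_variant_threshold(self):
        rule = alpha_rule_variant()
        assert rule.gate_metric == "frontal_alpha"
        assert rule.gate_threshold == pytest.approx(-0.01)

    def test_invalid_zone_rejected(self):
        with pytest.raises(ValueError):
            AdaptiveRule(hr_zone=(115.0, 100.0))


class TestModulation:
    rule = AdaptiveRule()

    def test_speed_clamped_at_table_maximum(self):
        cfg = DifficultyConfig(target_speed=4.9)
        d = evaluate_rule(self.rule, 85.0, 1.8)
        out = apply_modulation(cfg, d)
        assert out.target_speed == pytest.approx(5.0)

    def test_hold_leaves_config_unchanged(self):
        cfg = PRESETS["medium"]
        d = evaluate_rule(self.rule, 107.0, 1.8)
        assert apply_modulation(cfg, d) == cfg

    def test_size_clamped_at_minimum(self):
        cfg = DifficultyConfig(target_size=0.31)
        d = ModulationDecision("increase", {"target_size": 0.9})
        out = apply_modulation(apply_modulation(cfg, d), d)
        assert out.target_size == pytest.approx(0.3)

    def test_decrease_is_inverse_direction(self):
        cfg = DifficultyConfig(target_speed=2.0, n_targets=10)
        inc = apply_modulation(cfg, ModulationDecision("increase", {"target_speed": 0.25, "n_targets": 1}))
        dec = apply_modulation(inc, ModulationDecision("decrease", {"target_speed": 0.25, "n_targets": 1}))
        assert dec.target_speed == pytest.approx(cfg.target_speed)
        assert dec.n_targets == cfg.n_targets

    @given(st.lists(st.sampled_from(["increase", "decrease", "hold"]), min_size=1, max_size=60))
    def test_ranges_invariant_under_any_decision_sequence(self, directions):
        cfg = PRESETS["easy"]
        rule = AdaptiveRule()
        for direction in directions:
            step = {} if direction == "hold" else dict(rule.increase_step)
            cfg = apply_modulation(cfg, ModulationDecision(direction, step))
            for name, (lo, hi) in RANGES.items():
                assert lo <= getattr(cfg, name) <= hi


class TestPerformance:
    @pytest.mark.parametrize("shots,destroyed,expected", [(50, 32, 0.64), (10, 5, 0.5)])
    def test_ratio(self, shots, destroyed, expected):
        assert shooting_performance(shots, destroyed) == pytest.approx(expected)

    def test_zero_shots_undefined(self):
        assert np.isnan(shooting_performance(0, 0))

    def test_destroyed_exceeding_shots_rejected(self):
        with pytest.raises(ValueError):
            shooting_performance(5, 6)

    def test_record_invariants(self):
        r = PerformanceRecord(shots=50, destroyed=32)
        assert r.performance == pytest.approx(0.64)
        with pytest.raises(ValueError):
            PerformanceRecord(shots=3, destroyed=4)


class TestBiofeedback:
    rule = AdaptiveRule()

    def test_zone_center_full_calmness(self):
        m = biofeedback_metrics(107.5, 1.8, self.rule)
        assert m["calmness"] == pytest.approx(1.0)

    def test_theta_at_target_full_focus(self):
        assert biofeedback_metrics(107.5, 1.5, self.rule)["focus"] == pytest.approx(1.0)
        assert biofeedback_metrics(107.5, 2.0, self.rule)["focus"] == pytest.approx(1.0)

    def test_far_outside_zone_zero_calmness(self):
        assert biofeedback_metrics(160.0, 1.8, self.rule)["calmness"] == 0.0

    def test_metrics_bounded(self):
        for hr in (40.0, 90.0, 107.5, 140.0):
            for th in (0.5, 1.5, 2.5):
                m = biofeedback_metrics(hr, th, self.rule)
                assert 0.0 <= m["calmness"] <= 1.0
                assert 0.0 <= m["focus"] <= 1.0


class TestClosedLoop:
    def test_same_seed_identical_trajectories(self):
        a = run_closed_loop(AdaptiveRule(), duration=120.0, seed=4)
        b = run_closed_loop(AdaptiveRule(), duration=120.0, seed=4)
        assert a.frame.equals(b.frame)

    def test_hold_only_rule_tracks_fixed_setpoint(self):
        """With a zone wide enough that the rule always holds, the plant
        settles at the easy-preset setpoint."""
        rule = AdaptiveRule(hr_zone=(1e-3, 500.0))
        res = run_closed_loop(rule, duration=600.0, seed=3)
        sp = hr_setpoint(PRESETS["easy"])
        assert abs(res.final_minute_mean_hr() - sp) < 3.0

    def test_duration_precondition(self):
        with pytest.raises(ValueError):
            run_closed_loop(AdaptiveRule(), duration=30.0, seed=0)

    def test_difficulty_fields_always_in_range(self):
        res = run_closed_loop(AdaptiveRule(), duration=300.0, seed=5)
        for name, (lo, hi) in RANGES.items():
            col = res.frame[name]
            assert col.between(lo, hi).all()

    def test_steady_state_hr_monotone_in_zone_lower_bound(self):
        """Sweeping the zone's lower bound upward raises the settled HR
        (zero plant noise for a deterministic sweep)."""
        quiet = PlantParams(hr_noise_sd=0.0, theta_noise_sd=0.0)
        means = []
        for lb in (80.0, 90.0, 100.0, 110.0):
            res = run_closed_loop(
                AdaptiveRule(hr_zone=(lb, lb + 15.0)),
                duration=600.0,
                seed=0,
                plant_params=quiet,
            )
            means.append(res.final_minute_mean_hr())
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestSessionProtocol:
    def test_presets_match_study_blocks(self):
        proto = SessionProtocol()
        assert proto.presets["easy"].n_targets == 10
        assert proto.presets["easy"].target_speed == 0.0
        assert proto.presets["medium"].target_speed == 0.5
        assert proto.presets["hard"].n_targets == 20
        assert proto.presets["hard"].target_speed == 1.0
        assert proto.block_duration == 180.0

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            SessionProtocol(block_duration=0.0)
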