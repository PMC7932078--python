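"""Temporal profile, policy velocities and closed-loop advancement."""

import math

import numpy as np
import pytest

from snakescomp.compensation import (
    DEFAULT_TEMPORAL_FUNCTION,
    CompensationPolicy,
    CompensationState,
    TemporalFunction,
    advance,
    eccentricity_deg,
    f_eval,
    load_policies,
    default_policies,
    policy_velocity,
    pulse_velocity,
    simulate_trial,
    threshold_velocity,
)
from snakescomp.gaze import DetectorConfig
from snakescomp.stimulus import DEFAULT_GEOMETRY, Disk, build_layout

from conftest import make_stream


def brute_force_f(tf: TemporalFunction, t: float) -> float:
    total = tf.constant
    for a, dt in tf.components:
        if t <= dt:
            total += a * math.sin(math.pi * t / dt)
    return total


class TestTemporalFunction:
    def test_clamped_beyond_longest_timescale(self):
        for t in (1000.0001, 1200.0, 5000.0, 1e9):
            assert f_eval(DEFAULT_TEMPORAL_FUNCTION, t) == 0.277

    def test_value_at_zero_is_constant(self):
        assert f_eval(DEFAULT_TEMPORAL_FUNCTION, 0.0) == pytest.approx(0.277)

    def test_value_at_50ms(self):
        # term-by-term: 2.56*sin(pi/2) + 1.66*sin(pi/3) + 1.80*sin(pi/5)
        #             + 0.830*sin(pi/10) + 0.554*sin(pi/20) + 0.277
        expected = (
            2.56 * 1.0
            + 1.66 * math.sin(math.pi / 3)
            + 1.80 * math.sin(math.pi / 5)
            + 0.830 * math.sin(math.pi / 10)
            + 0.554 * math.sin(math.pi / 20)
            + 0.277
        )
        assert f_eval(DEFAULT_TEMPORAL_FUNCTION, 50.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(5.676, abs=1e-3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            f_eval(DEFAULT_TEMPORAL_FUNCTION, -1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        ts = rng.uniform(0, 1500, size=10_000)
        got = f_eval(DEFAULT_TEMPORAL_FUNCTION, ts)
        want = np.array([brute_force_f(DEFAULT_TEMPORAL_FUNCTION, t) for t in ts])
        assert np.max(np.abs(got - want)) < 1e-9

    def test_coincident_timescales_sum_independently(self):
        tf = TemporalFunction(components=((1.0, 200.0), (0.5, 200.0)))
        assert f_eval(tf, 100.0) == pytest.approx(1.5)


class TestEccentricity:
    def test_zero_at_disk_center(self):
        d = Disk(center_px=(960.0, 540.0))
        assert eccentricity_deg(d, (960.0, 540.0)) == 0.0

    def test_300px_matches_trigonometry(self):
        d = Disk(center_px=(960.0 + 300.0, 540.0))
        g = DEFAULT_GEOMETRY
        want = math.degrees(math.atan(300.0 * g.pixel_pitch_mm / g.viewing_distance_mm))
        assert eccentricity_deg(d, (960.0, 540.0)) == pytest.approx(want, abs=1e-12)
        assert want == pytest.approx(9.43, abs=0.01)

    def test_left_right_symmetry(self):
        left = Disk(center_px=(660.0, 540.0))
        right = Disk(center_px=(1260.0, 540.0))
        eye = (960.0, 540.0)
        assert eccentricity_deg(left, eye) == eccentricity_deg(right, eye)

    def test_invalid_eye_rejected(self):
        with pytest.raises(ValueError):
            eccentricity_deg(Disk(center_px=(0, 0)), (math.nan, 0.0))


class TestPolicyVelocity:
    def test_kind_a_zero_at_fovea(self):
        p = CompensationPolicy(kind="A", c=-0.71)
        assert policy_velocity(p, 0.0, CompensationState()) == 0.0

    def test_kind_u_constant_everywhere(self):
        p = CompensationPolicy(kind="U", c=-0.14)
        for ecc in (0.0, 5.0, 20.0):
            for t in (math.inf, 0.0, 123.0):
                assert policy_velocity(p, ecc, CompensationState(t)) == -0.14

    def test_kind_c_after_decay(self):
        p = CompensationPolicy(kind="C", c=-0.39)
        v = policy_velocity(p, 8.0, CompensationState(1200.0))
        assert v == pytest.approx(-0.39 * 8.0 * 0.277, abs=1e-9)

    def test_pre_event_uses_constant_terms_only(self):
        state = CompensationState()  # t = inf
        b = CompensationPolicy(kind="B", c=-0.35)
        assert policy_velocity(b, 5.0, state) == pytest.approx(-0.35 * 0.277)
        c = CompensationPolicy(kind="C", c=-0.39)
        assert policy_velocity(c, 5.0, state) == pytest.approx(-0.39 * 5.0 * 0.277)

    def test_linear_in_constant(self):
        rng = np.random.default_rng(1)
        for kind in ("A", "B", "C", "U"):
            for _ in range(20):
                c0, ecc, t = rng.uniform(-1, 0), rng.uniform(0, 20), rng.uniform(0, 2000)
                v1 = policy_velocity(CompensationPolicy(kind=kind, c=c0), ecc, CompensationState(t))
                v2 = policy_velocity(CompensationPolicy(kind=kind, c=2 * c0), ecc, CompensationState(t))
                assert v2 == pytest.approx(2 * v1, abs=1e-12)

    def test_b_constant_and_c_proportional_after_decay(self):
        b = CompensationPolicy(kind="B", c=-0.35)
        c = CompensationPolicy(kind="C", c=-0.39)
        vals_b = [policy_velocity(b, e, CompensationState(t))
                  for e in (1.0, 9.0) for t in (1001.0, 1500.0, 1e5)]
        assert vals_b == pytest.approx([-0.35 * 0.277] * 6)
        v4 = policy_velocity(c, 4.0, CompensationState(2000.0))
        v8 = policy_velocity(c, 8.0, CompensationState(2000.0))
        assert v8 == pytest.approx(2 * v4)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            CompensationPolicy(kind="Z")


class TestThresholdAndPulse:
    @pytest.mark.parametrize(
        "ecc,t,expected",
        [(10.0, 100.0, 0.5), (5.0, 100.0, 0.0), (10.0, 400.0, 0.0)],
    )
    def test_threshold_rule(self, ecc, t, expected):
        p = CompensationPolicy(kind="EXP1_THRESHOLD", r_th_deg=8.0, dt_ms=300.0,
                               delta_theta_deg_per_s=0.5)
        assert threshold_velocity(p, ecc, CompensationState(t)) == expected

    def test_threshold_is_two_valued(self):
        p = CompensationPolicy(kind="EXP1_THRESHOLD", delta_theta_deg_per_s=-0.5)
        rng = np.random.default_rng(2)
        vals = {threshold_velocity(p, rng.uniform(0, 20), CompensationState(rng.uniform(0, 600)))
                for _ in range(200)}
        assert vals <= {0.0, -0.5}

    def test_pulse_shape(self):
        assert pulse_velocity(2.0, 500.0, 250.0) == pytest.approx(2.0)
        assert pulse_velocity(2.0, 500.0, 750.0) == 0.0
        assert pulse_velocity(2.0, 600.0, 100.0) == pytest.approx(1.0)

    def test_pulse_constant_when_dt_infinite(self):
        for t in (0.0, 100.0, 1e6):
            assert pulse_velocity(-0.83, math.inf, t) == -0.83


class TestAdvance:
    def test_policy_o_leaves_orientations(self, pair_layout):
        state = CompensationState()
        out = advance(pair_layout, CompensationPolicy(kind="O"), state, [], 16.7, (960, 540))
        assert all(d.orientation_deg == 0.0 for d in out.disks)

    def test_constant_velocity_integrates(self, pair_layout):
        p = CompensationPolicy(kind="U", c=0.5)
        state = CompensationState(0.0)
        out = advance(pair_layout, p, state, [], 1000.0, (960, 540))
        assert all(d.orientation_deg == pytest.approx(0.5) for d in out.disks)

    def test_event_resets_elapsed_time(self):
        p = CompensationPolicy(kind="B", c=1.0)
        state = CompensationState(5000.0)
        layout = build_layout("exp1_pair", +1)
        advance(layout, p, state, ["saccade"], 11.1, (960, 540))
        assert state.t_since_event_ms == 0.0
        # velocity right at reset equals c * f(0)
        assert policy_velocity(p, 3.0, CompensationState(0.0)) == pytest.approx(0.277)


class TestSimulateTrial:
    def test_vectorized_matches_scalar_policy(self, pair_layout):
        rng = np.random.default_rng(4)
        pos = np.cumsum(rng.normal(0, 6.0, size=(120, 2)), axis=0) + (960.0, 540.0)
        stream = make_stream(pos)
        for kind, kw in [
            ("A", {"c": -0.71}),
            ("B", {"c": -0.35}),
            ("C", {"c": -0.39}),
            ("U", {"c": -0.14}),
            ("EXP1_THRESHOLD", {"delta_theta_deg_per_s": -0.5}),
            ("EXP2_PULSE", {"pulse_amplitude_deg_per_s": -0.8, "dt_ms": 500.0}),
        ]:
            policy = CompensationPolicy(kind=kind, **kw)
            trace = simulate_trial(pair_layout, policy, stream)
            for i in (0, 37, 80, 119):
                state = CompensationState(trace.t_since_event_ms[i])
                for j in (0, 5, 11):
                    want = policy_velocity(policy, trace.ecc_deg[i, j], state)
                    assert trace.v_comp[i, j] == pytest.approx(want, abs=1e-12)

    def test_blink_holds_last_valid_position(self, pair_layout):
        pos = [(700.0, 540.0)] * 30
        valid = np.ones(30, dtype=bool)
        valid[10:15] = False
        stream = make_stream(pos, valid=valid)
        trace = simulate_trial(pair_layout, CompensationPolicy(kind="A", c=-1.0), stream)
        assert np.allclose(trace.ecc_deg[12], trace.ecc_deg[9])


class TestPolicyConfig:
    def test_bundled_defaults_carry_reference_parameters(self):
        pols = default_policies()
        assert pols["A"].c == -0.71
        assert pols["B"].c == -0.35
        assert pols["C"].c == -0.39
        assert pols["U"].c == -0.14
        assert pols["EXP1"].r_th_deg == 8.0
        assert pols["EXP1"].dt_ms == 300.0
        assert pols["B"].temporal.components[0] == (2.56, 100.0)

    def test_load_policies_from_toml(self, tmp_path):
        p = tmp_path / "pol.toml"
        p.write_text(
            "[policies.mine]\nkind = \"U\"\nc = -0.2\n"
            "[policies.other]\nkind = \"EXP2_PULSE\"\ndt_ms = 250.0\n"
            "pulse_amplitude_deg_per_s = -1.5\n"
        )
        pols = load_policies(p)
        assert pols["mine"].c == -0.2
        assert pols["other"].dt_ms == 250.0
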