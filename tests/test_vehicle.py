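"""Arena, kinematics, ray-cast laser, and the Braitenberg demonstration."""

import math

import numpy as np
import pytest

from spikeloop import (
    Arena,
    LaserScanParams,
    RobotState,
    ValidationError,
    braitenberg_wiring,
    default_arena,
    run_braitenberg_demo,
    scan,
    step_kinematics,
)
from spikeloop.runtime import build_graph, run_pipeline


def open_arena():
    """Huge empty arena: every beam reads max range."""
    return Arena(bounds=(-100.0, -100.0, 100.0, 100.0))


class TestKinematics:
    def test_straight_advance(self):
        s = RobotState(x=0, y=0, theta=0)
        s2 = step_kinematics(s, (1.0, 0.0), 1.0)
        assert (s2.x, s2.y) == pytest.approx((1.0, 0.0))

    def test_in_place_half_turn(self):
        s = RobotState(x=0, y=0, theta=0, omega_cap=4.0)
        s2 = step_kinematics(s, (0.0, math.pi), 1.0)
        assert abs(abs(s2.theta) - math.pi) < 1e-9
        assert (s2.x, s2.y) == pytest.approx((0.0, 0.0))

    def test_full_circle_returns_to_start(self):
        s = RobotState(x=1.0, y=2.0, theta=0.5)
        n = 1000
        dt = 2 * math.pi / n
        for _ in range(n):
            s = step_kinematics(s, (1.0, 1.0), dt)
        assert (s.x, s.y) == pytest.approx((1.0, 2.0), abs=1e-9)
        assert s.theta == pytest.approx(0.5, abs=1e-9)

    def test_velocity_caps_applied(self):
        s = RobotState(x=0, y=0, theta=0, v_cap=1.0)
        s2 = step_kinematics(s, (10.0, 0.0), 1.0)
        assert s2.x == pytest.approx(1.0)

    def test_collision_freezes_position_and_flags(self):
        arena = Arena(bounds=(0, 0, 4, 4))
        s = RobotState(x=0.5, y=2.0, theta=math.pi, radius=0.3)
        s2 = step_kinematics(s, (1.0, 0.0), 1.0, arena)
        assert s2.collided and s2.v == 0.0
        assert (s2.x, s2.y) == (s.x, s.y)


class TestScan:
    def test_empty_arena_reads_max_range(self):
        laser = LaserScanParams()
        r = scan(open_arena(), RobotState(x=0, y=0, theta=0.3), laser)
        assert r.shape == (100,)
        assert np.all(r == 5.0)

    def test_wall_dead_ahead(self):
        # wall of the bounding box 2 m in front of the robot
        arena = Arena(bounds=(-10, -10, 2, 10))
        laser = LaserScanParams(n_beams=101)
        r = scan(arena, RobotState(x=0, y=0, theta=0.0), laser)
        assert r[50] == pytest.approx(2.0, abs=1e-9)

    def test_frame_invariance_under_rotation(self):
        # rotating robot and world together leaves the scan unchanged
        c = (2.0, 1.0, 0.5)
        arena1 = Arena(bounds=(-50, -50, 50, 50), circles=[c])
        r1 = scan(arena1, RobotState(x=0, y=0, theta=0.0), LaserScanParams())
        phi = 1.1
        rot = (
            c[0] * math.cos(phi) - c[1] * math.sin(phi),
            c[0] * math.sin(phi) + c[1] * math.cos(phi),
            c[2],
        )
        arena2 = Arena(bounds=(-50, -50, 50, 50), circles=[rot])
        r2 = scan(arena2, RobotState(x=0, y=0, theta=phi), LaserScanParams())
        assert np.allclose(r1, r2, atol=1e-9)

    def test_beam_zero_is_leftmost(self):
        # obstacle placed 90 degrees to the LEFT of the heading
        arena = Arena(bounds=(-50, -50, 50, 50), circles=[(0.0, 2.0, 0.5)])
        r = scan(arena, RobotState(x=0, y=0, theta=0.0), LaserScanParams())
        assert r[0] < 5.0 and r[-1] == 5.0


class TestWiring:
    def test_cruise_straight_when_quiet(self):
        v, om = braitenberg_wiring(0.0, 0.0, v0=0.4)
        assert (v, om) == (0.4, 0.0)

    def test_left_activity_turns_right(self):
        _, om = braitenberg_wiring(2.0, 0.5)
        assert om < 0

    def test_symmetric_activation_slows_down(self):
        v, om = braitenberg_wiring(1.5, 1.5, v0=0.4, k_v=0.12)
        assert om == 0.0
        assert v == pytest.approx(max(0.4 - 0.12 * 3.0, 0.0))


class TestArena:
    def test_obstacle_must_leave_start_pose_free(self):
        arena = Arena(bounds=(0, 0, 4, 4), circles=[(1.0, 1.0, 0.5)])
        assert arena.clearance(1.0, 1.8) == pytest.approx(0.3)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValidationError):
            Arena(bounds=(0, 0, 0, 4))


class TestClosedLoop:
    def _demo_graph(self, env_params):
        specs = [
            ("env", "environment", env_params),
            ("adapt", "adapter", {"adapter": "hemisphere", "m": 100, "n": 2,
                                  "normalize": ("invert_range", 5.0)}),
            ("enc", "encoder", {"mode": "regular", "n_neurons": 2, "v_min": 0.0,
                                "v_max": 100.0}),
            ("neurons", "parrot", {"n_neurons": 2}),
            ("dec", "decoder", {"mode": "exp", "n_neurons": 2, "tau_dec": 0.1}),
            ("motor", "motor", {}),
        ]
        conns = ["env.scan -> adapt.in", "adapt.out -> enc.in",
                 "enc.out -> neurons.in", "neurons.out -> dec.in",
                 "dec.out -> motor.in", "motor.cmd -> env.cmd"]
        return build_graph(specs, conns, 0.05)

    def test_short_demo_run_no_collisions(self):
        res = run_braitenberg_demo(T=15.0, seed=0)
        assert res["collisions"] == 0
        assert res["spikes"].n_neurons == 2
        tr = res["trajectory"]
        assert {"time", "x", "y", "theta", "v", "omega", "collision_flag"} <= set(tr)

    def test_empty_arena_near_straight_trajectory(self):
        g = self._demo_graph({"bounds": (-100, -100, 100, 100), "x0": 0.0,
                              "y0": 0.0, "theta0": 0.0, "heading_jitter": 0.0})
        run_pipeline(g, 20.0, seed=0)
        tr = g.components["env"].trajectory_frame()
        assert g.components["env"].collisions == 0
        drift = np.degrees(np.abs(tr.theta.to_numpy()).max())
        assert drift < 5.0

    def test_left_obstacle_turns_right_on_average(self):
        g = self._demo_graph({"bounds": (0, 0, 40, 40), "circles": [(23.0, 21.5, 1.0)],
                              "x0": 20.0, "y0": 20.0, "theta0": 0.0,
                              "heading_jitter": 0.0})
        run_pipeline(g, 8.0, seed=0)
        tr = g.components["env"].trajectory_frame()
        window = tr[(tr.time > 0.5) & (tr.time < 6.0)]
        assert window.omega.mean() < 0
        assert g.components["env"].collisions == 0

    def test_approaching_wall_raises_sensor_neuron_rate(self):
        """Range down -> proximity code up -> encoder rate up, monotonically."""
        from spikeloop import AdapterSpec, RateEncoderParams, apply_adapter
        from spikeloop import instantaneous_rate
        from spikeloop.core import ContinuousSignal, TimeGrid

        laser = LaserScanParams()
        arena = Arena(bounds=(-10, -10, 2, 10))
        p = RateEncoderParams(v_min=0, v_max=100)
        spec = AdapterSpec("hemisphere", m=100, n=2,
                           normalize=("invert_range", 5.0))
        rates = []
        for x in (-4.0, -2.0, -1.0, 0.0, 1.0):
            r = scan(arena, RobotState(x=x, y=0, theta=0.0), laser)
            sig = ContinuousSignal(TimeGrid(0, 1e-3, 1e-3), r[None, :])
            drive = apply_adapter(sig, spec).values[0]
            rates.append(instantaneous_rate(drive, p).mean())
        assert np.all(np.diff(rates) > 0)
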