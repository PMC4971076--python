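"""2D arena, differential-drive robot, ray-cast laser, Braitenberg demo.

The robot is a disc with unicycle kinematics commanded by a linear /
angular velocity pair (v, omega) — the skid-steer platform reduced to
the command interface it actually exposes.  A fixed-width laser scanner
(100 beams, 5 m range, 20 Hz) sweeps a field of view centered on the
heading; beam 0 is leftmost.

The Braitenberg Vehicle III ("Explorer") demonstration closes the loop:
laser scan -> proximity coding -> hemisphere adapter -> two-neuron rate
encoder -> repeater neurons -> exponential-filter decoder -> wheel
commands.  A nearer obstacle on the LEFT raises the left sensor-neuron
activity and steers the vehicle RIGHT (omega < 0), away from it; a
symmetric head-on activation slows the vehicle down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import ValidationError
from .runtime import (
    Component,
    Connection,
    LatencyProbe,
    PipelineGraph,
    Port,
    ProbeComponent,
    register_component,
    run_pipeline,
)

__all__ = [
    "Arena",
    "RobotState",
    "LaserScanParams",
    "default_arena",
    "step_kinematics",
    "scan",
    "braitenberg_wiring",
    "run_braitenberg_demo",
    "demo_config_path",
]


@dataclass
class Arena:
    """Rectangular arena with circular and polygonal obstacles.

    ``bounds = (xmin, ymin, xmax, ymax)`` in meters; circles are
    ``(cx, cy, r)``; polygons are vertex lists (closed implicitly).
    """

    bounds: tuple[float, float, float, float]
    circles: list[tuple[float, float, float]] = field(default_factory=list)
    polygons: list[list[tuple[float, float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bounds
        if not (x1 > x0 and y1 > y0):
            raise ValidationError("arena bounds must have positive extent")

    def segments(self) -> np.ndarray:
        """All wall + polygon segments as an (S, 4) array (x1, y1, x2, y2)."""
        x0, y0, x1, y1 = self.bounds
        segs = [
            (x0, y0, x1, y0),
            (x1, y0, x1, y1),
            (x1, y1, x0, y1),
            (x0, y1, x0, y0),
        ]
        for poly in self.polygons:
            for a, b in zip(poly, poly[1:] + poly[:1]):
                segs.append((a[0], a[1], b[0], b[1]))
        return np.asarray(segs, dtype=float)

    def clearance(self, x: float, y: float) -> float:
        """Signed distance to the nearest obstacle boundary or wall.

        Negative when the point is outside the bounds or inside an
        obstacle — i.e. a pose with ``clearance < radius`` collides.
        """
        d = math.inf
        segs = self.segments()
        px = np.array([x, y])
        for sx1, sy1, sx2, sy2 in segs:
            a, b = np.array([sx1, sy1]), np.array([sx2, sy2])
            ab = b - a
            tt = np.clip(np.dot(px - a, ab) / max(np.dot(ab, ab), 1e-300), 0.0, 1.0)
            d = min(d, float(np.linalg.norm(px - (a + tt * ab))))
        for cx, cy, r in self.circles:
            d = min(d, abs(math.hypot(x - cx, y - cy) - r))
        x0, y0, x1, y1 = self.bounds
        inside = (x0 <= x <= x1) and (y0 <= y <= y1)
        if inside:
            for cx, cy, r in self.circles:
                if math.hypot(x - cx, y - cy) < r:
                    inside = False
                    break
        if inside:
            for poly in self.polygons:
                if _point_in_polygon(x, y, poly):
                    inside = False
                    break
        return d if inside else -d


@dataclass
class RobotState:
    """Pose + commanded velocities of the disc robot."""

    x: float
    y: float
    theta: float
    v: float = 0.0
    omega: float = 0.0
    radius: float = 0.3
    v_cap: float = 1.0
    omega_cap: float = 2.0
    collided: bool = False


@dataclass
class LaserScanParams:
    n_beams: int = 100
    fov: float = math.pi
    max_range: float = 5.0
    update_rate: float = 20.0


def default_arena() -> Arena:
    """12 x 12 m walled arena with three circular pillars."""
    return Arena(
        bounds=(0.0, 0.0, 12.0, 12.0),
        circles=[(8.5, 8.5, 0.9), (3.0, 8.0, 0.7), (8.0, 3.0, 0.7)],
    )


def _point_in_polygon(x: float, y: float, poly) -> bool:
    inside = False
    for (ax, ay), (bx, by) in zip(poly, poly[1:] + poly[:1]):
        if (ay > y) != (by > y):
            x_cross = ax + (y - ay) / (by - ay) * (bx - ax)
            if x < x_cross:
                inside = not inside
    return inside


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


def step_kinematics(state: RobotState, cmd: tuple[float, float], dt: float,
                    arena: Arena | None = None) -> RobotState:
    """Advance the unicycle model by ``dt`` under command ``(v, omega)``.

    Constant (v, omega) over the step is integrated exactly along the
    circular arc (reducing to the straight-line update as omega -> 0),
    so a full-circle command returns to the start to machine precision.
    Velocity caps are applied; if the new pose would collide (clearance
    below the robot radius) the robot stays put with v forced to 0 and
    the collision flag set.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    v = float(np.clip(cmd[0], -state.v_cap, state.v_cap))
    om = float(np.clip(cmd[1], -state.omega_cap, state.omega_cap))
    th = state.theta
    if abs(om) < 1e-12:
        nx = state.x + v * math.cos(th) * dt
        ny = state.y + v * math.sin(th) * dt
    else:
        nx = state.x + v / om * (math.sin(th + om * dt) - math.sin(th))
        ny = state.y - v / om * (math.cos(th + om * dt) - math.cos(th))
    nth = _wrap_angle(th + om * dt)
    if arena is not None and arena.clearance(nx, ny) < state.radius:
        return replace(state, theta=nth, v=0.0, omega=om, collided=True)
    return replace(state, x=nx, y=ny, theta=nth, v=v, omega=om, collided=False)


def _ray_segments(ox, oy, dx, dy, segs: np.ndarray) -> np.ndarray:
    """Smallest positive ray parameter against each segment (inf if none)."""
    x1, y1, x2, y2 = segs[:, 0], segs[:, 1], segs[:, 2], segs[:, 3]
    ex, ey = x2 - x1, y2 - y1
    denom = dx * ey - dy * ex
    with np.errstate(divide="ignore", invalid="ignore"):
        t = ((x1 - ox) * ey - (y1 - oy) * ex) / denom
        s = ((x1 - ox) * dy - (y1 - oy) * dx) / denom
    ok = (np.abs(denom) > 1e-300) & (t > 1e-9) & (s >= -1e-12) & (s <= 1 + 1e-12)
    return np.where(ok, t, np.inf)


def _ray_circles(ox, oy, dx, dy, circles) -> float:
    best = math.inf
    for cx, cy, r in circles:
        fx, fy = ox - cx, oy - cy
        b = fx * dx + fy * dy
        c = fx * fx + fy * fy - r * r
        disc = b * b - c
        if disc < 0:
            continue
        sq = math.sqrt(disc)
        for t in (-b - sq, -b + sq):
            if t > 1e-9:
                best = min(best, t)
                break
    return best


def scan(arena: Arena, state: RobotState, laser: LaserScanParams) -> np.ndarray:
    """Exact ray-cast range scan; beam 0 leftmost, no hit -> max_range."""
    n = laser.n_beams
    angles = state.theta + (laser.fov / 2) - np.arange(n) * laser.fov / max(n - 1, 1)
    segs = arena.segments()
    ranges = np.empty(n)
    for i, a in enumerate(angles):
        dx, dy = math.cos(a), math.sin(a)
        t = float(np.min(_ray_segments(state.x, state.y, dx, dy, segs)))
        t = min(t, _ray_circles(state.x, state.y, dx, dy, arena.circles))
        ranges[i] = min(t, laser.max_range)
    return ranges


def braitenberg_wiring(aL: float, aR: float, *, v0: float = 0.4, k_v: float = 0.12,
                       k_omega: float = 0.9) -> tuple[float, float]:
    """Explorer wiring: proximity activity inhibits speed, steers away.

    ``v = v0 - k_v * (aL + aR)`` (clamped at 0) and
    ``omega = k_omega * (aR - aL)``: a nearer LEFT obstacle (aL > aR)
    gives omega < 0 — turn right, away from it.
    """
    v = max(v0 - k_v * (aL + aR), 0.0)
    omega = k_omega * (aR - aL)
    return v, omega


@register_component("environment")
class EnvironmentComponent(Component):
    """Arena + robot + laser as a pipeline component.

    Consumes a (v, omega) command, advances the kinematics over the tick
    (zero-order hold), ray-casts a fresh scan, and outputs the raw
    ranges in meters.  Initial heading is jittered by the run seed so
    repeated runs explore different trajectories.
    """

    def __init__(self, name, params, tick):
        super().__init__(name, params, tick)
        bounds = self._p("bounds", (0.0, 0.0, 12.0, 12.0))
        circles = self._p("circles")
        if self._p("arena", None) == "default":
            self.arena = default_arena()
        else:
            self.arena = Arena(
                bounds=tuple(bounds),
                circles=[tuple(c) for c in (circles or [])],
            )
        self.laser = LaserScanParams(
            n_beams=int(self._p("n_beams", 100)),
            fov=float(self._p("fov", math.pi)),
            max_range=float(self._p("max_range", 5.0)),
            update_rate=float(self._p("update_rate", 20.0)),
        )
        self.start = (
            float(self._p("x0", 2.0)),
            float(self._p("y0", 2.0)),
            float(self._p("theta0", math.pi / 4)),
        )
        self.heading_jitter = float(self._p("heading_jitter", 0.5))
        self.radius = float(self._p("radius", 0.3))

    def in_ports(self):
        return {"cmd": Port("cmd", "continuous", 2)}

    def out_ports(self):
        return {"scan": Port("scan", "continuous", self.laser.n_beams)}

    def build(self, rng):
        jitter = self.heading_jitter * (2 * rng.random() - 1)
        self.state = RobotState(
            x=self.start[0], y=self.start[1], theta=self.start[2] + jitter,
            radius=self.radius,
        )
        if self.arena.clearance(self.state.x, self.state.y) < self.radius:
            raise ValidationError("robot start pose collides with the arena")
        self.trajectory: list[tuple] = []
        self.collisions = 0

    def step(self, t, dt, inputs):
        v_cmd, om_cmd = (float(c) for c in inputs["cmd"]) if "cmd" in inputs else (0.0, 0.0)
        self.state = step_kinematics(self.state, (v_cmd, om_cmd), dt, self.arena)
        if self.state.collided:
            self.collisions += 1
        s = self.state
        self.trajectory.append((t, s.x, s.y, s.theta, s.v, s.omega, int(s.collided)))
        return {"scan": scan(self.arena, s, self.laser)}

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.trajectory,
            columns=["time", "x", "y", "theta", "v", "omega", "collision_flag"],
        )


@register_component("motor")
class MotorComponent(Component):
    """Braitenberg wiring: two filtered activities -> one (v, omega) command."""

    def __init__(self, name, params, tick):
        super().__init__(name, params, tick)
        self.v0 = float(self._p("v0", 0.4))
        self.k_v = float(self._p("k_v", 0.12))
        self.k_omega = float(self._p("k_omega", 0.9))

    def in_ports(self):
        return {"in": Port("in", "continuous", 2)}

    def out_ports(self):
        return {"cmd": Port("cmd", "continuous", 2)}

    def step(self, t, dt, inputs):
        aL, aR = float(inputs["in"][0]), float(inputs["in"][1])
        return {"cmd": np.array(braitenberg_wiring(
            aL, aR, v0=self.v0, k_v=self.k_v, k_omega=self.k_omega))}


def demo_config_path() -> str:
    """Path to the shipped Braitenberg demo pipeline config."""
    from importlib.resources import files

    return str(files("spikeloop") / "demos" / "braitenberg.ini")


def run_braitenberg_demo(config=None, T: float = 60.0, seed: int = 0, outdir=None):
    """Run the closed-loop obstacle-avoidance demonstration.

    Loads the shipped 6-component pipeline (or ``config``), attaches a
    spike probe to the controlling neurons, and runs ``T`` seconds of
    simulated time at the 20 Hz sensor/motor rate.  Returns a dict with
    the trajectory DataFrame, the two controlling neurons' spike trains,
    the collision count, and the run timings.
    """
    from .runtime import parse_config

    g = parse_config(config or demo_config_path())
    env = next(
        c for c in g.components.values() if isinstance(c, EnvironmentComponent)
    )
    neuro = next(
        (name for name, c in g.components.items()
         if "event" in {p.ptype for p in c.out_ports().values()}),
        None,
    )
    if neuro is not None:
        probe = ProbeComponent(
            "spike_probe",
            {"width": next(iter(g.components[neuro].out_ports().values())).width,
             "ptype": "event"},
            g.music_dt,
        )
        g.components["spike_probe"] = probe
        out_port = next(iter(g.components[neuro].out_ports()))
        g.connections.append(
            Connection(neuro, out_port, "spike_probe", "in", 0, "")
        )
        g._validate()

    res = run_pipeline(g, T, seed=seed, outdir=outdir)
    traj = env.trajectory_frame()
    out = {
        "trajectory": traj,
        "spikes": res["probes"].get("spike_probe"),
        "collisions": env.collisions,
        "timings": res["timings"],
        "conservation": res["conservation"],
    }
    if outdir is not None:
        import pathlib

        traj.to_csv(pathlib.Path(outdir) / "trajectory.csv", index=False)
    return out
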