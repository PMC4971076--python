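"""Tick-based co-simulation engine with per-hop buffered ports.

A pipeline is a graph of named components (sources, adapters, encoders,
decoders, neural simulators, environments, probes) connected through
typed ports.  The engine advances a global tick of ``music_dt`` seconds;
every connection buffers its data for exactly one tick — a value
produced at tick *k* is visible to the consumer at tick *k + 1* — so the
sensory-to-motor latency of a chain of *c* connections is ``c * music_dt``
in simulated time, growing linearly with the tick period.  Feedback
loops are always legal because every hop is buffered.

Ports are ``continuous`` (a float vector per tick, zero-order hold) or
``event`` (a list of ``(neuron_id, spike_time)`` tuples produced during
the tick).  Spike counts are conserved across every connection and the
engine records them per hop.

Configs are INI-style text: top-level ``music_dt``, one section per
component with ``kind =`` plus parameters, and ``connect src.port ->
dst.port [width]`` lines.
"""

from __future__ import annotations

import ast
import itertools
import json
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ContinuousSignal, RunTimings, SpikeTrainSet, TimeGrid, ValidationError
from .adapters import AdapterSpec, apply_adapter
from .encoders import RateCodeStepper, RateEncoderParams
from .neurosim import (
    LIFParams,
    LIFState,
    NetworkSpec,
    build_balanced_network,
    lif_step,
)

__all__ = [
    "Port",
    "Component",
    "Connection",
    "PipelineGraph",
    "LatencyReport",
    "LatencyProbe",
    "register_component",
    "parse_config",
    "run_pipeline",
    "measure_latency",
    "sweep",
]


@dataclass(frozen=True)
class Port:
    name: str
    ptype: str  # 'continuous' | 'event'
    width: int


class Component:
    """Base class: subclasses declare ports and implement ``step``."""

    def __init__(self, name: str, params: dict, tick: float):
        self.name = name
        self.params = params
        self.tick = tick

    def in_ports(self) -> dict[str, Port]:
        return {}

    def out_ports(self) -> dict[str, Port]:
        return {}

    def build(self, rng: np.random.Generator) -> None:
        """Allocate state; called once before the run barrier."""

    def step(self, t: float, dt: float, inputs: dict) -> dict:
        raise NotImplementedError

    def finalize(self) -> None:
        pass

    def _p(self, key, default=None, required=False):
        if required and key not in self.params:
            raise ValidationError(f"component {self.name!r}: missing parameter {key!r}")
        return self.params.get(key, default)


@dataclass
class Connection:
    src: str
    src_port: str
    dst: str
    dst_port: str
    width: int
    ptype: str
    sent: int = 0
    received: int = 0

    @property
    def label(self) -> str:
        return f"{self.src}.{self.src_port}->{self.dst}.{self.dst_port}"


@dataclass
class LatencyReport:
    stimulus_time: float
    response_time: float
    latency: float
    hops: int
    music_dt: float

    def __post_init__(self) -> None:
        if self.latency < 0:
            raise ValidationError("latency must be >= 0")


@dataclass
class LatencyProbe:
    """Where to look for the step response of a latency measurement."""

    probe: str
    stimulus_time: float
    channel: int = 0
    threshold: float = 0.5
    baseline: float = 0.0
    source: str | None = None  # for hop counting


# ---------------------------------------------------------------------------
# component registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, type[Component]] = {}


def register_component(kind: str):
    def deco(cls):
        _REGISTRY[kind] = cls
        return cls

    return deco


@register_component("source")
class SourceComponent(Component):
    """Analytic test-signal source: constant, step, sine or randomwalk.

    The step source is the latency-probe stimulus: it switches from
    ``lo`` to ``hi`` at ``t_step`` (quantized to the tick it falls in).
    """

    def __init__(self, name, params, tick):
        super().__init__(name, params, tick)
        self.channels = int(self._p("channels", 1))
        self.signal_kind = self._p("signal", "constant")

    def out_ports(self):
        return {"out": Port("out", "continuous", self.channels)}

    def build(self, rng):
        self._rng = rng
        self._walk = np.zeros(self.channels)

    def step(self, t, dt, inputs):
        k = self.signal_kind
        if k == "constant":
            v = np.full(self.channels, float(self._p("value", 0.0)))
        elif k == "step":
            lo, hi = float(self._p("lo", -1.0)), float(self._p("hi", 1.0))
            v = np.full(self.channels, hi if t >= float(self._p("t_step", 0.0)) - 1e-12 else lo)
        elif k == "sine":
            f, amp = float(self._p("freq", 1.0)), float(self._p("amp", 1.0))
            v = np.full(self.channels, amp * np.sin(2 * np.pi * f * t))
        elif k == "randomwalk":
            sigma = float(self._p("sigma", 1.0))
            self._walk = np.clip(
                self._walk + self._rng.normal(0, sigma * np.sqrt(dt), self.channels), -1, 1
            )
            v = self._walk.copy()
        else:
            raise ValidationError(f"source {self.name!r}: unknown signal {k!r}")
        return {"out": np.clip(v, -1.0, 1.0)}


@register_component("adapter")
class AdapterComponent(Component):
    """Dimension/normalization adapter around :func:`adapters.apply_adapter`."""

    def __init__(self, name, params, tick):
        super().__init__(name, params, tick)
        norm = self._p("normalize")
        if isinstance(norm, str):
            norm = ast.literal_eval(norm)
        self.spec = AdapterSpec(
            kind=self._p("adapter", "identity"),
            m=int(self._p("m", 1)),
            n=int(self._p("n", 1)),
            matrix=self._p("matrix"),
            normalize=tuple(norm) if norm else None,
        )

    def in_ports(self):
        return {"in": Port("in", "continuous", self.spec.m)}

    def out_ports(self):
        return {"out": Port("out", "continuous", self.spec.n)}

    def step(self, t, dt, inputs):
        grid = TimeGrid(t, t + dt, dt)
        sig = ContinuousSignal(grid, inputs["in"][None, :])
        out = apply_adapter(sig, self.spec)
        return {"out": out.values[0]}


@register_component("encoder")
class EncoderComponent(Component):
    """Regular or Poisson rate encoder, one neuron per drive channel."""

    def __init__(self, name, params, tick):
        super().__init__(name, params, tick)
        self.n = int(self._p("n_neurons", 1))
        self.ep = RateEncoderParams(
            v_min=float(self._p("v_min", 0.0)),
            v_max=float(self._p("v_max", 100.0)),
            n_neurons=self.n,
            mode=self._p("mode", "regular"),
            seed=0,  # replaced in build()
        )

    def in_ports(self):
        return {"in": Port("in", "continuous", self.n)}

    def out_ports(self):
        return {"out": Port("out", "event", self.n)}

    def build(self, rng):
        if self.ep.mode == "poisson":
            self.ep.seed = int(rng.integers(2**31))
        self.stepper = RateCodeStepper(self.ep)

    def step(self, t, dt, inputs):
        return {"out": self.stepper.advance(t, dt, inputs["in"])}


@register_component("decoder")
class DecoderComponent(Component):
    """Exponential-filter + linear-readout decoder (or raw counts).

    ``mode='exp'`` keeps one exponentially filtered activity per input
    neuron (time constant ``tau_dec``), updated exactly per tick;
    ``mode='count'`` has no intrinsic time constant (the latency-probe
    decoder) and outputs the per-tick spike count.  Output is
    ``activities @ weights``; ``weights`` defaults to identity.
    """

    def __init__(self, name, params, tick):
        super().__init__(name, params, tick)
        self.n = int(self._p("n_neurons", 1))
        self.mode = self._p("mode", "exp")
        self.tau = float(self._p("tau_dec", 0.02))
        w = self._p("weights")
        self.W = np.eye(self.n) if w is None else np.atleast_2d(np.asarray(w, dtype=float))
        if self.W.shape[0] != self.n:
            raise ValidationError(
                f"decoder {self.name!r}: weights shape {self.W.shape} "
                f"incompatible with {self.n} input neurons"
            )
        self.k = self.W.shape[1]

    def in_ports(self):
        return {"in": Port("in", "event", self.n)}

    def out_ports(self):
        return {"out": Port("out", "continuous", self.k)}

    def build(self, rng):
        self.a = np.zeros(self.n)

    def step(self, t, dt, inputs):
        events = inputs["in"]
        if self.mode == "count":
            a = np.zeros(self.n)
            for nid, _ts in events:
                a[nid] += 1.0
        else:
            t_end = t + dt
            self.a *= np.exp(-dt / self.tau)
            for nid, ts in events:
                self.a[nid] += np.exp(-max(t_end - ts, 0.0) / self.tau)
            a = self.a
        return {"out": a @ self.W}


@register_component("parrot")
class ParrotComponent(Component):
    """Repeater neurons: one output spike per input spike, shifted by ``delay``."""

    def __init__(self, name, params, tick):
        super().__init__(name, params, tick)
        self.n = int(self._p("n_neurons", 1))
        self.delay = float(self._p("delay", 0.0))

    def in_ports(self):
        return {"in": Port("in", "event", self.n)}

    def out_ports(self):
        return {"out": Port("out", "event", self.n)}

    def build(self, rng):
        self._pending: list[tuple[int, float]] = []

    def step(self, t, dt, inputs):
        for nid, ts in inputs["in"]:
            self._pending.append((nid, ts + self.delay))
        due = [e for e in self._pending if e[1] < t + dt]
        self._pending = [e for e in self._pending if e[1] >= t + dt]
        return {"out": due}


@register_component("lif_group")
class LIFGroupComponent(Component):
    """Independent LIF neurons driven by input spikes (delta synapses).

    One input channel per neuron; each input spike causes a voltage jump
    of ``weight`` mV at the next neural substep.  Optional bias current
    ``I_e`` (pA).  Substeps at the neural resolution ``lif_dt``.
    """

    def __init__(self, name, params, tick):
        super().__init__(name, params, tick)
        self.n = int(self._p("n_neurons", 1))
        self.weight = float(self._p("weight", 1.0))
        self.I_e = float(self._p("I_e", 0.0))
        self.lif = LIFParams(dt=float(self._p("lif_dt", 1e-3)))

    def in_ports(self):
        return {"in": Port("in", "event", self.n)}

    def out_ports(self):
        return {"out": Port("out", "event", self.n)}

    def build(self, rng):
        self.state = LIFState.resting(self.n, self.lif)

    def step(self, t, dt, inputs):
        p = self.lif
        substeps = max(1, int(round(dt / p.dt)))
        jumps = np.zeros((substeps, self.n))
        for nid, ts in inputs["in"]:
            k = min(max(int((ts - (t - dt)) / p.dt), 0), substeps - 1)
            # buffered events carry last-tick timestamps; deliver in order
            jumps[k, nid] += self.weight
        out = []
        for k in range(substeps):
            self.state, spiked = lif_step(self.state, self.I_e, jumps[k], p)
            if np.any(spiked):
                ts = t + (k + 1) * p.dt
                out.extend((int(i), ts) for i in np.nonzero(spiked)[0])
        return {"out": out}


@register_component("balanced_network")
class BalancedNetworkComponent(Component):
    """The 80/20 balanced random network as a pipeline load component.

    Input spikes (optional) are injected onto neurons 0..k-1 at weight
    ``w_ext``; the output port carries the spikes of the first
    ``n_record`` neurons.
    """

    def __init__(self, name, params, tick):
        super().__init__(name, params, tick)
        self.n_total = int(self._p("n_total", 1000))
        self.n_in = int(self._p("n_in", self.n_total))
        self.n_record = int(self._p("n_record", min(100, self.n_total)))
        self.spec_kwargs = {
            k: self.params[k]
            for k in ("w", "g", "indegree_frac", "delay", "ext_rate", "w_ext")
            if k in self.params
        }

    def in_ports(self):
        return {"in": Port("in", "event", self.n_in)}

    def out_ports(self):
        return {"out": Port("out", "event", self.n_record)}

    def build(self, rng):
        spec = NetworkSpec(n_total=self.n_total, seed=int(rng.integers(2**31)),
                           **{k: float(v) for k, v in self.spec_kwargs.items()})
        self.net = build_balanced_network(spec)
        self.state = LIFState.resting(self.n_total, spec.lif)
        self.d_steps = max(1, int(round(spec.delay / spec.lif.dt)))
        self.ring = np.zeros((self.d_steps, self.n_total))
        self._k = 0
        self._rng = np.random.default_rng(rng.integers(2**31))

    def step(self, t, dt, inputs):
        spec, p = self.net.spec, self.net.spec.lif
        substeps = max(1, int(round(dt / p.dt)))
        jumps = np.zeros((substeps, self.n_total))
        for nid, ts in inputs["in"]:
            if nid < self.n_total:
                k = min(max(int((ts - (t - dt)) / p.dt), 0), substeps - 1)
                jumps[k, nid] += spec.w_ext
        out = []
        for k in range(substeps):
            slot = self._k % self.d_steps
            dj = self.ring[slot].copy()
            self.ring[slot] = 0.0
            dj += self._rng.poisson(spec.ext_rate * p.dt, size=self.n_total) * spec.w_ext
            dj += jumps[k]
            self.state, spiked = lif_step(self.state, 0.0, dj, p)
            ids = np.nonzero(spiked)[0]
            if ids.size:
                arrive = (self._k + self.d_steps) % self.d_steps
                for j in ids:
                    tg = self.net.targets_of(j)
                    if tg.size:
                        self.ring[arrive][tg] += self.net.weights[j]
                ts = t + (k + 1) * p.dt
                out.extend((int(i), ts) for i in ids if i < self.n_record)
            self._k += 1
        return {"out": out}


@register_component("passthrough")
class PassthroughComponent(Component):
    """Instantaneous identity on a continuous port (hop-latency probe stage)."""

    def __init__(self, name, params, tick):
        super().__init__(name, params, tick)
        self.width = int(self._p("width", 1))
        self.gain = float(self._p("gain", 1.0))

    def in_ports(self):
        return {"in": Port("in", "continuous", self.width)}

    def out_ports(self):
        return {"out": Port("out", "continuous", self.width)}

    def step(self, t, dt, inputs):
        return {"out": self.gain * inputs["in"]}


@register_component("probe")
class ProbeComponent(Component):
    """Records everything arriving on its input port, with tick timestamps."""

    def __init__(self, name, params, tick):
        super().__init__(name, params, tick)
        self.width = int(self._p("width", 1))
        self.ptype = self._p("ptype", "continuous")

    def in_ports(self):
        return {"in": Port("in", self.ptype, self.width)}

    def build(self, rng):
        self.times: list[float] = []
        self.values: list[np.ndarray] = []
        self.events: list[tuple[int, float]] = []

    def step(self, t, dt, inputs):
        if self.ptype == "continuous":
            self.times.append(t)
            self.values.append(np.array(inputs["in"], dtype=float, copy=True))
        else:
            self.events.extend(inputs["in"])
        return {}

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(np.array(self.values) if self.values else np.empty((0, self.width)))
        df.columns = [f"ch{i}" for i in range(self.width)]
        df.insert(0, "time", self.times)
        return df

    def as_spikes(self, window: TimeGrid) -> SpikeTrainSet:
        trains: list[list[float]] = [[] for _ in range(self.width)]
        for nid, ts in self.events:
            trains[nid].append(ts)
        return SpikeTrainSet(trains, window)


# ---------------------------------------------------------------------------
# graph + config
# ---------------------------------------------------------------------------

class PipelineGraph:
    """Validated component graph with typed, width-checked connections."""

    def __init__(self, components: dict[str, Component], connections: list[Connection],
                 music_dt: float):
        if not components:
            raise ValidationError("no components in pipeline")
        if music_dt <= 0:
            raise ValidationError("music_dt must be positive")
        self.components = components
        self.connections = connections
        self.music_dt = music_dt
        self._validate()

    def _validate(self) -> None:
        for c in self.connections:
            for end, port_name, ports in (
                (c.src, c.src_port, "out"),
                (c.dst, c.dst_port, "in"),
            ):
                if end not in self.components:
                    raise ValidationError(f"connection {c.label}: unknown component {end!r}")
            src_ports = self.components[c.src].out_ports()
            dst_ports = self.components[c.dst].in_ports()
            if c.src_port not in src_ports:
                raise ValidationError(
                    f"connection {c.label}: {c.src!r} has no output port {c.src_port!r}"
                )
            if c.dst_port not in dst_ports:
                raise ValidationError(
                    f"connection {c.label}: {c.dst!r} has no input port {c.dst_port!r}"
                )
            sp, dp = src_ports[c.src_port], dst_ports[c.dst_port]
            if sp.ptype != dp.ptype:
                raise ValidationError(
                    f"connection {c.label}: port type mismatch {sp.ptype} -> {dp.ptype}"
                )
            if sp.width != dp.width:
                raise ValidationError(
                    f"width mismatch on {c.label}: {sp.width} -> {dp.width}"
                )
            if c.width and c.width != sp.width:
                raise ValidationError(
                    f"width mismatch on {c.label}: declared {c.width}, ports {sp.width}"
                )
            c.width = sp.width
            c.ptype = sp.ptype
        # weak connectivity
        if len(self.components) > 1:
            adj: dict[str, set[str]] = {n: set() for n in self.components}
            for c in self.connections:
                adj[c.src].add(c.dst)
                adj[c.dst].add(c.src)
            seen = set()
            stack = [next(iter(self.components))]
            while stack:
                n = stack.pop()
                if n in seen:
                    continue
                seen.add(n)
                stack.extend(adj[n] - seen)
            if seen != set(self.components):
                missing = sorted(set(self.components) - seen)
                raise ValidationError(f"pipeline graph is not connected: {missing} unreachable")
        for comp in self.components.values():
            ratio = comp.tick / self.music_dt
            if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
                raise ValidationError(
                    f"component {comp.name!r}: tick {comp.tick} is not an integer "
                    f"multiple of music_dt {self.music_dt}"
                )

    def hops_between(self, src: str, dst: str) -> int:
        """Number of buffered connections on the shortest path src -> dst."""
        from collections import deque

        adj: dict[str, list[str]] = {n: [] for n in self.components}
        for c in self.connections:
            adj[c.src].append(c.dst)
        q = deque([(src, 0)])
        seen = {src}
        while q:
            n, d = q.popleft()
            if n == dst:
                return d
            for m in adj[n]:
                if m not in seen:
                    seen.add(m)
                    q.append((m, d + 1))
        raise ValidationError(f"no directed path from {src!r} to {dst!r}")


def _parse_value(raw: str):
    raw = raw.strip()
    try:
        return ast.literal_eval(raw)
    except (ValueError, SyntaxError):
        return raw


def parse_config(path, overrides: dict | None = None, *, strict: bool = True) -> PipelineGraph:
    """Parse an INI-style pipeline config into a validated graph.

    Format: optional top-level ``music_dt = <seconds>``, ``[name]``
    sections with ``kind = <registered kind>``, ``tick = <seconds>`` and
    arbitrary parameters, plus ``connect src.port -> dst.port [width]``
    lines.  ``overrides`` maps dotted keys (``section.param`` or
    ``music_dt``) onto replacement values.
    """
    sections: dict[str, dict] = {}
    top: dict = {}
    conns: list[tuple[str, str, str, str, int]] = []
    current: dict | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                name = line[1:-1].strip()
                if name in sections:
                    raise ValidationError(f"{path}:{lineno}: duplicate section {name!r}")
                current = sections.setdefault(name, {})
                continue
            if line.startswith("connect"):
                rest = line[len("connect"):].strip()
                if "->" not in rest:
                    raise ValidationError(f"{path}:{lineno}: malformed connect line")
                lhs, rhs = (s.strip() for s in rest.split("->", 1))
                parts = rhs.split()
                rhs, width = parts[0], int(parts[1]) if len(parts) > 1 else 0
                try:
                    src, sp = lhs.rsplit(".", 1)
                    dst, dp = rhs.rsplit(".", 1)
                except ValueError:
                    raise ValidationError(
                        f"{path}:{lineno}: connect endpoints must be component.port"
                    ) from None
                conns.append((src, sp, dst, dp, width))
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected key = value, got {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            (top if current is None else current)[key] = _parse_value(val)

    for key, val in (overrides or {}).items():
        if "." in key:
            sec, param = key.split(".", 1)
            if sec not in sections:
                raise ValidationError(f"override {key!r}: unknown section {sec!r}")
            sections[sec][param] = val
        else:
            top[key] = val

    music_dt = float(top.pop("music_dt", 0.05))
    if strict and top:
        raise ValidationError(f"unknown top-level keys: {sorted(top)}")

    components: dict[str, Component] = {}
    for name, params in sections.items():
        params = dict(params)
        kind = params.pop("kind", None)
        if kind is None:
            raise ValidationError(f"section [{name}] missing 'kind'")
        if kind not in _REGISTRY:
            raise ValidationError(
                f"section [{name}]: unknown component kind {kind!r}; "
                f"registered: {sorted(_REGISTRY)}"
            )
        tick = float(params.pop("tick", music_dt))
        components[name] = _REGISTRY[kind](name, params, tick)

    connections = [
        Connection(src, sp, dst, dp, width, "") for src, sp, dst, dp, width in conns
    ]
    return PipelineGraph(components, connections, music_dt)


def build_graph(specs: list[tuple[str, str, dict]], connections: list[str],
                music_dt: float) -> PipelineGraph:
    """Programmatic graph construction.

    ``specs`` are (name, kind, params) triples; ``connections`` are
    ``"src.port -> dst.port"`` strings.
    """
    comps: dict[str, Component] = {}
    for name, kind, params in specs:
        params = dict(params)
        tick = float(params.pop("tick", music_dt))
        comps[name] = _REGISTRY[kind](name, params, tick)
    conns = []
    for line in connections:
        lhs, rhs = (s.strip() for s in line.split("->"))
        src, sp = lhs.rsplit(".", 1)
        dst, dp = rhs.rsplit(".", 1)
        conns.append(Connection(src, sp, dst, dp, 0, ""))
    return PipelineGraph(comps, conns, music_dt)


# ---------------------------------------------------------------------------
# scheduler
# ---------------------------------------------------------------------------

def run_pipeline(g: PipelineGraph, T: float, seed: int = 0, outdir=None):
    """Run the pipeline for ``T`` simulated seconds.

    Components execute once per their tick; every connection delivers
    with exactly one ``music_dt`` of buffering.  Build and run phases are
    timed separately around an explicit barrier; the returned
    :class:`RunTimings` carries the wall-clock real-time factor of this
    process.  Deterministic given ``seed``.

    Returns a dict with ``timings``, ``probes`` (name -> DataFrame or
    SpikeTrainSet), and per-connection ``conservation`` counts.
    """
    ticks = round(T / g.music_dt)
    if abs(ticks * g.music_dt - T) > 1e-9:
        raise ValidationError("T must be a multiple of music_dt")

    t_wall0 = time.perf_counter()
    streams = np.random.SeedSequence(seed).spawn(len(g.components))
    for comp, ss in zip(g.components.values(), streams):
        comp.build(np.random.default_rng(ss))
    # explicit barrier between build and run phases
    t_barrier = time.perf_counter()

    visible: dict[tuple[str, str], object] = {}
    pending: dict[tuple[str, str], object] = {}
    inbox: dict[tuple[str, str], list] = {}
    by_dst: dict[str, list[Connection]] = {}
    by_src: dict[tuple[str, str], list[Connection]] = {}
    for c in g.connections:
        key_dst = (c.dst, c.dst_port)
        by_dst.setdefault(c.dst, []).append(c)
        by_src.setdefault((c.src, c.src_port), []).append(c)
        if c.ptype == "continuous":
            visible[key_dst] = np.zeros(c.width)
        else:
            inbox[key_dst] = []

    order = list(g.components.values())
    for k in range(ticks):
        t = k * g.music_dt
        produced: dict[tuple[str, str], object] = {}
        for comp in order:
            stride = round(comp.tick / g.music_dt)
            if k % stride:
                continue
            ins = {}
            for c in by_dst.get(comp.name, []):
                key = (c.dst, c.dst_port)
                if c.ptype == "continuous":
                    ins[c.dst_port] = visible[key]
                else:
                    ins[c.dst_port] = inbox[key]
                    c.received += len(inbox[key])
                    inbox[key] = []
            try:
                outs = comp.step(t, comp.tick, ins)
            except ValidationError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise RuntimeError(
                    f"component {comp.name!r} failed at tick {k} (t={t:g}s): {exc}"
                ) from exc
            for port, val in (outs or {}).items():
                produced[(comp.name, port)] = val
        # promote: data produced at tick k becomes visible at tick k+1
        for key, val in produced.items():
            for c in by_src.get(key, []):
                dkey = (c.dst, c.dst_port)
                if c.ptype == "continuous":
                    visible[dkey] = np.asarray(val, dtype=float)
                else:
                    ev = list(val)
                    c.sent += len(ev)
                    inbox[dkey].extend(ev)

    # account for events still in flight in the one-tick buffers
    for c in g.connections:
        if c.ptype == "event":
            key = (c.dst, c.dst_port)
            c.received += len(inbox[key])

    t_run_end = time.perf_counter()
    for comp in order:
        comp.finalize()
    t_final = time.perf_counter()
    timings = RunTimings(
        t_sim=T,
        t_build=t_barrier - t_wall0,
        t_run=t_run_end - t_barrier,
        epsilon=t_final - t_run_end,
    )

    window = TimeGrid(0.0, max(T, g.music_dt), g.music_dt)
    probes: dict[str, object] = {}
    for name, comp in g.components.items():
        if isinstance(comp, ProbeComponent):
            probes[name] = (
                comp.as_frame() if comp.ptype == "continuous" else comp.as_spikes(window)
            )
    conservation = {c.label: (c.sent, c.received) for c in g.connections}

    if outdir is not None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_spikes

        for name, rec in probes.items():
            if isinstance(rec, pd.DataFrame):
                rec.to_csv(out / f"{name}.csv", index=False, float_format="%.17g")
            else:
                write_spikes(rec, out / f"{name}.gdf")
        summary = {
            "t_sim": timings.t_sim,
            "t_build": timings.t_build,
            "t_run": timings.t_run,
            "epsilon": timings.epsilon,
            "rtf": timings.rtf,
            "conservation": conservation,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))

    return {"timings": timings, "probes": probes, "conservation": conservation}


def measure_latency(g: PipelineGraph, probe_spec: LatencyProbe, T: float,
                    seed: int = 0) -> LatencyReport:
    """Step-response latency of a pipeline, in simulated time.

    Runs the pipeline and reports the first tick at which the probed
    channel deviates from ``baseline`` by more than ``threshold``, minus
    the stimulus time.  With instantaneous components the result is
    purely architectural: (number of buffered hops) x music_dt.
    """
    res = run_pipeline(g, T, seed=seed)
    rec = res["probes"].get(probe_spec.probe)
    if rec is None or not isinstance(rec, pd.DataFrame):
        raise ValidationError(f"no continuous probe named {probe_spec.probe!r}")
    dev = np.abs(rec[f"ch{probe_spec.channel}"].to_numpy() - probe_spec.baseline)
    hit = np.nonzero(dev > probe_spec.threshold)[0]
    if hit.size == 0:
        raise ValidationError(
            f"no response within T={rec['time'].iloc[-1] if len(rec) else 0}s "
            f"(max deviation {dev.max() if dev.size else 0:g} <= "
            f"threshold {probe_spec.threshold:g})"
        )
    response_time = float(rec["time"].iloc[hit[0]])
    hops = 0
    if probe_spec.source is not None:
        hops = g.hops_between(probe_spec.source, probe_spec.probe)
    return LatencyReport(
        stimulus_time=probe_spec.stimulus_time,
        response_time=response_time,
        latency=response_time - probe_spec.stimulus_time,
        hops=hops,
        music_dt=g.music_dt,
    )


def sweep(config_path, param_grid: dict[str, list], T: float, seed: int = 0,
          probe_spec: LatencyProbe | None = None) -> pd.DataFrame:
    """Run the config once per grid point; return a tidy results table.

    ``param_grid`` maps dotted override keys (``music_dt`` or
    ``section.param``) to value lists; the cartesian product is run with
    deterministically offset seeds.  Columns: the grid parameters, seed,
    rtf, and (with a ``probe_spec``) latency and hops.
    """
    keys = list(param_grid)
    rows = []
    for i, combo in enumerate(itertools.product(*(param_grid[k] for k in keys))):
        overrides = dict(zip(keys, combo))
        g = parse_config(config_path, overrides=overrides)
        run_seed = seed + i
        row = dict(overrides)
        row["seed"] = run_seed
        if probe_spec is not None:
            rep = measure_latency(g, probe_spec, T, seed=run_seed)
            row["latency"] = rep.latency
            row["hops"] = rep.hops
            row["rtf"] = float("nan")
        else:
            res = run_pipeline(g, T, seed=run_seed)
            row["rtf"] = res["timings"].rtf
        rows.append(row)
    return pd.DataFrame(rows)
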