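"""File formats and test-signal fixtures.

Spike trains travel as plain two-column ASCII (neuron id, spike time in
seconds), one spike per line, ``#`` comments allowed — the de-facto
gdf-style convention of the spiking-simulator ecosystem.  Continuous
signals travel as CSV with a ``time,ch0,ch1,...`` header on a uniform
time column.  Both round-trip losslessly at double precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GRID_ATOL, ContinuousSignal, SpikeTrainSet, TimeGrid, ValidationError

__all__ = [
    "read_spikes",
    "write_spikes",
    "read_signal",
    "write_signal",
    "make_fixture",
    "FIXTURE_KINDS",
]


def read_spikes(path, *, window: TimeGrid | None = None, n_neurons: int | None = None) -> SpikeTrainSet:
    """Parse a two-column ASCII spike file into a :class:`SpikeTrainSet`.

    Lines are ``<neuron_id> <time_in_seconds>``; blank lines and ``#``
    comments are skipped.  If ``window`` is omitted it is inferred as
    ``[0, max_time rounded up to 1 ms)`` (or ``[0, 1 ms)`` for an empty
    file).  ``n_neurons`` extends the train list beyond the largest id
    seen (ids are zero-based).
    """
    ids, times = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected '<neuron_id> <time>', got {raw!r}"
                )
            try:
                nid = int(parts[0])
                t = float(parts[1])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if t < 0:
                raise ValidationError(f"{path}:{lineno}: negative spike time {t}")
            if nid < 0:
                raise ValidationError(f"{path}:{lineno}: negative neuron id {nid}")
            ids.append(nid)
            times.append(t)

    n = max(ids) + 1 if ids else 0
    if n_neurons is not None:
        if ids and n > n_neurons:
            raise ValidationError(
                f"file contains neuron id {n - 1} but n_neurons={n_neurons}"
            )
        n = n_neurons
    if window is None:
        dt = 1e-3
        t_max = max(times) if times else 0.0
        t_stop = max(dt, np.ceil((t_max + GRID_ATOL) / dt) * dt)
        # ensure strict inclusion of the last spike in the half-open window
        if times and t_stop <= t_max:
            t_stop += dt
        window = TimeGrid(0.0, float(t_stop), dt)
    trains = [[] for _ in range(n)]
    for nid, t in zip(ids, times):
        trains[nid].append(t)
    return SpikeTrainSet(trains, window)


def write_spikes(spikes: SpikeTrainSet, path) -> None:
    """Write spikes in time-major order (merged across neurons)."""
    nid = np.concatenate(
        [np.full(t.size, n, dtype=int) for n, t in enumerate(spikes.trains)]
        or [np.empty(0, dtype=int)]
    )
    t = np.concatenate(spikes.trains or [np.empty(0)])
    order = np.argsort(t, kind="stable")
    with open(path, "w") as fh:
        fh.write("# neuron_id time_s\n")
        for i in order:
            fh.write(f"{nid[i]} {t[i]:.12g}\n")


def read_signal(path) -> ContinuousSignal:
    """Read a ``time,ch0,...`` CSV into a :class:`ContinuousSignal`.

    The time column must be uniform; the offending row is named otherwise.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need a time column plus >= 1 channel")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if t.size < 2:
        raise ValidationError(f"{path}: need >= 2 samples to infer the grid")
    dt = t[1] - t[0]
    steps = np.diff(t)
    bad = np.nonzero(np.abs(steps - dt) > max(GRID_ATOL, 1e-9 * abs(dt)))[0]
    if bad.size:
        row = int(bad[0]) + 2  # +1 for header, +1 for 0-based diff index
        raise ValidationError(
            f"{path}: non-uniform grid at data row {row} "
            f"(step {steps[bad[0]]:g}, expected {dt:g})"
        )
    grid = TimeGrid(float(t[0]), float(t[0] + dt * t.size), float(dt))
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    normalized = bool(values.size) and values.min() >= -1 and values.max() <= 1
    return ContinuousSignal(grid, values, normalized=normalized)


def write_signal(sig: ContinuousSignal, path) -> None:
    cols = {"time": sig.grid.times()}
    for k in range(sig.channels):
        cols[f"ch{k}"] = sig.values[:, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


FIXTURE_KINDS = ("constant", "step", "sine", "randomwalk", "ramp")


def make_fixture(kind: str, grid: TimeGrid, *, channels: int = 1, seed: int | None = None,
                 **params) -> ContinuousSignal:
    """Deterministic normalized test signals.

    kinds
    -----
    constant : ``value`` (default 0.0) on every sample
    step     : jumps from ``lo`` (default -1) to ``hi`` (default +1) at
               ``t_step`` (default mid-window); the latency probe stimulus
    sine     : ``amp * sin(2*pi*freq*(t - t_start) + phase)``
    randomwalk : clipped Gaussian increments, ``sigma`` per sqrt(s); needs seed
    ramp     : linear from ``lo`` to ``hi`` across the window
    """
    t = grid.times()
    if kind == "constant":
        value = float(params.pop("value", 0.0))
        v = np.full((grid.n_samples, channels), value)
    elif kind == "step":
        lo = float(params.pop("lo", -1.0))
        hi = float(params.pop("hi", 1.0))
        t_step = float(params.pop("t_step", 0.5 * (grid.t_start + grid.t_stop)))
        v = np.where(t[:, None] >= t_step - GRID_ATOL, hi, lo)
        v = np.broadcast_to(v, (grid.n_samples, channels)).copy()
    elif kind == "sine":
        freq = float(params.pop("freq", 1.0))
        amp = float(params.pop("amp", 1.0))
        phase = float(params.pop("phase", 0.0))
        v = amp * np.sin(2 * np.pi * freq * (t - grid.t_start) + phase)
        v = np.repeat(v[:, None], channels, axis=1)
    elif kind == "randomwalk":
        if seed is None:
            raise ValidationError("randomwalk fixture requires a seed")
        sigma = float(params.pop("sigma", 1.0))
        rng = np.random.default_rng(seed)
        steps = rng.normal(0.0, sigma * np.sqrt(grid.dt), size=(grid.n_samples, channels))
        v = np.clip(np.cumsum(steps, axis=0), -1.0, 1.0)
    elif kind == "ramp":
        lo = float(params.pop("lo", -1.0))
        hi = float(params.pop("hi", 1.0))
        frac = (t - grid.t_start) / grid.duration
        v = (lo + (hi - lo) * frac)[:, None] * np.ones((1, channels))
    else:
        raise ValidationError(
            f"unknown fixture kind {kind!r}; valid kinds: {', '.join(FIXTURE_KINDS)}"
        )
    if params:
        raise ValidationError(f"unknown parameters for {kind!r} fixture: {sorted(params)}")
    v = np.clip(v, -1.0, 1.0)
    return ContinuousSignal(grid, v, normalized=True)
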