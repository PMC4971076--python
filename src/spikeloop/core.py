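"""Shared domain types for the closed-loop signal-conversion toolkit.

Three containers travel through every pipeline:

* :class:`TimeGrid` — a uniform sampling/tick grid in seconds.
* :class:`ContinuousSignal` — a multi-channel sampled signal on a grid
  (the "analog" side of every codec).
* :class:`SpikeTrainSet` — per-neuron ordered spike times over a window
  (the "spiking" side of every codec).

All times are seconds internally; neural conventions (ms) are converted
at module boundaries.  Simulation windows are half-open ``[t_start,
t_stop)``: a spike exactly at ``t_stop`` belongs to the next window, so
that concatenating windows is associative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeGrid",
    "ContinuousSignal",
    "SpikeTrainSet",
    "RunTimings",
    "ValidationError",
]

#: absolute tolerance, in seconds, for grid-commensurability checks
GRID_ATOL = 1e-9


class ValidationError(ValueError):
    """An input violates a domain-type invariant."""


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid: ``n_samples`` points at ``t_start + k*dt``.

    Parameters
    ----------
    t_start, t_stop : float
        Window bounds in seconds, half-open ``[t_start, t_stop)``.
    dt : float
        Sample (tick) period in seconds.  ``t_stop - t_start`` must be an
        integer multiple of ``dt`` to within 1 ns.
    """

    t_start: float
    t_stop: float
    dt: float

    def __post_init__(self) -> None:
        if not (self.t_stop > self.t_start):
            raise ValidationError(
                f"t_stop ({self.t_stop}) must exceed t_start ({self.t_start})"
            )
        if not self.dt > 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        span = self.t_stop - self.t_start
        n = round(span / self.dt)
        if n < 1 or abs(span - n * self.dt) > GRID_ATOL:
            raise ValidationError(
                f"window length {span} is not an integer multiple of dt={self.dt}"
            )

    @property
    def n_samples(self) -> int:
        return round((self.t_stop - self.t_start) / self.dt)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def times(self) -> np.ndarray:
        """Sample times ``t_start + k*dt`` for ``k = 0 .. n_samples-1``."""
        return self.t_start + self.dt * np.arange(self.n_samples)

    def index_of(self, t: float) -> int:
        """Index of the first grid sample at or after time ``t``."""
        return int(np.ceil((t - self.t_start) / self.dt - GRID_ATOL))


class ContinuousSignal:
    """Multi-channel signal sampled on a uniform :class:`TimeGrid`.

    ``values`` has shape ``(grid.n_samples, channels)``.  Codec inputs are
    expected dimensionless in [-1, 1] and flagged ``normalized``; physical
    units are allowed pre-normalization.
    """

    def __init__(self, grid: TimeGrid, values: np.ndarray, *, normalized: bool = False):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[0] == 1 and grid.n_samples != 1 and values.shape[1] == grid.n_samples:
            values = values.T
        if values.shape[0] != grid.n_samples:
            raise ValidationError(
                f"values has {values.shape[0]} samples, grid expects {grid.n_samples}"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("signal values must be finite")
        if normalized and (values.min() < -1 - 1e-12 or values.max() > 1 + 1e-12):
            raise ValidationError(
                "normalized signal has entries outside [-1, 1]: "
                f"range [{values.min():g}, {values.max():g}]"
            )
        self.grid = grid
        self.values = values
        self.normalized = bool(normalized)

    @property
    def channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def channel(self, k: int) -> np.ndarray:
        return self.values[:, k]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ContinuousSignal({self.n_samples} samples x {self.channels} ch, "
            f"dt={self.grid.dt:g}s, normalized={self.normalized})"
        )


class SpikeTrainSet:
    """Per-neuron spike times over a half-open window.

    ``trains`` is a list of 1-D float arrays (seconds), one per neuron,
    strictly increasing.  Unordered input is sorted on construction (the
    documented policy); duplicate times within a train are allowed only
    through explicit multiplicity in the input and are kept.
    Spikes outside ``[window.t_start, window.t_stop)`` are rejected.
    """

    def __init__(self, trains, window: TimeGrid):
        clean = []
        for n, t in enumerate(trains):
            t = np.asarray(t, dtype=float).ravel()
            if t.size and not np.all(np.isfinite(t)):
                raise ValidationError(f"neuron {n}: non-finite spike time")
            t = np.sort(t, kind="stable")
            if t.size:
                if t[0] < window.t_start - GRID_ATOL or t[-1] >= window.t_stop:
                    raise ValidationError(
                        f"neuron {n}: spike outside window "
                        f"[{window.t_start}, {window.t_stop})"
                    )
            clean.append(t)
        self.trains = clean
        self.window = window

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return sum(t.size for t in self.trains)

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.trains], dtype=int)

    def rates(self) -> np.ndarray:
        """Mean firing rate per neuron over the window, in Hz."""
        return self.counts() / self.window.duration

    def isis(self, neuron: int) -> np.ndarray:
        return np.diff(self.trains[neuron])

    def shifted(self, delta: float, window: TimeGrid | None = None) -> "SpikeTrainSet":
        """All spike times shifted by ``delta`` seconds."""
        w = window or TimeGrid(
            self.window.t_start + delta, self.window.t_stop + delta, self.window.dt
        )
        return SpikeTrainSet([t + delta for t in self.trains], w)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikeTrainSet):
            return NotImplemented
        return self.n_neurons == other.n_neurons and all(
            a.size == b.size and np.allclose(a, b, rtol=0, atol=1e-12)
            for a, b in zip(self.trains, other.trains)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SpikeTrainSet({self.n_neurons} neurons, {self.n_spikes} spikes, "
            f"window [{self.window.t_start:g}, {self.window.t_stop:g})s)"
        )


@dataclass
class RunTimings:
    """Wall-clock decomposition of a pipeline run.

    ``rtf`` is the real-time factor: simulated time divided by the
    wall-clock run time; values >= 1 mean the run kept up with real time.
    ``t_total = t_build + t_run + epsilon`` with ``epsilon`` the residual
    (teardown, garbage collection) not covered by build or run.
    """

    t_sim: float
    t_build: float
    t_run: float
    epsilon: float = 0.0
    rtf: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("t_sim", "t_build", "t_run", "epsilon"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        self.rtf = self.t_sim / self.t_run if self.t_run > 0 else float("inf")

    @property
    def t_total(self) -> float:
        return self.t_build + self.t_run + self.epsilon
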