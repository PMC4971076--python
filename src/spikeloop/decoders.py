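"""Spiking-to-continuous decoding: exponential filtering + linear readout.

Each spike train is low-pass filtered with the causal exponential kernel
``k(t) = exp(-t / tau_dec)`` (t >= 0), giving a per-neuron activity trace

    a_n(t) = sum_i k(t - t_{i,n}),

and the traces are linearly combined into readout channels

    z_k(t) = sum_n a_n(t) * phi_{nk}.

The kernel is unnormalized — each spike contributes a unit jump — so any
gain normalization lives in the readout weights.  The filter is computed
recursively (exact per-sample decay plus the kernel-weighted contribution
of the spikes falling in each sample interval), which matches the direct
kernel sum to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .core import ContinuousSignal, SpikeTrainSet, TimeGrid, ValidationError

__all__ = ["ReadoutParams", "exp_filter", "linear_readout", "decode", "fit_readout"]


@dataclass
class ReadoutParams:
    """Exponential-filter time constant plus readout weight matrix.

    ``weights`` has shape (n_neurons, k_outputs); ``tau_dec`` in seconds.
    ``bias`` (per output channel) makes the readout affine; it is zero
    for the pure linear combination and is only nonzero when fitted
    (activities are non-negative, so signals with negative excursions
    need an offset outside the NEF encoder/decoder pairing).
    """

    tau_dec: float
    weights: np.ndarray
    filter_dt: float = 1e-3
    bias: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        if self.tau_dec <= 0:
            raise ValidationError("tau_dec must be positive")
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("readout weights must be finite")
        self.bias = np.broadcast_to(
            np.asarray(self.bias, dtype=float), (self.weights.shape[1],)
        ).copy()


def exp_filter(s: SpikeTrainSet, tau_dec: float, grid: TimeGrid | None = None,
               *, warn_dt: bool = True) -> ContinuousSignal:
    """Filter every train with ``exp(-t/tau_dec)``; one channel per neuron.

    A spike exactly at a grid point contributes from that sample onward
    (the kernel is 1 at t = 0); a spike between grid points enters the
    next sample already decayed by the elapsed fraction.  Causal: traces
    are zero before the first spike.
    """
    if tau_dec <= 0:
        raise ValidationError("tau_dec must be positive")
    grid = grid or s.window
    if warn_dt and grid.dt > tau_dec / 2:
        import warnings

        warnings.warn(
            f"filter grid dt={grid.dt:g}s coarser than tau_dec/2={tau_dec / 2:g}s",
            stacklevel=2,
        )
    decay = np.exp(-grid.dt / tau_dec)
    t0, dt, n = grid.t_start, grid.dt, grid.n_samples
    jumps = np.zeros((n, s.n_neurons))
    for ch, train in enumerate(s.trains):
        if train.size == 0:
            continue
        # first sample index at which each spike is visible
        idx = np.ceil((train - t0) / dt - 1e-9).astype(int)
        vis = (idx >= 0) & (idx < n)
        idx, tt = idx[vis], train[vis]
        # kernel already decayed from the spike time to that sample
        w = np.exp(-((t0 + idx * dt) - tt) / tau_dec)
        np.add.at(jumps[:, ch], idx, w)
    # a[k] = a[k-1] * decay + jumps[k] — a first-order IIR filter
    out = scipy.signal.lfilter([1.0], [1.0, -decay], jumps, axis=0)
    return ContinuousSignal(grid, out)


def linear_readout(activities: ContinuousSignal, weights: np.ndarray) -> ContinuousSignal:
    """Per-sample linear combination ``z = a @ phi`` of activity traces."""
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    if activities.channels != weights.shape[0]:
        raise ValidationError(
            f"activities have {activities.channels} channels, "
            f"weights expect {weights.shape[0]} (weights shape {weights.shape})"
        )
    return ContinuousSignal(activities.grid, activities.values @ weights)


def decode(s: SpikeTrainSet, p: ReadoutParams, grid: TimeGrid | None = None) -> ContinuousSignal:
    """Exponential filter followed by the (possibly affine) linear readout."""
    acts = exp_filter(s, p.tau_dec, grid)
    out = linear_readout(acts, p.weights)
    if np.any(p.bias != 0.0):
        out = ContinuousSignal(out.grid, out.values + p.bias)
    return out


def fit_readout(s: SpikeTrainSet, target: ContinuousSignal, tau_dec: float,
                regularization: float = 0.1, *, discard: float | None = None,
                intercept: bool = True) -> ReadoutParams:
    """Fit readout weights by regularized least squares on filtered activity.

    Filters the spikes on the target's grid, optionally discards an
    initial transient of ``discard`` seconds (default one ``tau_dec``),
    and solves the same ridge problem as the NEF decoder training:
    ``phi = argmin ||Z - A phi||^2 + N sigma^2 ||phi||^2`` with
    ``sigma = regularization * max(A)``.  With ``intercept`` (default) a
    constant column is fitted as well and returned as the readout bias:
    filtered activities are non-negative, so targets with negative
    excursions are unreachable by a purely linear combination.
    """
    from .encoders import lstsq_decoders

    acts = exp_filter(s, tau_dec, target.grid)
    A, Z = acts.values, target.values
    skip = target.grid.index_of(
        target.grid.t_start + (tau_dec if discard is None else discard)
    )
    A, Z = A[skip:], Z[skip:]
    if intercept:
        scale = max(A.max(), 1.0)
        Aa = np.column_stack([A, np.full(A.shape[0], scale)])
        phi = lstsq_decoders(Aa, Z, regularization)
        return ReadoutParams(tau_dec=tau_dec, weights=phi[:-1],
                             filter_dt=target.grid.dt, bias=phi[-1] * scale)
    phi = lstsq_decoders(A, Z, regularization)
    return ReadoutParams(tau_dec=tau_dec, weights=phi, filter_dt=target.grid.dt)
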