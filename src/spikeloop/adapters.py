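"""Signal adapters: map m sensory channels onto n encoder drive channels.

The encoders expect one drive value per neuron per sample, in [-1, 1].
Adapters bridge the dimensionality gap and carry the (optional)
normalization from physical sensor units into that range:

* ``broadcast`` — every output channel receives the mean over all input
  channels (the mean, not the sum, so the [-1, 1] contract survives).
* ``hemisphere`` — the input is split into two halves (left / right
  for a laser scan); each half is averaged onto one of two outputs.
* ``matrix`` — arbitrary linear map, ``n x m`` weights.
* ``identity`` — pass-through, requires m == n.

Normalization (applied before the mapping):

* ``affine(lo, hi)`` — maps [lo, hi] linearly onto [-1, 1], clamped.
* ``invert_range(d_max)`` — proximity coding for range sensors:
  ``I = 1 - 2*d/d_max`` so a touching obstacle reads +1 and free space
  (d = d_max) reads -1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ContinuousSignal, ValidationError

__all__ = ["AdapterSpec", "apply_adapter", "normalize_laser"]

_KINDS = ("broadcast", "hemisphere", "matrix", "identity")


@dataclass
class AdapterSpec:
    """Declarative adapter: kind, dimensions, optional matrix, normalization.

    ``normalize`` is ``None``, ``("affine", lo, hi)`` or
    ``("invert_range", d_max)``.
    """

    kind: str
    m: int
    n: int
    matrix: np.ndarray | None = None
    normalize: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(
                f"unknown adapter kind {self.kind!r}; valid: {', '.join(_KINDS)}"
            )
        if self.m < 1 or self.n < 1:
            raise ValidationError("adapter dimensions must be >= 1")
        if self.kind == "hemisphere" and self.n != 2:
            raise ValidationError("hemisphere adapter requires n = 2")
        if self.kind == "identity" and self.m != self.n:
            raise ValidationError(f"identity adapter requires m == n, got {self.m} != {self.n}")
        if self.kind == "matrix":
            if self.matrix is None:
                raise ValidationError("matrix adapter requires a weight matrix")
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.matrix.shape != (self.n, self.m):
                raise ValidationError(
                    f"matrix shape {self.matrix.shape} != (n={self.n}, m={self.m})"
                )
            if not np.all(np.isfinite(self.matrix)):
                raise ValidationError("adapter matrix must be finite")

    def mapping_matrix(self) -> np.ndarray:
        """The n x m linear map this adapter applies after normalization."""
        if self.kind == "identity":
            return np.eye(self.n)
        if self.kind == "broadcast":
            return np.full((self.n, self.m), 1.0 / self.m)
        if self.kind == "hemisphere":
            W = np.zeros((2, self.m))
            half = math.ceil(self.m / 2)
            W[0, :half] = 1.0 / half
            if self.m > half:
                W[1, half:] = 1.0 / (self.m - half)
            return W
        return self.matrix


def _normalize(values: np.ndarray, normalize: tuple | None) -> np.ndarray:
    if normalize is None:
        return values
    if normalize[0] == "affine":
        _, lo, hi = normalize
        if not hi > lo:
            raise ValidationError(f"affine normalization needs hi > lo, got [{lo}, {hi}]")
        return np.clip(-1.0 + 2.0 * (values - lo) / (hi - lo), -1.0, 1.0)
    if normalize[0] == "invert_range":
        _, d_max = normalize
        if np.any(values < 0):
            raise ValidationError("range values must be non-negative")
        return np.clip(1.0 - 2.0 * values / d_max, -1.0, 1.0)
    raise ValidationError(f"unknown normalization {normalize[0]!r}")


def apply_adapter(sig: ContinuousSignal, spec: AdapterSpec) -> ContinuousSignal:
    """Normalize then linearly map an m-channel signal onto n channels."""
    if sig.channels != spec.m:
        raise ValidationError(
            f"adapter expects {spec.m} input channels, signal has {sig.channels}"
        )
    v = _normalize(sig.values, spec.normalize)
    out = v @ spec.mapping_matrix().T
    normalized = sig.normalized or spec.normalize is not None
    if spec.kind == "matrix":
        normalized = normalized and bool(
            out.size == 0 or (out.min() >= -1 - 1e-12 and out.max() <= 1 + 1e-12)
        )
    return ContinuousSignal(sig.grid, out, normalized=normalized)


def normalize_laser(ranges: np.ndarray, d_max: float) -> np.ndarray:
    """Proximity-code a range scan: 0 m -> +1 (touching), d_max -> -1 (free).

    Accepts one scan (1-D) or a stack of scans (2-D, scans x beams);
    ranges beyond ``d_max`` are clamped to -1.
    """
    ranges = np.asarray(ranges, dtype=float)
    if np.any(ranges < 0):
        raise ValidationError("laser ranges must be non-negative")
    if d_max <= 0:
        raise ValidationError("d_max must be positive")
    return np.clip(1.0 - 2.0 * ranges / d_max, -1.0, 1.0)
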