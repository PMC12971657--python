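"""Orthonormal single-level Haar wavelet transforms.

The 1D pair uses the 1/sqrt(2) (orthonormal) normalization, so the
transform is an isometry: energy is conserved and the inverse is the
adjoint.  The 2D transform applies the 1D decomposition along rows and
then columns per channel, producing four half-resolution subbands

* ``A`` - approximation (low/low),
* ``H`` - horizontal-frequency detail (low over rows, high over columns;
  responds to variation along the horizontal axis, i.e. vertical edges),
* ``V`` - vertical-frequency detail (high over rows, low over columns;
  responds to horizontal edges and stripes),
* ``D`` - diagonal detail (high/high).

For a 2x2 block ``[[p, q], [r, s]]`` the coefficients are
``A=(p+q+r+s)/2``, ``H=(p-q+r-s)/2``, ``V=(p+q-r-s)/2``, ``D=(p-q-r+s)/2``.

Odd spatial extents are edge-replicated by one row/column at the bottom /
right before the transform; the padding is recorded in the subband set and
removed again by the inverse, so reconstruction returns the original shape.

All functions accept either ``numpy.ndarray`` or autodiff ``Tensor``
inputs (the network path differentiates through them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

from . import tensor as T

Array = Union[np.ndarray, T.Tensor]

_SQRT2 = float(np.sqrt(2.0))
_INV_SQRT2 = float(1.0 / np.sqrt(2.0))


def _cat(parts, axis):
    if any(isinstance(p, T.Tensor) for p in parts):
        return T.concat([T.astensor(p) for p in parts], axis=axis)
    return np.concatenate(parts, axis=axis)


def _expand(x: Array, axis: int) -> Array:
    if isinstance(x, T.Tensor):
        shape = list(x.shape)
        shape.insert(axis % (x.ndim + 1), 1)
        return x.reshape(shape)
    return np.expand_dims(x, axis)


def _shape(x: Array) -> tuple:
    return x.shape


@dataclass
class SubbandSet:
    """The four subbands of one 2D Haar level plus the padding record."""

    A: Array
    H: Array
    V: Array
    D: Array
    pad_spec: Tuple[int, int] = (0, 0)

    def bands(self):
        return (self.A, self.H, self.V, self.D)

    def map(self, fns) -> "SubbandSet":
        """Apply ``fns = (fA, fH, fV, fD)`` branch-wise, keeping pad_spec."""
        fA, fH, fV, fD = fns
        return SubbandSet(fA(self.A), fH(self.H), fV(self.V), fD(self.D),
                          self.pad_spec)


# ---------------------------------------------------------------------------
# 1D
# ---------------------------------------------------------------------------

def haar_dwt1d(s: Array) -> Tuple[Array, Array]:
    """Single-level 1D Haar analysis of an even-length signal.

    Returns ``(approx, detail)`` with ``approx[n] = (s[2n]+s[2n+1])/sqrt(2)``
    and ``detail[n] = (s[2n]-s[2n+1])/sqrt(2)``.
    """
    n = _shape(s)[-1]
    if n == 0:
        raise ValueError("empty signal")
    if n % 2:
        raise ValueError(
            f"haar_dwt1d requires even length, got {n}; pad the signal "
            "(e.g. edge-replicate one sample) before transforming")
    even = s[..., 0::2]
    odd = s[..., 1::2]
    return (even + odd) * _INV_SQRT2, (even - odd) * _INV_SQRT2


def haar_idwt1d(approx: Array, detail: Array) -> Array:
    """Exact inverse of :func:`haar_dwt1d`."""
    if _shape(approx) != _shape(detail):
        raise ValueError(f"approx/detail length mismatch: "
                         f"{_shape(approx)} vs {_shape(detail)}")
    even = (approx + detail) * _INV_SQRT2
    odd = (approx - detail) * _INV_SQRT2
    inter = _cat([_expand(even, -1), _expand(odd, -1)], axis=-1)
    if isinstance(inter, T.Tensor):
        return inter.reshape(list(_shape(approx))[:-1] + [2 * _shape(approx)[-1]])
    return inter.reshape(inter.shape[:-2] + (2 * approx.shape[-1],))


def haar_decompose(s: np.ndarray) -> list:
    """Full recursive 1D decomposition of a length-2^J signal.

    Returns ``[a0, d0, d1, ..., d_{J-1}]`` from coarsest approximation to
    finest detail.
    """
    s = np.asarray(s, dtype=np.float64)
    n = s.shape[-1]
    if n & (n - 1):
        raise ValueError("recursive decomposition requires power-of-two length")
    details = []
    a = s
    while a.shape[-1] > 1:
        a, d = haar_dwt1d(a)
        details.append(d)
    return [a] + details[::-1]


def haar_reconstruct(coeffs: list) -> np.ndarray:
    """Inverse of :func:`haar_decompose`."""
    a = coeffs[0]
    for d in coeffs[1:]:
        a = haar_idwt1d(a, d)
    return a


# ---------------------------------------------------------------------------
# 2D
# ---------------------------------------------------------------------------

def _spatial_view(x: Array):
    """Normalize to (..., H, W, C) layout; remembers if a 2D array came in."""
    if x.ndim < 2:
        raise ValueError("need at least a 2D map")
    if x.ndim == 2:
        if isinstance(x, T.Tensor):
            return x.reshape(list(x.shape) + [1]), True
        return x[:, :, None], True
    return x, False


def haar_dwt2d(x: Array) -> SubbandSet:
    """Single-level 2D Haar analysis, channel-wise.

    ``x`` is ``(..., H, W, C)`` (or a bare ``(H, W)`` map).  Odd ``H``/``W``
    are edge-replicated by one row/column (recorded in ``pad_spec``); the
    subbands have shape ``(..., ceil(H/2), ceil(W/2), C)``.
    """
    x, squeeze = _spatial_view(x)
    h, w = _shape(x)[-3], _shape(x)[-2]
    if h == 0 or w == 0:
        raise ValueError("empty feature map")
    pad_r = h % 2
    pad_c = w % 2
    if pad_r:
        x = _cat([x, x[..., -1:, :, :]], axis=-3)
    if pad_c:
        x = _cat([x, x[..., :, -1:, :]], axis=-2)
    a = x[..., 0::2, 0::2, :]
    b = x[..., 0::2, 1::2, :]
    c = x[..., 1::2, 0::2, :]
    d = x[..., 1::2, 1::2, :]
    A = (a + b + c + d) * 0.5
    H = (a - b + c - d) * 0.5
    V = (a + b - c - d) * 0.5
    D = (a - b - c + d) * 0.5
    if squeeze:
        A, H, V, D = (band[..., :, :, 0] for band in (A, H, V, D))
    return SubbandSet(A, H, V, D, (pad_r, pad_c))


def haar_idwt2d(sb: SubbandSet) -> Array:
    """Exact inverse of :func:`haar_dwt2d`, removing any recorded padding."""
    shapes = {tuple(_shape(band)) for band in sb.bands()}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent subband shapes: {sorted(shapes)}")
    A, H, V, D = sb.bands()
    squeeze = A.ndim == 2
    if squeeze:
        A, H, V, D = (_expand(band, -1) for band in (A, H, V, D))
    a = (A + H + V + D) * 0.5
    b = (A - H + V - D) * 0.5
    c = (A + H - V - D) * 0.5
    d = (A - H - V + D) * 0.5
    hh, ww = _shape(a)[-3], _shape(a)[-2]

    def _reshape(t, shape):
        return t.reshape(list(shape)) if isinstance(t, T.Tensor) else t.reshape(shape)

    lead = tuple(_shape(a)[:-3])
    # interleave columns: (.., h, w, 2, C) -> (.., h, 2w, C)
    top = _reshape(_cat([_expand(a, -2), _expand(b, -2)], axis=-2),
                   lead + (hh, 2 * ww, _shape(a)[-1]))
    bot = _reshape(_cat([_expand(c, -2), _expand(d, -2)], axis=-2),
                   lead + (hh, 2 * ww, _shape(a)[-1]))
    # interleave rows: (.., h, 2, 2w, C) -> (.., 2h, 2w, C)
    out = _reshape(_cat([_expand(top, -3), _expand(bot, -3)], axis=-3),
                   lead + (2 * hh, 2 * ww, _shape(a)[-1]))
    pad_r, pad_c = sb.pad_spec
    if pad_r:
        out = out[..., :-1, :, :]
    if pad_c:
        out = out[..., :, :-1, :]
    if squeeze:
        out = out[..., :, :, 0]
    return out


def subband_energies(x: np.ndarray) -> dict:
    """Squared L2 norm of each single-level subband of ``x`` (numpy path)."""
    sb = haar_dwt2d(np.asarray(x, dtype=np.float64))
    return {name: float((np.asarray(band) ** 2).sum())
            for name, band in zip("AHVD", sb.bands())}
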