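"""Arithmetic primitives of the segmentation network.

All convolutions are cross-correlations (no kernel flip), matching the
index form ``L(i,j) = sum_a sum_b P(a+i, b+j) * Q(a,b)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "output_size",
    "discrete_conv2d",
    "im2col",
    "DilationSchedule",
    "hdc_max_gap",
    "check_no_gridding",
    "sigmoid",
    "sigmoid_deriv",
    "relu",
    "relu_deriv",
    "mse_loss",
]


def output_size(i: int, q: int, o: int = 0, t: int = 1, dilation: int = 1) -> int:
    """Spatial size of a convolution output: ``floor((i - q_eff + 2o)/t) + 1``.

    ``q_eff = q + (q-1)(dilation-1)`` is the effective extent of a dilated
    kernel; with ``dilation=1`` this is the plain size formula. Non-integer
    division is floored.
    """
    if t < 1:
        raise ValueError(f"stride must be >= 1, got {t}")
    if o < 0:
        raise ValueError(f"padding must be >= 0, got {o}")
    if dilation < 1:
        raise ValueError(f"dilation must be >= 1, got {dilation}")
    q_eff = q + (q - 1) * (dilation - 1)
    if i + 2 * o < q_eff:
        raise ValueError(
            f"effective kernel {q_eff} larger than padded input {i + 2 * o}"
        )
    return (i - q_eff + 2 * o) // t + 1


def im2col(
    x: np.ndarray, q: int, stride: int, padding: int, dilation: int
) -> tuple[np.ndarray, int, int]:
    """Unfold ``(N, C, H, W)`` into ``(N*Ho*Wo, C*q*q)`` patch rows."""
    n, c, h, w = x.shape
    ho = output_size(h, q, padding, stride, dilation)
    wo = output_size(w, q, padding, stride, dilation)
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    q_eff = q + (q - 1) * (dilation - 1)
    win = sliding_window_view(x, (q_eff, q_eff), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]
    win = win[:, :, :ho, :wo]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * q * q)
    return cols, ho, wo


def discrete_conv2d(
    feature_map: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> np.ndarray:
    """Discrete 2-D cross-correlation of a feature map with a kernel bank.

    Parameters
    ----------
    feature_map:
        ``(C, H, W)`` input maps (a bare ``(H, W)`` array is promoted to
        one channel).
    weights:
        ``(O, C, q, q)`` kernel bank (a bare ``(q, q)`` kernel is promoted
        to one-in/one-out).
    bias:
        Optional per-output-map offset of length ``O``.

    Returns
    -------
    ``(O, Ho, Wo)`` output maps whose spatial size obeys :func:`output_size`.
    """
    x = np.asarray(feature_map, dtype=np.float64)
    squeeze = False
    if x.ndim == 2:
        x = x[None]
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim == 2:
        w = w[None, None]
        squeeze = True
    if x.ndim != 3 or w.ndim != 4:
        raise ValueError("feature_map must be (C,H,W) and weights (O,C,q,q)")
    if w.shape[1] != x.shape[0]:
        raise ValueError(
            f"kernel expects {w.shape[1]} input maps, feature map has {x.shape[0]}"
        )
    if w.shape[2] != w.shape[3]:
        raise ValueError("only square kernels are supported")
    q = w.shape[2]
    cols, ho, wo = im2col(x[None], q, stride, padding, dilation)
    out = cols @ w.reshape(w.shape[0], -1).T
    if bias is not None:
        out = out + np.asarray(bias, dtype=np.float64)
    out = out.reshape(ho, wo, w.shape[0]).transpose(2, 0, 1)
    return out[0] if squeeze else out


@dataclass(frozen=True)
class DilationSchedule:
    """Per-layer dilation intervals and the induced maximum-gap bounds."""

    lambdas: tuple[int, ...]
    max_gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.lambdas) != len(self.max_gaps):
            raise ValueError("lambdas and max_gaps must align")


def hdc_max_gap(lambdas) -> DilationSchedule:
    """Backward gap recursion over a stack of dilated layers.

    ``N_n = lambda_n`` and, going backwards,
    ``N_i = max(N_{i+1} - 2*lambda_i, N_{i+1} - 2*(N_{i+1} - lambda_i), lambda_i)``.
    A schedule is gap-safe when the first entry does not exceed the kernel
    coverage; :func:`check_no_gridding` audits this by brute force.
    """
    lams = tuple(int(v) for v in lambdas)
    if not lams:
        raise ValueError("empty dilation schedule")
    if any(v < 1 for v in lams):
        raise ValueError(f"dilations must be >= 1, got {lams}")
    n = len(lams)
    gaps = [0] * n
    gaps[-1] = lams[-1]
    for i in range(n - 2, -1, -1):
        nxt = gaps[i + 1]
        gaps[i] = max(nxt - 2 * lams[i], nxt - 2 * (nxt - lams[i]), lams[i])
    return DilationSchedule(lambdas=lams, max_gaps=tuple(gaps))


def check_no_gridding(lambdas, kernel_size: int) -> tuple[bool, np.ndarray]:
    """Audit a dilation stack for gridding by explicit footprint composition.

    Composes the 1-D tap offsets ``{lambda_i * j : j = 0..q-1}`` of every
    layer into the set of input positions reachable by the stacked
    receptive field. Returns ``(verdict, coverage)`` where ``coverage`` is
    a boolean array over the receptive-field span and the verdict is true
    iff every position is covered (no gaps).
    """
    lams = tuple(int(v) for v in lambdas)
    if not lams:
        raise ValueError("empty dilation schedule")
    if any(v < 1 for v in lams):
        raise ValueError(f"dilations must be >= 1, got {lams}")
    if kernel_size < 1:
        raise ValueError("kernel_size must be >= 1")
    span = sum(lam * (kernel_size - 1) for lam in lams)
    reachable = np.zeros(span + 1, dtype=bool)
    reachable[0] = True
    for lam in lams:
        nxt = np.zeros_like(reachable)
        for j in range(kernel_size):
            off = lam * j
            nxt[off:] |= reachable[: reachable.size - off]
        reachable = nxt
    return bool(reachable.all()), reachable


def sigmoid(c):
    """Logistic function ``1/(1+exp(-c))``, overflow-safe at both tails."""
    c = np.asarray(c, dtype=np.float64)
    out = np.empty_like(c)
    pos = c >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-c[pos]))
    ec = np.exp(c[~pos])
    out[~pos] = ec / (1.0 + ec)
    return out if out.ndim else float(out)


def sigmoid_deriv(c):
    """Slope of the logistic: ``exp(-c)/(1+exp(-c))^2 == s(c)(1-s(c))``."""
    s = sigmoid(c)
    return s * (1.0 - s)


def relu(c):
    """``max(0, c)``."""
    c = np.asarray(c, dtype=np.float64)
    out = np.maximum(0.0, c)
    return out if out.ndim else float(out)


def relu_deriv(c):
    """1 for positive input, 0 otherwise (the kink at 0 maps to 0)."""
    c = np.asarray(c, dtype=np.float64)
    out = (c > 0).astype(np.float64)
    return out if out.ndim else float(out)


def mse_loss(targets: np.ndarray, outputs: np.ndarray, m: int | None = None) -> float:
    """Half mean squared error ``R = (1/2m) * sum((K - g(P))^2)``.

    ``m`` defaults to the number of outputs.
    """
    k = np.asarray(targets, dtype=np.float64)
    g = np.asarray(outputs, dtype=np.float64)
    if k.shape != g.shape:
        raise ValueError(f"shape mismatch: targets {k.shape} vs outputs {g.shape}")
    if m is None:
        m = k.size
    if m <= 0:
        raise ValueError("m must be positive")
    return float(np.sum((k - g) ** 2) / (2.0 * m))
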