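"""Savitzky-Golay filtering primitives.

A Savitzky-Golay (SG) filter smooths a uniformly sampled signal by fitting,
inside a symmetric moving window of ``2M + 1`` samples, a least-squares
polynomial of order ``N`` and replacing the centre sample with the fitted
value.  Because the fit is linear in the data, the whole procedure collapses
to a discrete convolution with a fixed weight vector: the row of the
pseudo-inverse of the window design matrix that yields the constant
coefficient of the fitted polynomial.

This module provides the design matrix, the central convolution weights, a
brute-force per-window polynomial fit (the reference path the weights must
reproduce), shift-invariant filtering, and polynomial extrapolation for the
``M`` samples at each end of the record that lack a full window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly


@dataclass(frozen=True)
class SignalSeries:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples
        Amplitude values, one per tick (e.g. mV).  Stored as a float64
        array; must be finite and non-empty.
    sampling_rate
        Samples per second (Hz); must be positive.  The implied time axis
        is the sample index, so ``t[i+1] - t[i] == 1`` in sample units.
    """

    samples: np.ndarray
    sampling_rate: float = 360.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1:
            raise ValueError(f"samples must be one-dimensional, got shape {arr.shape}")
        if arr.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ValueError("signal contains non-finite samples")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "sampling_rate", float(self.sampling_rate))

    def __len__(self) -> int:
        return self.samples.size


def _check_window(M: int, N: int) -> None:
    if M < 1:
        raise ValueError(f"half-window M must be >= 1, got M={M}")
    if not 0 <= N <= 2 * M:
        raise ValueError(
            f"polynomial order N must satisfy 0 <= N <= 2M for a full-rank fit, "
            f"got N={N}, M={M}"
        )


def sg_design_matrix(M: int, N: int) -> np.ndarray:
    """Vandermonde design matrix of the windowed polynomial fit.

    Row for offset ``n`` (``-M <= n <= M``) and column ``k`` holds ``n**k``,
    with ``0**0 == 1`` so the constant column is all ones.

    Returns
    -------
    numpy.ndarray of shape ``(2M + 1, N + 1)``.
    """
    _check_window(M, N)
    n = np.arange(-M, M + 1, dtype=np.float64)
    return npoly.polyvander(n, N)


def sg_weights(M: int, N: int) -> np.ndarray:
    """Central SG convolution weights for half-window ``M`` and order ``N``.

    These are the coefficients ``h`` such that ``h @ window`` equals the
    least-squares order-``N`` polynomial fit to the window, evaluated at the
    window centre — i.e. the constant-coefficient row of the pseudo-inverse
    of the design matrix.

    On the symmetric abscissae ``-M..M`` the even and odd monomials are
    Gram-orthogonal, so the fitted value at the centre depends only on the
    even-degree block; the weights are computed from a QR factorisation of
    that block, which is far better conditioned than pseudo-inverting the
    full Vandermonde matrix at high order.  (This is also why orders
    ``2k`` and ``2k + 1`` share identical central weights.)

    The weights sum to 1 (constant signals pass through unchanged) and are
    symmetric about the centre.
    """
    _check_window(M, N)
    n = np.arange(-M, M + 1, dtype=np.float64)
    even = np.arange(0, N + 1, 2)
    A = n[:, None] ** even[None, :]
    Q, R = np.linalg.qr(A)
    if np.abs(np.diag(R)).min() == 0:  # cannot happen on integer abscissae
        raise np.linalg.LinAlgError("rank-deficient SG design matrix")
    # alpha0 = e0^T R^-1 Q^T y  =>  h = Q R^-T e0
    e0 = np.zeros(even.size)
    e0[0] = 1.0
    h = Q @ np.linalg.solve(R.T, e0)
    return 0.5 * (h + h[::-1])  # the exact solution is symmetric


@dataclass(frozen=True)
class SGFilterSpec:
    """A fixed SG filter: half-window ``M``, order ``N``, derived weights."""

    M: int
    N: int
    weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        _check_window(self.M, self.N)
        object.__setattr__(self, "weights", sg_weights(self.M, self.N))

    @property
    def window_length(self) -> int:
        return 2 * self.M + 1


def sg_fit_center(window: np.ndarray, N: int) -> float:
    """Least-squares order-``N`` polynomial fit to ``window``, evaluated at
    its centre.

    This is the direct (non-convolutional) formulation of SG smoothing: fit
    the polynomial on the integer offsets ``-M..M`` and return ``f(0)``,
    the constant coefficient.  It is the reference that the precomputed
    convolution weights of :func:`sg_weights` must reproduce.
    """
    w = np.asarray(window, dtype=np.float64)
    if w.ndim != 1 or w.size % 2 == 0:
        raise ValueError(f"window must be a 1-D odd-length array, got shape {w.shape}")
    M = w.size // 2
    if N > w.size - 1:
        raise ValueError(f"order N={N} needs at least N+1 samples, window has {w.size}")
    n = np.arange(-M, M + 1, dtype=np.float64)
    coeffs = npoly.polyfit(n, w, N)
    return float(coeffs[0])


def sg_filter(x: SignalSeries, spec: SGFilterSpec) -> SignalSeries:
    """Apply a fixed SG filter to a whole signal.

    Interior samples (those with a full window) are the discrete convolution
    of the signal with the central weights; the first and last ``M`` samples
    are replaced by :func:`edge_polyfit` values using the same order ``N``.
    Output length equals input length.
    """
    n = len(x)
    if n < spec.window_length:
        raise ValueError(
            f"signal of length {n} is shorter than the window 2M+1={spec.window_length}"
        )
    y = np.empty(n, dtype=np.float64)
    # Eq. of SG filtering: y[i] = sum_m h[m] x[i - m]; h is symmetric so
    # correlation and convolution coincide, but keep the convolution form.
    y[spec.M : n - spec.M] = np.convolve(x.samples, spec.weights, mode="valid")
    y[: spec.M] = edge_polyfit(x, spec.M, spec.N, "head")
    y[n - spec.M :] = edge_polyfit(x, spec.M, spec.N, "tail")
    return SignalSeries(y, x.sampling_rate)


def edge_polyfit(x: SignalSeries, M: int, N: int, side: str) -> np.ndarray:
    """Replacement values for the ``M`` edge samples without a full window.

    Fits a single order-``N`` least-squares polynomial over the first
    (``side="head"``) or last (``side="tail"``) full window of ``2M + 1``
    samples and evaluates it at the ``M`` edge positions, in signal order.
    """
    _check_window(M, N)
    n = len(x)
    if n < 2 * M + 1:
        raise ValueError(f"signal of length {n} is shorter than the window 2M+1={2 * M + 1}")
    offsets = np.arange(-M, M + 1, dtype=np.float64)
    if side == "head":
        window = x.samples[: 2 * M + 1]
        eval_at = np.arange(-M, 0, dtype=np.float64)  # indices 0..M-1
    elif side == "tail":
        window = x.samples[n - 2 * M - 1 :]
        eval_at = np.arange(1, M + 1, dtype=np.float64)  # indices n-M..n-1
    else:
        raise ValueError(f"side must be 'head' or 'tail', got {side!r}")
    coeffs = npoly.polyfit(offsets, window, N)
    return npoly.polyval(eval_at, coeffs)
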