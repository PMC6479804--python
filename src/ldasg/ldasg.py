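"""Low-distortion adaptive Savitzky-Golay (LDASG) filtering.

Instead of one fixed polynomial order, the order is chosen per sample by
uniformly quantising the discrete-curvature profile of the input into the
range ``1..N``: flat stretches (low curvature) get low orders and hence
strong smoothing, sharp features such as QRS complexes get high orders and
hence low distortion.  The ``N`` candidate weight vectors are precomputed
once per configuration as a filter bank; filtering is then a per-sample
dot product with the selected bank row.  The window length ``2M + 1`` is
fixed for all samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_sg import SignalSeries, edge_polyfit, sg_weights
from .curvature import CurvatureParams, CurvatureProfile, curvature_profile


@dataclass(frozen=True)
class LDASGConfig:
    """Configuration of the adaptive filter.

    N
        Number of candidate polynomial orders (orders run 1..N).  Uniform
        quantisation with N between 9 and 20 is ample for ECG; default 10.
    M
        Half-window in samples; window length is ``2M + 1``.  Default 8
        (17-sample window, ~47 ms at 360 Hz); scale proportionally for
        other sampling rates.
    curvature_params
        DSS search parameters driving the order selection.
    fallback_order
        Order used for every sample when the curvature profile is constant
        (``cmax == cmin``), e.g. on a flat or perfectly straight record.
    """

    N: int = 10
    M: int = 8
    curvature_params: CurvatureParams = field(default_factory=CurvatureParams)
    fallback_order: int = 1

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")
        if not 1 <= self.N <= 2 * self.M:
            raise ValueError(f"need 1 <= N <= 2M, got N={self.N}, M={self.M}")
        if not 1 <= self.fallback_order <= self.N:
            raise ValueError(
                f"fallback_order must be in [1, N]={self.N}, got {self.fallback_order}"
            )

    @property
    def window_length(self) -> int:
        return 2 * self.M + 1


@dataclass(frozen=True)
class OrderMap:
    """Per-sample selected polynomial order, aligned to the signal index.

    Indices without a defined curvature carry the order of the nearest
    defined index, so every entry is in ``[1, N]``.
    """

    orders: np.ndarray


@dataclass(frozen=True)
class FilterBank:
    """The ``N`` precomputed central SG weight rows for a fixed half-window.

    ``rows[i - 1]`` holds the weights for order ``i``; consecutive
    even/odd orders share identical central weights (a standard SG
    identity), so the bank contains duplicate rows by construction.
    """

    M: int
    rows: np.ndarray

    @property
    def N(self) -> int:
        return self.rows.shape[0]

    def row(self, order: int) -> np.ndarray:
        if not 1 <= order <= self.N:
            raise ValueError(f"order must be in [1, {self.N}], got {order}")
        return self.rows[order - 1]


def map_orders(profile: CurvatureProfile, N: int, fallback_order: int = 1) -> OrderMap:
    """Uniformly quantise a curvature profile into integer orders 1..N.

    Applies ``Order(n) = floor(N * C(n) / (cmax - cmin) + 1/2)`` and clamps
    the result into ``[1, N]``; a degenerate profile (``cmax == cmin``)
    maps every sample to ``fallback_order``.  Undefined (edge) indices are
    filled with the nearest defined order.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    defined = profile.defined_mask
    if not defined.any():
        raise ValueError("curvature profile has no defined values")
    n = profile.values.size
    orders = np.empty(n, dtype=np.int64)
    lo, hi = profile.valid_range
    if profile.cmax == profile.cmin:
        orders[:] = fallback_order
        return OrderMap(orders=orders)
    c = profile.values[lo : hi + 1]
    q = np.floor(N * c / (profile.cmax - profile.cmin) + 0.5).astype(np.int64)
    orders[lo : hi + 1] = np.clip(q, 1, N)
    orders[:lo] = orders[lo]
    orders[hi + 1 :] = orders[hi]
    return OrderMap(orders=orders)


def build_filter_bank(N: int, M: int) -> FilterBank:
    """Precompute the central SG weights for every order 1..N at half-window M."""
    if N > 2 * M:
        raise ValueError(f"order count N={N} exceeds 2M={2 * M}")
    rows = np.vstack([sg_weights(M, i) for i in range(1, N + 1)])
    return FilterBank(M=M, rows=rows)


def ldasg_denoise_traced(
    x: SignalSeries, cfg: LDASGConfig | None = None
) -> tuple[SignalSeries, CurvatureProfile, OrderMap]:
    """As :func:`ldasg_denoise`, additionally returning the curvature profile
    and order map actually used (diagnostics for plots and tests)."""
    if cfg is None:
        cfg = LDASGConfig()
    n = len(x)
    if n < cfg.window_length:
        raise ValueError(
            f"signal of length {n} is shorter than the window 2M+1={cfg.window_length}"
        )
    profile = curvature_profile(x, cfg.curvature_params, exclusion=cfg.M)
    omap = map_orders(profile, cfg.N, cfg.fallback_order)
    bank = build_filter_bank(cfg.N, cfg.M)

    M = cfg.M
    windows = np.lib.stride_tricks.sliding_window_view(x.samples, cfg.window_length)
    interior_orders = omap.orders[M : n - M]
    # Per-sample dot product with the selected bank row (weights are
    # symmetric, so correlation equals the convolution form).
    y = np.empty(n, dtype=np.float64)
    y[M : n - M] = np.einsum("ij,ij->i", windows, bank.rows[interior_orders - 1])
    # Edge samples: one polynomial fit per side, at the order selected for
    # the nearest interior sample.
    y[:M] = edge_polyfit(x, M, int(omap.orders[M]), "head")
    y[n - M :] = edge_polyfit(x, M, int(omap.orders[n - 1 - M]), "tail")
    return SignalSeries(y, x.sampling_rate), profile, omap


def ldasg_denoise(x: SignalSeries, cfg: LDASGConfig | None = None) -> SignalSeries:
    """Denoise a signal with the curvature-adaptive SG filter.

    Pipeline: curvature profile (edges excluded) -> uniform quantisation to
    per-sample orders -> precomputed filter bank -> per-sample convolution;
    the first and last ``M`` samples are replaced by the evaluation of a
    single least-squares polynomial fitted over the first/last full window.
    Output length equals input length, with no index shift.
    """
    y, _, _ = ldasg_denoise_traced(x, cfg)
    return y
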