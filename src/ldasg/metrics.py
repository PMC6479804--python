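"""Denoising evaluation metrics: SNR improvement, MSE, PRD.

For a clean signal ``x`` and denoised signal ``y`` of length ``K``:

    SNRimp = 10 * log10( sum(x^2) / sum((y - x)^2) )      [dB]
    MSE    = mean((y - x)^2)                              [signal units^2]
    PRD    = 100 * sqrt( sum((y - x)^2) / sum(x^2) )      [percent]

SNRimp as defined here is the output signal-to-distortion ratio; at 0 dB
input SNR it numerically equals the improvement over the noisy input.
PRD and SNRimp are algebraically locked together:
``PRD = 100 * 10**(-SNRimp / 20)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_sg import SignalSeries


@dataclass(frozen=True)
class MetricsReport:
    """SNR improvement (dB), MSE, PRD (%) for one (clean, denoised) pair."""

    snr_imp: float
    mse: float
    prd: float
    k: int

    def as_dict(self) -> dict:
        return {"snr_imp": self.snr_imp, "mse": self.mse, "prd": self.prd, "k": self.k}


def _samples(sig) -> np.ndarray:
    return sig.samples if isinstance(sig, SignalSeries) else np.asarray(sig, dtype=np.float64)


def evaluate(clean, denoised) -> MetricsReport:
    """Compute SNRimp, MSE and PRD over all samples of a signal pair.

    Perfect reconstruction reports ``snr_imp = inf`` and ``prd = 0``; a
    zero-energy clean signal is rejected (both ratios are undefined).
    """
    x = _samples(clean)
    y = _samples(denoised)
    if x.size != y.size:
        raise ValueError(f"length mismatch: clean has {x.size}, denoised has {y.size}")
    if x.size < 1:
        raise ValueError("signals must be non-empty")
    ex = float(np.sum(x**2))
    if ex == 0:
        raise ValueError("clean signal has zero energy; SNRimp and PRD are undefined")
    resid = float(np.sum((y - x) ** 2))
    k = x.size
    mse = resid / k
    if resid == 0:
        return MetricsReport(snr_imp=math.inf, mse=0.0, prd=0.0, k=k)
    return MetricsReport(
        snr_imp=10.0 * math.log10(ex / resid),
        mse=mse,
        prd=100.0 * math.sqrt(resid / ex),
        k=k,
    )


def percent_decrease(reference: float, new: float) -> float:
    """Relative decrease ``100 * (reference - new) / reference`` in percent."""
    if not reference > 0:
        raise ValueError(f"reference must be positive, got {reference}")
    return 100.0 * (reference - new) / reference


def summarize_table(per_record_reports) -> pd.DataFrame:
    """Per-record metric rows plus an arithmetic-mean "Average" row.

    Takes ``[(record_id, MetricsReport), ...]`` and returns a DataFrame in
    the conventional benchmark layout (one row per record, metrics rounded
    to 2 decimals for display, mean in the last row).
    """
    reports = list(per_record_reports)
    if not reports:
        raise ValueError("need at least one report to summarize")
    rows = []
    for rec_id, rep in reports:
        rows.append({"record": rec_id, "snr_imp": rep.snr_imp, "mse": rep.mse, "prd": rep.prd})
    df = pd.DataFrame(rows)
    avg = {
        "record": "Average",
        "snr_imp": float(df["snr_imp"].mean()),
        "mse": float(df["mse"].mean()),
        "prd": float(df["prd"].mean()),
    }
    df = pd.concat([df, pd.DataFrame([avg])], ignore_index=True)
    for col in ("snr_imp", "mse", "prd"):
        df[col] = df[col].round(2)
    return df
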