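"""Noise synthesis, exact-SNR contamination, and a synthetic ECG generator.

The contamination protocol mirrors the standard ECG-denoising benchmark:
white Gaussian noise, pink (1/f) noise, and a recorded muscle-artifact (MA)
channel are mixed in configurable power proportions and scaled so the
realised signal-to-noise ratio hits the requested target exactly.  Colored
noise is produced by spectrally shaping a white Gaussian draw to a power
spectral density proportional to ``1 / f**beta`` (``beta = 0`` white,
``beta = 1`` pink).

Real MA noise must be supplied by the caller (e.g. a noise-stress-test
record); :func:`muscle_artifact_surrogate` provides a synthetic band-limited
stand-in so the full mixture path is exercisable without any recording.

The synthetic ECG is a sum of Gaussian bumps (P, Q, R, S, T) per beat —
a morphological stand-in for real recordings that keeps ground-truth R-peak
positions known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core_sg import SignalSeries

_NOISE_KINDS = ("wgn", "pink", "ma", "mixture")


@dataclass(frozen=True)
class NoiseSpec:
    """What noise to add and how strong.

    kind
        "wgn", "pink", "ma", or "mixture" (weighted combination of the
        three, power proportions given by ``mixture_weights``).
    beta
        PSD exponent for the colored component; 0 is white, 1 is pink.
        Used when kind is "pink" (and for the pink part of a mixture).
    target_snr_db
        Desired clean-signal-to-noise power ratio in dB; the realised SNR
        matches this exactly for each realisation.
    mixture_weights
        Power fractions (wgn, pink, ma); must be non-negative and sum to 1.
        Only consulted for kind "mixture".
    ma_samples
        Recorded or surrogate muscle-artifact amplitudes; required whenever
        the MA component has nonzero weight.
    seed
        RNG seed; identical seeds give bit-identical noise.
    """

    kind: str = "wgn"
    beta: float = 1.0
    target_snr_db: float = 0.0
    mixture_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    ma_samples: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"kind must be one of {_NOISE_KINDS}, got {self.kind!r}")
        w = np.asarray(self.mixture_weights, dtype=np.float64)
        if w.size != 3 or (w < 0).any():
            raise ValueError("mixture_weights must be three non-negative fractions")
        if abs(float(w.sum()) - 1.0) > 1e-12:
            raise ValueError(f"mixture_weights must sum to 1, got {w.sum()!r}")


def generate_colored_noise(n: int, beta: float, seed=None) -> np.ndarray:
    """Unit-power Gaussian noise with power spectral density ~ 1/f**beta.

    A white Gaussian draw is shaped in the frequency domain (amplitude
    spectrum multiplied by ``f**(-beta/2)``); the DC bin is zeroed to avoid
    the 1/0 singularity, and the output is rescaled to exactly unit mean
    power.  ``seed`` may be anything accepted by ``numpy.random.default_rng``.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    spectrum[1:] *= f[1:] ** (-beta / 2.0)
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n)
    return x / math.sqrt(float(np.mean(x**2)))


def muscle_artifact_surrogate(
    n: int, sampling_rate: float = 360.0, seed=None, band: tuple[float, float] = (20.0, 120.0)
) -> np.ndarray:
    """Synthetic stand-in for recorded muscle-artifact (EMG) noise.

    Band-limited Gaussian noise (default 20-120 Hz, the dominant surface-EMG
    band) at exactly unit mean power.  It reproduces the broadband spectral
    footprint of muscle artifact but none of its burst nonstationarity, so
    it is a test surrogate, not a substitute for a real recording.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    nyq = sampling_rate / 2.0
    lo, hi = band
    hi = min(hi, 0.99 * nyq)
    rng = np.random.default_rng(seed)
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / math.sqrt(float(np.mean(x**2)))


def _unit_power(v: np.ndarray) -> np.ndarray:
    p = float(np.mean(v**2))
    if p == 0:
        raise ValueError("noise component has zero power")
    return v / math.sqrt(p)


def mixture_components(n: int, spec: NoiseSpec) -> dict[str, np.ndarray]:
    """The weighted noise components that :func:`contaminate` sums.

    Each requested component is generated at unit power (or taken from
    ``spec.ma_samples`` for MA, mean-removed and renormalised) and scaled by
    ``sqrt(weight)``, so component powers follow ``mixture_weights`` exactly
    before the final SNR scaling.
    """
    if spec.kind == "mixture":
        weights = {k: w for k, w in zip(("wgn", "pink", "ma"), spec.mixture_weights)}
    else:
        weights = {spec.kind: 1.0}

    rng = np.random.default_rng(spec.seed)
    out: dict[str, np.ndarray] = {}
    for kind, w in weights.items():
        if w == 0:
            continue
        if kind == "wgn":
            comp = generate_colored_noise(n, 0.0, rng)
        elif kind == "pink":
            comp = generate_colored_noise(n, spec.beta, rng)
        elif kind == "ma":
            if spec.ma_samples is None:
                raise ValueError(
                    "muscle-artifact noise requested but spec.ma_samples is None; "
                    "supply a recorded channel or muscle_artifact_surrogate()"
                )
            ma = np.asarray(spec.ma_samples, dtype=np.float64)
            if ma.size < n:
                ma = np.tile(ma, int(np.ceil(n / ma.size)))
            comp = _unit_power(ma[:n] - np.mean(ma[:n]))
        out[kind] = math.sqrt(w) * comp
    return out


def contaminate(x: SignalSeries, spec: NoiseSpec) -> tuple[SignalSeries, np.ndarray]:
    """Add noise to a clean signal at an exact target SNR.

    The components of :func:`mixture_components` are summed and the sum is
    rescaled so ``10*log10(P_signal / P_noise)`` equals ``target_snr_db``
    exactly for this realisation (the scale is computed from the realised
    noise power, not its expectation).

    Returns the contaminated series and the noise realisation that was added.
    """
    n = len(x)
    px = float(np.mean(x.samples**2))
    if px == 0:
        raise ValueError("clean signal has zero power; SNR is undefined")
    noise = sum(mixture_components(n, spec).values())
    pn = float(np.mean(noise**2))
    scale = math.sqrt(px / (pn * 10.0 ** (spec.target_snr_db / 10.0)))
    noise = noise * scale
    return SignalSeries(x.samples + noise, x.sampling_rate), noise


def spectral_slope(x: np.ndarray, f_lo: float = 0.002, f_hi: float = 0.25) -> float:
    """Log-log periodogram slope over a mid-band of normalised frequency.

    For noise with PSD ~ 1/f**beta the slope estimates -beta.  The band
    excludes the (zeroed) DC end and the near-Nyquist roll-off.
    """
    f, p = sps.periodogram(np.asarray(x, dtype=np.float64), fs=1.0)
    keep = (f >= f_lo) & (f <= f_hi) & (p > 0)
    coef = np.polynomial.polynomial.polyfit(np.log10(f[keep]), np.log10(p[keep]), 1)
    return float(coef[1])


# ---------------------------------------------------------------------------
# Synthetic ECG
# ---------------------------------------------------------------------------

#: Default per-beat wave parameters: (amplitude in signal units,
#: centre offset from the R peak in seconds, Gaussian sigma in seconds).
DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (0.15, -0.20, 0.040),
    "Q": (-0.10, -0.035, 0.010),
    "R": (1.00, 0.0, 0.011),
    "S": (-0.15, 0.035, 0.012),
    "T": (0.30, 0.28, 0.060),
}


@dataclass(frozen=True)
class SyntheticECGSpec:
    """Quasi-periodic synthetic ECG: a sum of Gaussian P-QRS-T bumps per beat.

    rr_jitter is the relative standard deviation of the beat-to-beat
    interval (0 gives a strictly periodic train; real rhythms have a few
    percent of variability).
    """

    sampling_rate: float = 360.0
    duration: float = 10.0
    heart_rate: float = 72.0
    waves: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WAVES)
    )
    rr_jitter: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.heart_rate > 0:
            raise ValueError(f"heart_rate must be positive, got {self.heart_rate}")
        if self.duration * self.heart_rate / 60.0 < 1:
            raise ValueError("duration too short for a single beat")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        for name, (_, _, width) in self.waves.items():
            if not width > 0:
                raise ValueError(f"wave {name} must have positive width, got {width}")
        if self.rr_jitter < 0:
            raise ValueError(f"rr_jitter must be >= 0, got {self.rr_jitter}")


def generate_ecg(spec: SyntheticECGSpec | None = None) -> tuple[SignalSeries, np.ndarray]:
    """Generate a synthetic ECG and its ground-truth R-peak sample indices.

    Beats are anchored at ``(k + 1/2) * RR`` (optionally jittered), so a
    10 s record at 72 bpm holds 12 complete beats.  Each beat adds five
    Gaussian bumps at the configured offsets from its anchor; the anchor is
    the R-peak position.
    """
    if spec is None:
        spec = SyntheticECGSpec()
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    rr = 60.0 / spec.heart_rate
    n_beats = int(math.floor(spec.duration / rr - 0.5)) + 1
    anchors = (np.arange(n_beats) + 0.5) * rr
    if spec.rr_jitter > 0:
        rng = np.random.default_rng(spec.seed)
        anchors = anchors + rng.normal(0.0, spec.rr_jitter * rr, n_beats)
        anchors = np.clip(anchors, 0.0, spec.duration - 1.0 / fs)

    x = np.zeros(n)
    for amp, offset, width in spec.waves.values():
        if amp == 0:
            continue
        centers = anchors + offset
        x += amp * np.exp(-((t[:, None] - centers[None, :]) ** 2) / (2 * width**2)).sum(axis=1)

    r_indices = np.round(anchors * fs).astype(np.int64)
    r_indices = r_indices[(r_indices >= 0) & (r_indices < n)]
    return SignalSeries(x, fs), r_indices
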