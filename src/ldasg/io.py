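"""Signal file I/O: delimited text and WFDB records.

Delimited text is the native interchange format: either a single amplitude
column (sampling rate supplied by the caller, default 360 Hz) or two columns
``time, amplitude`` with the rate inferred from the time spacing.  Values
are written at full float precision so a write/read round trip is exact.

WFDB (.hea/.dat) records are read through the ``wfdb`` package when it is
installed; otherwise a built-in minimal reader handles single- and
multi-channel records in formats 16 and 212 (the formats used by the
classic arrhythmia databases), applying gain and baseline from the header.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .core_sg import SignalSeries

DEFAULT_FS = 360.0  # sampling rate of the classic arrhythmia records


def read_signal(path, format: str = "auto", channel: int = 0, fs: float | None = None) -> SignalSeries:
    """Read a single-channel signal from delimited text or a WFDB record.

    format "auto" dispatches on the extension (".hea" or a bare record name
    with a .hea next to it -> WFDB; anything else -> delimited text).
    For one-column text the rate is ``fs`` (default 360 Hz); for two-column
    ``time, amplitude`` text the rate is inferred from the median time step.
    """
    path = Path(path)
    if format == "auto":
        if path.suffix == ".hea" or path.with_suffix(".hea").exists():
            format = "wfdb"
        else:
            format = "csv"
    if format == "wfdb":
        return _read_wfdb(path, channel)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}; expected auto, csv or wfdb")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data = np.loadtxt(path, delimiter=None if _is_whitespace_delimited(path) else ",")
    except ValueError as exc:
        raise ValueError(f"could not parse {path} as delimited numeric text: {exc}") from exc
    data = np.atleast_1d(data)
    if data.ndim == 1:
        return SignalSeries(data, fs if fs is not None else DEFAULT_FS)
    if data.shape[1] == 1:
        return SignalSeries(data[:, 0], fs if fs is not None else DEFAULT_FS)
    t, x = data[:, 0], data[:, 1]
    dt = np.median(np.diff(t))
    if not dt > 0:
        raise ValueError(f"time column of {path} is not strictly increasing")
    return SignalSeries(x, fs if fs is not None else 1.0 / float(dt))


def _is_whitespace_delimited(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                return "," not in line
    return True


def write_signal(series: SignalSeries, path) -> None:
    """Write amplitudes as one column of full-precision text
    (``read_signal(write_signal(s)) == s`` bit-exactly)."""
    np.savetxt(path, series.samples, fmt="%.17g")


# ---------------------------------------------------------------------------
# WFDB
# ---------------------------------------------------------------------------


def _read_wfdb(path: Path, channel: int) -> SignalSeries:
    record = path.with_suffix("") if path.suffix in (".hea", ".dat") else path
    try:
        import wfdb  # optional; the fallback reader below covers fmt 16/212
    except ImportError:
        return _read_wfdb_builtin(record, channel)
    rec = wfdb.rdrecord(str(record), channels=[channel])
    return SignalSeries(rec.p_signal[:, 0], float(rec.fs))


def _read_wfdb_builtin(record: Path, channel: int) -> SignalSeries:
    """Minimal WFDB reader: formats 16 (int16 LE) and 212 (packed 12-bit).

    Parses the header for channel count, sampling rate, per-channel format,
    gain and baseline, and converts ADC units to physical units as
    ``(adc - baseline) / gain``.
    """
    hea = record.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else DEFAULT_FS
    n_samp = int(head[3]) if len(head) > 3 else 0
    if not 0 <= channel < n_sig:
        raise ValueError(f"record has {n_sig} channels, channel {channel} requested")

    sig_lines = lines[1 : 1 + n_sig]
    specs = []
    for ln in sig_lines:
        parts = ln.split()
        fname, fmt = parts[0], parts[1].split("x")[0]
        gain, baseline = 200.0, 0.0
        if len(parts) > 2:
            g = parts[2].split("/")[0]
            if "(" in g:
                g, b = g.split("(")
                baseline = float(b.rstrip(")"))
            if float(g) != 0:
                gain = float(g)
        specs.append((fname, int(fmt), gain, baseline))

    fname, fmt, gain, baseline = specs[channel]
    dat = record.parent / fname
    if any(s[0] != fname for s in specs):
        raise ValueError("multi-file WFDB records are not supported by the built-in reader")
    raw = dat.read_bytes()
    if fmt == 16:
        adc_all = np.frombuffer(raw, dtype="<i2")
        adc = adc_all[channel::n_sig]
    elif fmt == 212:
        adc = _unpack_212(raw)[channel::n_sig]
    else:
        raise ValueError(
            f"WFDB format {fmt} needs the 'wfdb' package; built-in reader handles 16 and 212"
        )
    if n_samp:
        adc = adc[:n_samp]
    return SignalSeries((adc.astype(np.float64) - baseline) / gain, fs)


def _unpack_212(raw: bytes) -> np.ndarray:
    """Unpack WFDB format 212: two 12-bit two's-complement samples per 3 bytes."""
    b = np.frombuffer(raw, dtype=np.uint8)
    b = b[: (b.size // 3) * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(b.shape[0] * 2, dtype=np.int32)
    out[0::2] = s0
    out[1::2] = s1
    out[out > 2047] -= 4096
    return out


def load_ma_noise(path, channel: int = 0) -> np.ndarray:
    """Load a recorded muscle-artifact channel (delimited text or WFDB)."""
    return read_signal(path, channel=channel).samples
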