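"""Minimal European Data Format (EDF) writer and an MNE-backed reader.

The writer emits plain 16-bit EDF (one data record per second, symmetric
physical range per channel, microvolt units) — sufficient for continuous
iEEG exchange. Reading goes through :func:`mne.io.read_raw_edf`, so written
files are always interpreted by an independent implementation.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

DIG_MIN, DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    data: np.ndarray,
    sfreq: float,
    ch_names: list[str],
    *,
    phys_unit: str = "uV",
    patient_id: str = "X",
    recording_id: str = "synthetic iEEG",
) -> None:
    """Write a (n_channels, n_samples) microvolt array as 16-bit EDF.

    The tail is zero-padded to a whole number of 1-second records. The
    physical range of each channel is set symmetrically to its absolute
    maximum (or 1 if silent), so the quantization step is
    ``2 * max|x| / (DIG_MAX - DIG_MIN)``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    if len(ch_names) != n_ch:
        raise ValueError("ch_names length must match data rows")
    if sfreq <= 0 or abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError("writer requires a positive integer sampling rate")
    spr = int(round(sfreq))  # samples per 1-s record
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1.0)
    phys_min = -phys_max
    scale = (DIG_MAX - DIG_MIN) / (phys_max - phys_min)
    digital = np.round((padded - phys_min[:, None]) * scale[:, None] + DIG_MIN)
    digital = np.clip(digital, DIG_MIN, DIG_MAX).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 * (n_ch + 1)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(_field(name, 16) for name in ch_names),
            b"".join(_field("", 80) for _ in ch_names),
            b"".join(_field(phys_unit, 8) for _ in ch_names),
            b"".join(_field(f"{v:.6g}"[:8], 8) for v in phys_min),
            b"".join(_field(f"{v:.6g}"[:8], 8) for v in phys_max),
            b"".join(_field(str(DIG_MIN), 8) for _ in ch_names),
            b"".join(_field(str(DIG_MAX), 8) for _ in ch_names),
            b"".join(_field("", 80) for _ in ch_names),
            b"".join(_field(str(spr), 8) for _ in ch_names),
            b"".join(_field("", 32) for _ in ch_names),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        # records: channel-major within each 1-s record
        view = digital.reshape(n_ch, n_rec, spr)
        for r in range(n_rec):
            fh.write(view[:, r, :].tobytes())


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file via MNE; returns (microvolt array, sfreq, ch_names)."""
    import mne

    raw = mne.io.read_raw_edf(Path(path), preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)
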