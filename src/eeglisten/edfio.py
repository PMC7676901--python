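"""Minimal EDF / BDF reader and writer.

Implements just enough of the European Data Format (16-bit) and the BioSemi
BDF variant (24-bit) to round-trip multichannel recordings with their
sampling rate and channel labels: one fixed record duration, identical
sampling rate on every signal, no annotations.  Written by hand because no
EDF library is available in the target environment.
"""

from __future__ import annotations

import datetime as _dt
import os

import numpy as np

from .recording import EEGRecording

_HDR = 256  # bytes, fixed part and per-signal blocks


def _pad(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, rec: EEGRecording, *, bdf: bool | None = None) -> None:
    """Write a recording as EDF (16-bit) or BDF (24-bit).

    The sampling rate must be a positive integer; the signal is split into
    1-second data records (the tail partial second is zero-padded).
    """
    if bdf is None:
        bdf = str(path).lower().endswith(".bdf")
    fs = rec.fs
    if fs != int(fs) or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    nch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / fs))
    data = np.zeros((nch, n_rec * fs))
    data[:, : rec.n_samples] = rec.data

    dig_max = 8388607 if bdf else 32767
    dig_min = -dig_max - 1
    phys_min = np.floor(np.minimum(data.min(axis=1), -1.0))
    phys_max = np.ceil(np.maximum(data.max(axis=1), 1.0))

    now = _dt.datetime(2000, 1, 1)
    with open(path, "wb") as fh:
        if bdf:
            fh.write(b"\xffBIOSEMI")
        else:
            fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))  # patient id
        fh.write(_pad("Startdate X X X X", 80))  # recording id
        fh.write(_pad(now.strftime("%d.%m.%y"), 8))
        fh.write(_pad(now.strftime("%H.%M.%S"), 8))
        fh.write(_pad(_HDR * (1 + nch), 8))
        fh.write(_pad("24BIT" if bdf else "EDF+C", 44))
        fh.write(_pad(n_rec, 8))
        fh.write(_pad(1, 8))  # record duration, seconds
        fh.write(_pad(nch, 4))
        for lab in rec.labels:
            fh.write(_pad(lab, 16))
        for _ in range(nch):
            fh.write(_pad("Active electrode", 80))
        for _ in range(nch):
            fh.write(_pad("uV", 8))
        for v in phys_min:
            fh.write(_pad(int(v), 8))
        for v in phys_max:
            fh.write(_pad(int(v), 8))
        for _ in range(nch):
            fh.write(_pad(dig_min, 8))
        for _ in range(nch):
            fh.write(_pad(dig_max, 8))
        for _ in range(nch):
            fh.write(_pad("HP:0.0Hz", 80))  # prefiltering
        for _ in range(nch):
            fh.write(_pad(fs, 8))
        for _ in range(nch):
            fh.write(_pad("", 32))  # reserved

        gain = (phys_max - phys_min) / (dig_max - dig_min)
        dig = np.rint((data - phys_min[:, None]) / gain[:, None] + dig_min)
        dig = np.clip(dig, dig_min, dig_max).astype(np.int32)
        for r in range(n_rec):
            block = dig[:, r * fs : (r + 1) * fs]
            if bdf:
                b = block.astype("<i4").tobytes()
                arr = np.frombuffer(b, dtype=np.uint8).reshape(-1, 4)
                fh.write(arr[:, :3].tobytes())  # little-endian 24-bit
            else:
                fh.write(block.astype("<i2").tobytes())


def read_edf(path) -> EEGRecording:
    """Read an EDF/BDF file written by :func:`write_edf` (or compatible)."""
    with open(path, "rb") as fh:
        magic = fh.read(8)
        bdf = magic[:1] == b"\xff"
        fh.read(160)  # patient + recording ids
        fh.read(16)  # date + time
        fh.read(8)  # header bytes
        fh.read(44)  # reserved / version
        n_rec = int(fh.read(8))
        rec_dur = float(fh.read(8))
        nch = int(fh.read(4))
        labels = [fh.read(16).decode("ascii").strip() for _ in range(nch)]
        fh.read(80 * nch)  # transducer
        fh.read(8 * nch)  # units
        phys_min = np.array([float(fh.read(8)) for _ in range(nch)])
        phys_max = np.array([float(fh.read(8)) for _ in range(nch)])
        dig_min = np.array([int(fh.read(8)) for _ in range(nch)])
        dig_max = np.array([int(fh.read(8)) for _ in range(nch)])
        fh.read(80 * nch)  # prefiltering
        spr = [int(fh.read(8)) for _ in range(nch)]
        fh.read(32 * nch)
        if len(set(spr)) != 1:
            raise ValueError("mixed per-signal sampling rates not supported")
        ns = spr[0]
        fs = ns / rec_dur

        width = 3 if bdf else 2
        raw = fh.read(n_rec * nch * ns * width)

    if bdf:
        u = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
        ext = np.zeros((u.shape[0], 4), dtype=np.uint8)
        ext[:, :3] = u
        ext[:, 3] = np.where(u[:, 2] & 0x80, 0xFF, 0)
        dig = ext.view("<i4").ravel().astype(np.float64)
    else:
        dig = np.frombuffer(raw, dtype="<i2").astype(np.float64)
    dig = dig.reshape(n_rec, nch, ns)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = np.concatenate(
        [(dig[r] - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
         for r in range(n_rec)],
        axis=1,
    )
    rec = EEGRecording(data=data, fs=fs, labels=labels)
    rec.meta["source"] = os.fspath(path)
    return rec
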