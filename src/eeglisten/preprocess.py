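"""Deterministic EEG preprocessing.

Re-referencing, anti-aliased resampling, Hamming-windowed-sinc band-pass
filtering, audio/EEG delay estimation by cross-correlation, and splitting a
continuous recording into listening-condition fragments.

The judgment-based cleaning steps of a typical EEG workflow (ICA-based eye
artifact removal, visual rejection of noisy segments) are *not* computed
here; recordings carry externally supplied exclusion lists instead, which
downstream stages honour when assembling the feature matrix.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .recording import ConditionManifest, EEGRecording


def read_exclusions(path) -> dict:
    """Read a CSV of externally supplied exclusions.

    Columns: ``participant``, ``channel`` (optional), ``start_s`` / ``stop_s``
    (optional).  A row with a channel excludes that channel; a row with an
    interval excludes that time span.  Returns participant -> set of channel
    labels and (start_s, stop_s) tuples, ready for
    ``EEGRecording.exclusions``.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if "participant" not in df.columns:
        raise ValueError("exclusions CSV needs a 'participant' column")
    out: dict = {}
    for _, row in df.iterrows():
        entry = out.setdefault(row["participant"], set())
        chan = row.get("channel")
        if isinstance(chan, str) and chan:
            entry.add(chan)
        elif "start_s" in df.columns and np.isfinite(row.get("start_s", np.nan)):
            entry.add((float(row["start_s"]), float(row["stop_s"])))
        else:
            raise ValueError(f"exclusion row without channel or interval: "
                             f"{dict(row)}")
    return out


def rereference(rec: EEGRecording, ref_label: str) -> EEGRecording:
    """Subtract the reference channel from every channel.

    Idempotent: re-referencing to the same electrode twice equals doing it
    once, and reference-free contrasts (channel differences) are invariant.
    """
    if ref_label not in rec.labels:
        raise ValueError(f"reference channel {ref_label!r} not in recording")
    ref = rec.channel(ref_label).copy()
    out = rec.copy(data=rec.data - ref[None, :], reference=ref_label)
    return out


def bandpass_fir(fs: float, band=(0.5, 134.0), order: int = 3380) -> np.ndarray:
    """Hamming-windowed-sinc band-pass taps (order = numtaps - 1)."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} outside (0, {fs / 2}) Hz")
    numtaps = order + 1
    if numtaps % 2 == 0:
        numtaps += 1  # type-I linear phase for a band-pass
    return signal.firwin(numtaps, [lo, hi], pass_zero=False,
                         window="hamming", fs=fs)


def _filter_zero_phase(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """One-pass FIR with group-delay compensation (edges zero-padded).

    A single linear-phase pass delayed by (numtaps-1)/2 samples preserves the
    designed magnitude response exactly (unlike forward-backward filtering,
    which squares it); compensating the integer delay makes it zero-phase.
    """
    delay = (taps.size - 1) // 2
    n = data.shape[-1]
    padded = np.concatenate(
        [data, np.zeros(data.shape[:-1] + (delay,))], axis=-1)
    out = signal.oaconvolve(padded, taps[None, :] if data.ndim == 2 else taps,
                            mode="full", axes=-1)
    return out[..., delay:delay + n]


def resample_filter(rec: EEGRecording, target_fs: float = 512.0,
                    band=(0.5, 134.0), order: int = 3380) -> EEGRecording:
    """Anti-aliased resampling followed by a zero-phase band-pass.

    Resampling uses a polyphase FIR (anti-aliasing low-pass built in); the
    band-pass is a Hamming-windowed sinc of the given order applied after
    resampling, delay-compensated so features keep their timing.
    """
    if target_fs > rec.fs:
        raise ValueError("target_fs must not exceed the original rate")
    lo, hi = band
    if hi >= target_fs / 2:
        raise ValueError("band edge at or above Nyquist after resampling")
    data = rec.data
    if target_fs != rec.fs:
        from fractions import Fraction
        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator,
                                    axis=-1)
    taps = bandpass_fir(target_fs, band, order)
    data = _filter_zero_phase(data, taps)
    out = rec.copy(data=data, fs=float(target_fs))
    out.meta.update({"band": tuple(band), "filter_order": order,
                     "resampled_from": rec.fs})
    return out


def estimate_delay(recorded: np.ndarray, presented: np.ndarray,
                   max_lag: int | None = None) -> int:
    """Lag (in samples) of the recorded sound channel vs the presented audio.

    Positive lag means the audio arrives *later* in the recording (playback
    latency).  The lag maximizing the cross-correlation is returned; exact
    ties are broken toward the smallest absolute lag.
    """
    recorded = np.asarray(recorded, dtype=np.float64)
    presented = np.asarray(presented, dtype=np.float64)
    if recorded.std() == 0 or presented.std() == 0:
        raise ValueError("constant input: cross-correlation undefined")
    r = recorded - recorded.mean()
    p = presented - presented.mean()
    xc = signal.correlate(r, p, mode="full", method="fft")
    lags = signal.correlation_lags(r.size, p.size, mode="full")
    if max_lag is not None:
        keep = np.abs(lags) <= max_lag
        xc, lags = xc[keep], lags[keep]
    best = np.flatnonzero(xc == xc.max())
    lag = int(lags[best[np.argmin(np.abs(lags[best]))]])
    return lag


def compensate_delay(rec: EEGRecording, delay_samples: int,
                     scalp_labels=None) -> EEGRecording:
    """Shift the EEG channels by the estimated audio delay.

    Positive delay: EEG is advanced so that EEG time aligns with presented
    audio time.  Channels not in ``scalp_labels`` (the sync channel) are left
    untouched.
    """
    out = rec.copy()
    idx = range(rec.n_channels) if scalp_labels is None else [
        rec.labels.index(lab) for lab in scalp_labels]
    for i in idx:
        out.data[i] = np.roll(rec.data[i], -delay_samples)
        if delay_samples > 0:
            out.data[i, -delay_samples:] = 0.0
        elif delay_samples < 0:
            out.data[i, :-delay_samples] = 0.0
    out.meta["compensated_delay"] = int(delay_samples)
    return out


def split_fragments(rec: EEGRecording, manifest: ConditionManifest,
                    participant=None) -> list:
    """Cut the recording into per-condition fragments.

    Returns a list of ``(EEGRecording, tags)`` where ``tags`` is the manifest
    row as a dict.  Fragment sample counts equal ``(stop - start) * fs``
    rounded to the nearest sample.
    """
    rows = (manifest.fragments if participant is None
            else manifest.for_participant(participant))
    out = []
    for _, row in rows.iterrows():
        i0 = int(round(row["start_s"] * rec.fs))
        i1 = int(round(row["stop_s"] * rec.fs))
        if not 0 <= i0 < i1 <= rec.n_samples:
            raise ValueError(
                f"fragment [{row['start_s']}, {row['stop_s']}] s outside "
                f"recording of {rec.duration_s:.1f} s")
        frag = rec.copy(data=rec.data[:, i0:i1])
        frag.meta.update({k: row[k] for k in
                          ("participant", "task", "background", "topic")})
        frag.meta["start_s"] = float(row["start_s"])
        out.append((frag, dict(frag.meta)))
    return out
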