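"""Welch power spectra and power-spectrum-derived features.

Band definitions follow the common EEG convention: delta 1-4 Hz, theta
4-8 Hz, alpha 8-13 Hz (with a 7-13 Hz variant and lower/upper halves),
beta 13-30 Hz, gamma 30-45 Hz, and a 1-45 Hz wide band used as the
normalizer for relative power.  Band integrals use half-open bins
[f_lo, f_hi) so that a partition of 1-45 Hz yields relative powers summing
to one exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band {self.name}: "
                             f"({self.f_lo}, {self.f_hi})")


#: canonical band set
BANDS = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "alpha7": BandDefinition("alpha7", 7.0, 13.0),
    "lower_alpha": BandDefinition("lower_alpha", 8.0, 10.0),
    "upper_alpha": BandDefinition("upper_alpha", 10.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 45.0),
    "wide": BandDefinition("wide", 1.0, 45.0),
}

#: the five bands partitioning 1-45 Hz (relative powers over these sum to 1)
PARTITION = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass
class PSDEstimate:
    """One-sided Welch PSD: ``power`` in microvolt^2/Hz on grid ``freqs``."""

    freqs: np.ndarray
    power: np.ndarray
    params: dict

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ValueError("PSD must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def band_slice(self, f_lo: float, f_hi: float) -> np.ndarray:
        """Boolean mask of the half-open bin range [f_lo, f_hi)."""
        return (self.freqs >= f_lo) & (self.freqs < f_hi)


def welch_psd(x: np.ndarray, fs: float, window_s: float = 1.0,
              overlap_s: float = 0.5, nfft: int = 2 ** 14) -> PSDEstimate:
    """Welch periodogram with Hamming taper and 50% overlap.

    Density scaling: the rectangle-rule integral of the PSD over the full
    grid equals the signal variance (Parseval) up to estimator noise.
    ``nfft`` zero-pads each segment, giving a grid spacing of fs/nfft
    (0.03125 Hz for the 512 Hz / 2^14 default).
    """
    x = np.asarray(x, dtype=np.float64)
    nper = int(round(window_s * fs))
    if x.size < nper:
        raise ValueError(
            f"fragment of {x.size} samples shorter than one "
            f"{window_s} s window")
    nover = int(round(overlap_s * fs))
    nfft = max(nfft, nper)
    freqs, power = signal.welch(
        x, fs=fs, window="hamming", nperseg=nper, noverlap=nover,
        nfft=nfft, detrend="constant", scaling="density")
    return PSDEstimate(freqs=freqs, power=power,
                       params={"window_s": window_s, "overlap_s": overlap_s,
                               "nfft": nfft, "fs": fs})


def band_power(psd: PSDEstimate, f_lo: float, f_hi: float) -> float:
    """Absolute power: rectangle-rule integral of the PSD over [f_lo, f_hi)."""
    if f_hi > psd.freqs[-1] + psd.df:
        raise ValueError("band extends beyond the PSD range")
    sel = psd.band_slice(f_lo, f_hi)
    return float(np.sum(psd.power[sel]) * psd.df)


def band_powers(psd: PSDEstimate, bands=None) -> dict:
    """AP per band, RP per band (relative to 1-45 Hz) and the theta/alpha
    power ratio RPTA.

    Returns ``{"AP": {...}, "RP": {...}, "RPTA": float}``.
    """
    bands = bands or BANDS
    ap = {name: band_power(psd, b.f_lo, b.f_hi) for name, b in bands.items()}
    wide = ap.get("wide", band_power(psd, 1.0, 45.0))
    if wide <= 0:
        raise ValueError("zero wide-band power")
    rp = {name: ap[name] / wide for name in ap if name != "wide"}
    if ap.get("alpha", 0.0) <= 0:
        raise ValueError("zero alpha power: RPTA undefined")
    rpta = ap["theta"] / ap["alpha"]
    return {"AP": ap, "RP": rp, "RPTA": rpta}


def spectral_shape(psd: PSDEstimate, band: BandDefinition) -> tuple:
    """(CF, B, SEF95) of the PSD restricted to one band.

    CF is the power-weighted mean frequency (spectral centre of gravity);
    B the root second central spectral moment (spectral spread); SEF95 the
    smallest grid frequency below which 95% of the band power lies.
    """
    sel = psd.band_slice(band.f_lo, band.f_hi)
    p = psd.power[sel]
    f = psd.freqs[sel]
    total = p.sum()
    if total <= 0:
        raise ValueError(f"all-zero PSD in band {band.name}")
    cf = float(np.sum(f * p) / total)
    bw = float(np.sqrt(np.sum((f - cf) ** 2 * p) / total))
    cum = np.cumsum(p)
    sef = float(f[np.searchsorted(cum, 0.95 * total)])
    return cf, bw, sef


#: feature-registry defaults: which bands get CF/B/SEF95
SHAPE_BANDS = ("delta", "theta", "alpha", "beta", "gamma")


def spectral_features(x: np.ndarray, fs: float, *, bands=None,
                      shape_bands=SHAPE_BANDS, window_s: float = 1.0,
                      overlap_s: float = 0.5, nfft: int = 2 ** 14) -> dict:
    """All Welch-PSD features of one channel fragment as a flat dict.

    Keys: ``AP_<band>``, ``RP_<band>``, ``RPTA``, ``CF_<band>``, ``B_<band>``,
    ``SEF95_<band>``.
    """
    bands = bands or BANDS
    psd = welch_psd(x, fs, window_s, overlap_s, nfft)
    pw = band_powers(psd, bands)
    out = {}
    for name, v in pw["AP"].items():
        out[f"AP_{name}"] = v
    for name, v in pw["RP"].items():
        out[f"RP_{name}"] = v
    out["RPTA"] = pw["RPTA"]
    for name in shape_bands:
        cf, bw, sef = spectral_shape(psd, bands[name])
        out[f"CF_{name}"] = cf
        out[f"B_{name}"] = bw
        out[f"SEF95_{name}"] = sef
    return out
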