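"""Synthetic EEG cohorts with fully known ground truth.

Every downstream stage of the pipeline (preprocessing, spectral features,
alpha peak, DFA, PCA, mixed models) is tested against cohorts generated
here, because real listening-study EEG of this kind is rarely shareable.
The generator plants:

* a 1/f^a scale-free background per channel (spectral synthesis),
* region-weighted narrowband oscillators whose amplitude envelope is an
  offset fractional Gaussian noise with a chosen Hurst exponent (so the
  DFA scaling exponent of the alpha envelope is known by construction),
* condition- and participant-level shifts of band powers / Hurst exponents,
* a delayed copy of the presented audio on a sync channel, and
* exam keyword counts as a noisy linear function of planted latents.

All randomness flows from one integer seed per cohort; fragments draw
independent substreams via ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import BIOSEMI64, SUBREGIONS, default_subregion_map
from .recording import BACKGROUNDS, TASKS, ConditionManifest, EEGRecording

#: modulation depth of the oscillator envelope (fraction of its mean);
#: large enough that the planted Hurst exponent dominates the extracted
#: Hilbert envelope, small enough that clipping at zero is negligible.
ENVELOPE_DEPTH = 0.5
_ENVELOPE_FLOOR = 0.05

#: latent feature names the effect plan may shift / weight.
LATENTS = ("hurst", "log_alpha_power", "log_bg_power",
           "log_ap_delta", "log_ap_theta", "log_ap_beta", "log_ap_gamma")

_GAIN_BANDS = {  # latent -> frequency band whose background power it scales
    "log_ap_delta": (1.0, 4.0),
    "log_ap_theta": (4.0, 8.0),
    "log_ap_beta": (13.0, 30.0),
    "log_ap_gamma": (30.0, 45.0),
}


# ---------------------------------------------------------------------------
# elementary noise generators
# ---------------------------------------------------------------------------

def fgn(n: int, hurst: float, rng: np.random.Generator,
        sigma: float = 1.0) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding.

    Synthesizes ``n`` samples of zero-mean fGn with Hurst exponent
    ``hurst`` and standard deviation ``sigma`` using the Davies-Harte
    construction (circulant embedding of the fGn autocovariance), which is
    exact in distribution whenever the circulant eigenvalues are
    non-negative — true for the fGn covariance at any H in (0, 1).
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"Hurst exponent must be in (0, 1), got {hurst}")
    if n < 1:
        raise ValueError("n must be positive")
    if hurst == 0.5:
        return sigma * rng.standard_normal(n)
    k = np.arange(n + 1, dtype=np.float64)
    h2 = 2.0 * hurst
    gamma = 0.5 * sigma ** 2 * (
        np.abs(k + 1) ** h2 - 2 * np.abs(k) ** h2 + np.abs(k - 1) ** h2
    )
    # first row of the 2n circulant: gamma_0..gamma_n, gamma_{n-1}..gamma_1
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    lam = np.maximum(lam, 0.0)  # clip numerically tiny negatives
    m = row.size
    w = np.zeros(m, dtype=np.complex128)
    half = m // 2
    w[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
    w[half] = np.sqrt(lam[half] / m) * rng.standard_normal()
    a = rng.standard_normal(half - 1)
    b = rng.standard_normal(half - 1)
    amp = np.sqrt(lam[1:half] / (2 * m))
    w[1:half] = amp * (a + 1j * b)
    w[half + 1:] = np.conj(w[half - 1:0:-1])
    return np.fft.fft(w).real[:n]


def spectral_noise(n: int, fs: float, exponent: float,
                   rng: np.random.Generator, *,
                   total_power: float = 1.0,
                   power_range: tuple = (1.0, 45.0),
                   band_gains: dict | None = None) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent one-sided PSD.

    ``total_power`` fixes the integral of the PSD over ``power_range``
    (microvolt^2 when the signal is in microvolts).  ``band_gains`` maps
    ``(f_lo, f_hi)`` tuples to multiplicative power gains applied on top of
    the power-law shape — used to plant condition-dependent band powers.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    f = np.fft.rfftfreq(n, 1.0 / fs)
    psd = np.zeros_like(f)
    psd[1:] = f[1:] ** (-exponent)
    lo, hi = power_range
    sel = (f >= lo) & (f < hi)
    base = np.trapezoid(psd[sel], f[sel])
    if base <= 0:
        raise ValueError("degenerate power-law shape")
    psd *= total_power / base
    if band_gains:
        for (blo, bhi), gain in band_gains.items():
            psd[(f >= blo) & (f < bhi)] *= gain
    # E|X_k|^2 = S(f_k) * n * fs / 2 gives the requested one-sided density
    shape = np.sqrt(psd * n * fs / 2.0)
    x = rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)
    x *= shape / np.sqrt(2.0)
    x[0] = 0.0
    if n % 2 == 0:
        x[-1] = x[-1].real * np.sqrt(2.0)
    return np.fft.irfft(x, n)


def narrowband_phase(n: int, fs: float, center_hz: float, bandwidth_hz: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude narrowband oscillation cos(phi(t)).

    The instantaneous frequency wanders slowly around ``center_hz`` with a
    Gaussian spread of ``bandwidth_hz / 2`` (low-passed Gaussian noise), so
    the PSD is a bump of roughly the requested width while the oscillation
    keeps constant amplitude — any envelope multiplied on afterwards is, by
    construction, the Hilbert envelope of the oscillation.  (Normalizing
    narrowband-filtered noise to unit modulus does NOT work here: its phase
    slips create broadband clicks that band-pass filtering turns back into
    envelope noise, destroying a planted envelope exponent.)
    """
    f = np.fft.rfftfreq(n, 1.0 / fs)
    # unit-variance slow modulator: Gaussian-tapered low-pass of white noise
    shape = np.exp(-0.5 * (f / max(bandwidth_hz, 1e-6)) ** 2)
    shape[0] = 0.0
    spec = (rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size))
    g = np.fft.irfft(spec * shape, n)
    sd = g.std()
    if sd > 0:
        g /= sd
    inst_f = center_hz + 0.5 * bandwidth_hz * g
    phase = (2.0 * np.pi * np.cumsum(inst_f) / fs
             + 2.0 * np.pi * rng.random())
    return np.cos(phase)


def synthetic_audio(duration_s: float, fs: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Speech-like stand-in audio: broadband noise with ~4 Hz envelope."""
    n = int(round(duration_s * fs))
    carrier = rng.standard_normal(n)
    env = 1.0 + 0.8 * np.sin(
        2 * np.pi * 4.0 * np.arange(n) / fs + 2 * np.pi * rng.random())
    return carrier * env


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------

@dataclass
class OscillatorSpec:
    """One planted narrowband oscillator.

    ``peak_power`` is the total band-integrated power of the bump in
    microvolt^2; ``envelope_hurst`` the Hurst exponent of the fGn driving
    its amplitude envelope; ``region_weights`` per-subregion amplitude gains.
    """

    center_hz: float = 10.0
    peak_power: float = 30.0
    bandwidth_hz: float = 1.0
    envelope_hurst: float = 0.7
    region_weights: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.envelope_hurst < 1.0:
            raise ValueError("envelope_hurst must be in (0, 1)")
        if self.bandwidth_hz <= 0:
            raise ValueError("bandwidth_hz must be positive")
        if self.peak_power <= 0:
            raise ValueError("peak_power must be positive")
        unknown = set(self.region_weights) - set(SUBREGIONS)
        if unknown:
            raise ValueError(f"unknown subregions: {unknown}")

    def weight(self, subregion: str) -> float:
        return float(self.region_weights.get(subregion, 1.0))


@dataclass
class CohortSpec:
    """Design of a synthetic listening cohort.

    Defaults mirror the study design this pipeline targets: 23 participants,
    three listening tasks (lecture attended LA, background attended BA,
    background unattended BUA), four background sounds (pink noise PK only
    during lectures, multi-talker MT, highway HW, fluctuating traffic FT),
    5-minute lectures and 3-minute background fragments, 64 channels at
    512 Hz.  Scale down (fewer participants/topics/channels, shorter
    fragments, lower fs) for quick simulations.
    """

    n_participants: int = 23
    tasks: tuple = TASKS
    backgrounds: tuple = BACKGROUNDS
    fragment_duration_s: dict = field(
        default_factory=lambda: {"LA": 300.0, "BA": 180.0, "BUA": 180.0})
    fs: float = 512.0
    n_channels: int = 64
    seed: int = 0
    n_topics: int = 13
    n_background_fragments: int = 12  # per BA / BUA task
    gap_s: float = 2.0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks: {unknown}")
        unknown = set(self.backgrounds) - set(BACKGROUNDS)
        if unknown:
            raise ValueError(f"unknown backgrounds: {unknown}")
        if not 1 <= self.n_channels <= len(BIOSEMI64):
            raise ValueError("n_channels must be in [1, 64]")
        missing = set(self.tasks) - set(self.fragment_duration_s)
        if missing:
            raise ValueError(f"no duration for tasks: {missing}")

    @property
    def labels(self) -> list:
        return select_labels(self.n_channels)

    def participants(self) -> list:
        return [f"P{i + 1:02d}" for i in range(self.n_participants)]

    def manifest_rows(self, participant_idx: int) -> list:
        """Fragment plan for one participant (times are within their record).

        LA topics get backgrounds by rotating ``backgrounds`` with the
        participant index, which guarantees every topic is heard in pink
        noise by several participants (required by the exam z-score
        reference) while spreading the other backgrounds over topics.
        """
        rows = []
        t = 0.0
        pid = f"P{participant_idx + 1:02d}"
        la_bgs = [bg for bg in BACKGROUNDS if bg in self.backgrounds]
        noise_bgs = [bg for bg in la_bgs if bg != "PK"] or la_bgs
        if "LA" in self.tasks:
            dur = self.fragment_duration_s["LA"]
            for topic in range(self.n_topics):
                bg = la_bgs[(topic + participant_idx) % len(la_bgs)]
                rows.append((pid, "LA", bg, f"T{topic + 1:02d}", t, t + dur))
                t += dur + self.gap_s
        for task in ("BA", "BUA"):
            if task not in self.tasks:
                continue
            dur = self.fragment_duration_s[task]
            for i in range(self.n_background_fragments):
                bg = noise_bgs[i % len(noise_bgs)]
                rows.append((pid, task, bg, None, t, t + dur))
                t += dur + self.gap_s
        return rows


def select_labels(n: int) -> list:
    """First ``n`` scalp labels, chosen round-robin over subregions so every
    subregion stays populated even for small synthetic montages."""
    if n == len(BIOSEMI64):
        return list(BIOSEMI64)
    sub = default_subregion_map()
    by_region = {sr: [lab for lab in BIOSEMI64 if sub[lab] == sr]
                 for sr in SUBREGIONS}
    out: list = []
    i = 0
    while len(out) < n:
        sr = SUBREGIONS[i % len(SUBREGIONS)]
        pool = by_region[sr]
        if pool:
            out.append(pool.pop(0))
        i += 1
    return out


@dataclass
class EffectPlan:
    """Planted statistical structure on top of the base cohort.

    ``fixed_shifts`` maps ``(task, background, latent)`` to an additive shift
    of that latent (log powers in natural-log units, ``hurst`` in exponent
    units).  ``participant_sd`` scales Gaussian participant random
    intercepts on every latent (and on the exam score); ``fragment_sd``
    adds per-fragment jitter so latents vary within condition.
    ``exam_weights`` maps latents to slopes of the exam model (in keywords
    per standard deviation of the latent); ``exam_noise_sd`` is the
    residual scale of the exam in keywords.
    """

    fixed_shifts: dict = field(default_factory=dict)
    participant_sd: float = 0.1
    fragment_sd: float = 0.1
    exam_weights: dict = field(default_factory=dict)
    exam_noise_sd: float = 1.5
    exam_base_range: tuple = (8.0, 16.0)
    max_keywords: int = 25

    def __post_init__(self):
        if self.participant_sd < 0 or self.exam_noise_sd < 0:
            raise ValueError("scales must be non-negative")
        for key in self.fixed_shifts:
            if key[2] not in LATENTS:
                raise ValueError(f"unknown latent in fixed_shifts: {key[2]}")
        unknown = set(self.exam_weights) - set(LATENTS)
        if unknown:
            raise ValueError(f"unknown latents in exam_weights: {unknown}")

    def shift(self, task: str, background: str, latent: str) -> float:
        return float(self.fixed_shifts.get((task, background, latent), 0.0))


# ---------------------------------------------------------------------------
# recording-level generation
# ---------------------------------------------------------------------------

def generate_recording(spec: CohortSpec, oscillators, onef_exponent: float = 1.0,
                       seed: int | np.random.SeedSequence = 0, *,
                       duration_s: float | None = None,
                       background_power: float = 50.0,
                       band_gains: dict | None = None):
    """Generate one multichannel fragment and its ground truth.

    The per-channel PSD is a 1/f^``onef_exponent`` background (total
    ``background_power`` microvolt^2 over 1-45 Hz) plus one bump per
    oscillator.  Each oscillator is a constant-modulus narrowband carrier
    multiplied by a strictly positive offset-fGn envelope, shared across
    channels up to the per-subregion gain, so the planted envelope Hurst
    exponent is recoverable from any channel.

    Returns ``(EEGRecording, truth)`` where ``truth`` records every planted
    value.
    """
    if not 0.0 <= onef_exponent <= 2.0:
        raise ValueError("onef_exponent must be in [0, 2]")
    fs = spec.fs
    for osc in oscillators:
        if osc.center_hz >= fs / 2.0:
            raise ValueError(
                f"oscillator at {osc.center_hz} Hz >= Nyquist ({fs / 2} Hz)")
    dur = duration_s if duration_s is not None else min(
        spec.fragment_duration_s.values())
    n = int(round(dur * fs))
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)

    labels = spec.labels
    sub = default_subregion_map(labels, require_all=False)
    data = np.empty((len(labels), n))
    gains = None
    if band_gains:
        gains = {_GAIN_BANDS[k]: float(np.exp(v))
                 for k, v in band_gains.items() if k in _GAIN_BANDS}
    for c in range(len(labels)):
        data[c] = spectral_noise(n, fs, onef_exponent, rng,
                                 total_power=background_power,
                                 band_gains=gains)

    truth = {
        "fs": fs, "duration_s": dur, "onef_exponent": onef_exponent,
        "background_power": background_power,
        "band_gains": dict(band_gains or {}), "oscillators": [],
    }
    for osc in oscillators:
        env_raw = fgn(n, osc.envelope_hurst, rng)
        sd = env_raw.std()
        env = 1.0 + ENVELOPE_DEPTH * (env_raw / sd if sd > 0 else env_raw)
        np.clip(env, _ENVELOPE_FLOOR, None, out=env)
        carrier = narrowband_phase(n, fs, osc.center_hz, osc.bandwidth_hz, rng)
        amp = np.sqrt(2.0 * osc.peak_power / np.mean(env ** 2))
        wave = amp * env * carrier
        for c, lab in enumerate(labels):
            data[c] += osc.weight(sub[lab]) * wave
        truth["oscillators"].append({
            "center_hz": osc.center_hz, "peak_power": osc.peak_power,
            "bandwidth_hz": osc.bandwidth_hz,
            "envelope_hurst": osc.envelope_hurst,
            "region_weights": dict(osc.region_weights),
            "envelope": env,  # planted envelope (pre-modulation ground truth)
        })

    rec = EEGRecording(data=data, fs=fs, labels=list(labels))
    rec.meta["synthetic"] = True
    return rec, truth


def generate_sync_channel(rec: EEGRecording, audio: np.ndarray,
                          delay_samples: int, *,
                          noise_sd: float = 0.0,
                          rng: np.random.Generator | None = None,
                          label: str = "Sound") -> EEGRecording:
    """Append a sound channel: the audio delayed by ``delay_samples``.

    Positive delay means the audio arrives later in the recorded sound
    channel than in the presented file (playback latency).
    """
    if not 0 <= delay_samples < rec.n_samples:
        raise ValueError("delay_samples must be in [0, n_samples)")
    audio = np.asarray(audio, dtype=np.float64)
    chan = np.zeros(rec.n_samples)
    m = min(audio.size, rec.n_samples - delay_samples)
    chan[delay_samples:delay_samples + m] = audio[:m]
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        chan = chan + noise_sd * rng.standard_normal(chan.size)
    out = rec.copy(data=np.vstack([rec.data, chan]),
                   labels=list(rec.labels) + [label])
    out.meta["sync_delay_samples"] = int(delay_samples)
    return out


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------

_BASE = {  # cohort-level base values of the plantable latents
    "hurst": 0.7, "log_alpha_power": np.log(30.0),
    "log_bg_power": np.log(50.0), "log_ap_delta": 0.0, "log_ap_theta": 0.0,
    "log_ap_beta": 0.0, "log_ap_gamma": 0.0,
}


def generate_cohort(spec: CohortSpec, plan: EffectPlan | None = None, *,
                    onef_exponent: float = 1.0,
                    oscillator: OscillatorSpec | None = None,
                    background_power: float = 50.0,
                    signals: bool = True):
    """Yield ``(participant, EEGRecording, manifest_rows, truth_rows)``.

    One continuous recording per participant: all fragments of the manifest
    concatenated with short silent gaps.  ``truth_rows`` is a list of dicts
    holding the realized latent values of each fragment (the planted ground
    truth).  With ``signals=False`` the (identical) latent draws are made but
    no waveform is synthesized and the recording slot is ``None``.

    Recordings are yielded one at a time so full-size cohorts never have to
    be resident in memory at once.
    """
    plan = plan or EffectPlan()
    base_osc = oscillator or OscillatorSpec()
    base = dict(_BASE)
    base["log_alpha_power"] = float(np.log(base_osc.peak_power))
    base["log_bg_power"] = float(np.log(background_power))
    root = np.random.SeedSequence(spec.seed)
    part_ss, frag_root = root.spawn(2)
    part_rng = np.random.default_rng(part_ss)
    # participant random intercepts on every latent, drawn once
    intercepts = {
        pid: {lat: plan.participant_sd * part_rng.standard_normal()
              for lat in LATENTS}
        for pid in spec.participants()
    }
    frag_streams = iter(frag_root.spawn(
        spec.n_participants * len(spec.manifest_rows(0)) * 2))

    for p_idx, pid in enumerate(spec.participants()):
        rows = spec.manifest_rows(p_idx)
        n_total = int(round((rows[-1][5] + spec.gap_s) * spec.fs))
        data = np.zeros((spec.n_channels, n_total)) if signals else None
        truth_rows = []
        for frag_idx, (pid_, task, bg, topic, start, stop) in enumerate(rows):
            ss = next(frag_streams)
            jrng = np.random.default_rng(next(frag_streams))
            latents = {}
            for lat in LATENTS:
                latents[lat] = (base[lat]
                                + plan.shift(task, bg, lat)
                                + intercepts[pid][lat]
                                + plan.fragment_sd * jrng.standard_normal())
            hurst = float(np.clip(latents["hurst"], 0.05, 0.95))
            latents["hurst"] = hurst
            if signals:
                osc = OscillatorSpec(
                    center_hz=base_osc.center_hz,
                    peak_power=float(np.exp(latents["log_alpha_power"])),
                    bandwidth_hz=base_osc.bandwidth_hz,
                    envelope_hurst=hurst,
                    region_weights=dict(base_osc.region_weights),
                )
                frag, _ = generate_recording(
                    spec, [osc], onef_exponent, ss,
                    duration_s=stop - start,
                    background_power=float(np.exp(latents["log_bg_power"])),
                    band_gains={k: latents[k] for k in _GAIN_BANDS},
                )
                i0 = int(round(start * spec.fs))
                data[:, i0:i0 + frag.n_samples] = frag.data
            truth_rows.append({
                "participant": pid, "task": task, "background": bg,
                "topic": topic, "start_s": start, "stop_s": stop,
                **latents,
            })
        rec = None
        if signals:
            rec = EEGRecording(data=data, fs=spec.fs, labels=list(spec.labels))
            rec.meta["synthetic"] = True
            rec.meta["participant"] = pid
        yield pid, rec, rows, truth_rows


def cohort_truth_table(spec: CohortSpec, plan: EffectPlan | None = None, *,
                       onef_exponent: float = 1.0,
                       oscillator: OscillatorSpec | None = None) -> pd.DataFrame:
    """Planted per-fragment latents for the whole cohort, without keeping any
    recording (same random draws as :func:`generate_cohort`)."""
    frames = []
    for _, _, _, truth_rows in generate_cohort(
            spec, plan, onef_exponent=onef_exponent, oscillator=oscillator,
            signals=False):
        frames.extend(truth_rows)
    return pd.DataFrame(frames)


def manifest_for(spec: CohortSpec) -> ConditionManifest:
    rows = []
    for p_idx in range(spec.n_participants):
        rows.extend(spec.manifest_rows(p_idx))
    df = pd.DataFrame(rows, columns=["participant", "task", "background",
                                     "topic", "start_s", "stop_s"])
    return ConditionManifest(df)


# ---------------------------------------------------------------------------
# exam generation
# ---------------------------------------------------------------------------

def generate_exam_table(plan: EffectPlan, truth: pd.DataFrame,
                        seed: int = 0) -> pd.DataFrame:
    """Exam keyword counts from planted latents.

    ``truth`` must hold one row per LA fragment with columns ``participant``,
    ``topic``, ``background`` and the latent features named by
    ``plan.exam_weights``.  The keyword count for a (participant, topic) row
    is a rounded, clipped linear function of the standardized latents plus a
    participant intercept and Gaussian noise.  Raises if some topic has no
    pink-noise presentation (the exam z-score of Eq-style normalization
    needs a silence reference per topic).
    """
    la = truth[truth["task"] == "LA"].copy() if "task" in truth else truth.copy()
    if la.empty:
        raise ValueError("no LA fragments in truth table")
    if la["topic"].isna().any():
        raise ValueError("every LA fragment needs a topic")
    missing = [t for t, grp in la.groupby("topic")
               if (grp["background"] == "PK").sum() < 2]
    if missing:
        raise ValueError(
            f"topics without >=2 pink-noise presentations: {missing}")
    for lat in plan.exam_weights:
        if lat not in la.columns:
            raise ValueError(f"latent {lat!r} missing from truth table")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    topics = sorted(la["topic"].unique())
    lo, hi = plan.exam_base_range
    base = {t: rng.uniform(lo, hi) for t in topics}
    participants = sorted(la["participant"].unique())
    intercept = {p: plan.participant_sd * rng.standard_normal()
                 for p in participants}

    score = np.full(len(la), 0.0)
    for lat, w in plan.exam_weights.items():
        col = la[lat].to_numpy(dtype=float)
        sd = col.std(ddof=1)
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        score += w * z
    score += np.array([base[t] for t in la["topic"]])
    score += np.array([intercept[p] for p in la["participant"]])
    score += plan.exam_noise_sd * rng.standard_normal(len(la))
    kw = np.clip(np.rint(score), 0, plan.max_keywords).astype(int)

    return pd.DataFrame({
        "participant": la["participant"].to_numpy(),
        "topic": la["topic"].to_numpy(),
        "background": la["background"].to_numpy(),
        "keywords_correct": kw,
    })
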