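# eeglisten

EEG correlates of listening to — and learning from — speech in environmental
noise.  `eeglisten` is a tested, reusable pipeline for studies in which
participants listen to lectures embedded in realistic background sounds
(multi-talker babble, highway, fluctuating traffic, or near-silence/pink
noise) under different attention instructions, while 64-channel EEG is
recorded and retention is measured with a written exam.  It is aimed at
auditory-cognition and environmental-noise researchers who want the whole
chain — preprocessing, feature extraction, dimension reduction, mixed-effect
inference — as reproducible code rather than a pile of scripts.

Because raw EEG from such studies is rarely shareable, the package also
ships a **synthetic-cohort generator** that plants known ground truth
(band powers, alpha peak frequency, envelope Hurst exponents,
condition/participant effects, exam structure) so that every stage can be
validated by parameter recovery without any download.

## What it computes

Per channel and listening-condition fragment:

* **Welch spectra and band features** — absolute/relative power in
  delta (1–4), theta (4–8), alpha (8–13, 7–13, lower/upper), beta (13–30),
  gamma (30–45) and wide (1–45 Hz) bands; theta/alpha ratio; spectral
  centre of gravity CF, bandwidth B (root second spectral moment) and 95%
  spectral edge SEF95 per band.
* **Alpha peak** — root-MUSIC subspace line estimates (MF/MP in the 7–13
  and 8–13 Hz ranges, signal-subspace dimension P = 2) and the individual
  alpha frequency (IAF): 1/f detrending of ln power, single-Gaussian fit,
  95% prediction-bound acceptance, and the centre of gravity of the
  individually delimited alpha interval.
* **Long-range temporal correlations** — detrended fluctuation analysis of
  the 8–13 Hz Hilbert envelope: cumulative sum of the mean-removed
  envelope, 50%-overlapping log-spaced windows, linear detrending, scaling
  exponents SEV1/SEV2 (calculation ranges 2.5–180 s and 0.1–180 s, fit
  5–18 s); `0.5 < SEV < 1` flags LRTC.

Across the cohort:

* **PCA** of the z-scored (log-power) feature matrix via SVD — scores,
  loadings, explained variance, per-component contributions — and
  subregion-averaged component scores over six scalp regions.
* **Mixed-effect models** (participant random intercepts) of component
  scores within background and within task, with Tukey post-hoc tables; exam
  z-scores referenced to each topic's pink-noise performance; and exam
  prediction by constant / background-type / full-EEG / backward-AIC
  stepwise regressions compared by AIC and likelihood-ratio tests.

See `docs/methods.md` for the model of the synthetic world, estimator
conventions and known statistical limits.

## Worked example

```python
import numpy as np
from eeglisten.synth import CohortSpec, OscillatorSpec, generate_recording
from eeglisten.alphapeak import rootmusic_peak
from eeglisten.dfa import alpha_lrtc
from eeglisten.spectral import welch_psd, band_powers

spec = CohortSpec(n_participants=1, n_channels=6, fs=512.0)
osc = OscillatorSpec(center_hz=10.4, peak_power=40.0, envelope_hurst=0.8)
rec, truth = generate_recording(spec, [osc], onef_exponent=1.0, seed=7,
                                duration_s=180, background_power=4.0)

x = rec.data[0]
peak = rootmusic_peak(x, rec.fs, band=(8.0, 13.0))
sev = alpha_lrtc(x, rec.fs)
rp = band_powers(welch_psd(x, rec.fs))["RP"]["alpha"]
print(f"MF2813 = {peak.MF:.2f} Hz   SEV1 = {sev.SEV:.2f}   RP_alpha = {rp:.2f}")
```

prints

```
MF2813 = 10.40 Hz   SEV1 = 0.71   RP_alpha = 0.85
```

— the root-MUSIC alpha peak lands on the planted 10.4 Hz bump, the DFA
scaling exponent recovers the planted envelope Hurst exponent 0.8 (within
its ~0.07 sampling noise; `0.5 < SEV < 1` indicates long-range temporal
correlations), and the relative alpha power reflects the deliberately
strong-alpha regime of this example.

The same thing end to end, from a shell:

```bash
eeglisten run-all --out runs/demo --seed 1 \
    --participants 8 --channels 12 --fs 128 --topics 4 \
    --la-duration 60 --ba-duration 40
```

writes per-participant EDFs with a delayed sync-audio channel, the
condition manifest, planted ground truth, the long-format feature table,
PC scores/loadings/contributions, subregion scores, exam z-scores, Tukey
tables and the exam-model comparison report into `runs/demo/`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch on a seeded synthetic cohort
(simulate → preprocess/extract → PCA → mixed models), checks that every
stage produces its outputs, and writes the results JSON to `--out`.
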