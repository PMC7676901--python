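"""Preprocessing: re-referencing, filtering/resampling, delay estimation,
fragment splitting, EDF round-trips and the subregion partition."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from eeglisten.edfio import read_edf, write_edf
from eeglisten.montage import (BIOSEMI64, SUBREGIONS, default_subregion_map,
                               validate_subregion_map)
from eeglisten.preprocess import (bandpass_fir, estimate_delay, rereference,
                                  resample_filter, split_fragments)
from eeglisten.recording import ConditionManifest, EEGRecording


def _rec(rng, n_ch=4, fs=256.0, dur=10.0, labels=None):
    n = int(fs * dur)
    labels = labels or [f"ch{i}" for i in range(n_ch)]
    return EEGRecording(data=rng.standard_normal((len(labels), n)), fs=fs,
                        labels=labels)


class TestRereference:
    def test_idempotent_and_zero_reference(self, rng):
        rec = _rec(rng)
        once = rereference(rec, "ch0")
        twice = rereference(once, "ch0")
        np.testing.assert_allclose(once.data, twice.data)
        assert np.all(once.channel("ch0") == 0)
        assert once.reference == "ch0"

    def test_channel_contrast_invariant(self, rng):
        rec = _rec(rng)
        diff_before = rec.channel("ch1") - rec.channel("ch2")
        after = rereference(rec, "ch3")
        diff_after = after.channel("ch1") - after.channel("ch2")
        np.testing.assert_allclose(diff_before, diff_after, atol=1e-12)

    def test_missing_reference(self, rng):
        with pytest.raises(ValueError, match="reference"):
            rereference(_rec(rng), "Nose")


class TestResampleFilter:
    def test_passband_tone_preserved_and_dc_removed(self, rng):
        fs = 1024.0
        t = np.arange(int(fs * 20)) / fs
        x = 10.0 * np.sin(2 * np.pi * 10 * t) + 50.0  # tone + DC offset
        rec = EEGRecording(data=x[None, :], fs=fs, labels=["a"])
        out = resample_filter(rec, target_fs=512, band=(0.5, 134), order=1690)
        assert out.fs == 512
        y = out.data[0][512 * 2: -512 * 2]  # exclude edges
        amp = np.sqrt(2.0) * y.std()
        assert amp == pytest.approx(10.0, rel=0.01)
        assert abs(y.mean()) < 0.5  # DC suppressed to < 1% of 50 uV

    def test_slow_drift_attenuated(self):
        # evaluate the realized filter response at 0.05 Hz and in-band ripple
        taps = bandpass_fir(512, (0.5, 134), order=3380)
        w, h = signal.freqz(taps, worN=2 ** 15, fs=512)
        gain_db = 20 * np.log10(np.abs(h) + 1e-12)
        assert gain_db[np.argmin(np.abs(w - 0.05))] <= -20
        band = (w >= 1) & (w <= 100)
        assert np.max(np.abs(gain_db[band])) < 1.0  # ripple < 1 dB

    def test_linearity(self, rng):
        fs = 512.0
        x = rng.standard_normal((1, int(fs * 5)))
        y = rng.standard_normal((1, int(fs * 5)))
        def f(d):
            rec = EEGRecording(data=d, fs=fs, labels=["a"])
            return resample_filter(rec, target_fs=512, band=(1, 100),
                                   order=200).data
        np.testing.assert_allclose(f(2 * x + 3 * y), 2 * f(x) + 3 * f(y),
                                   atol=1e-9)

    def test_band_edge_validation(self, rng):
        rec = _rec(rng, fs=256)
        with pytest.raises(ValueError):
            resample_filter(rec, target_fs=256, band=(0.5, 140), order=100)


class TestEstimateDelay:
    def test_exact_shifts_both_signs(self, rng):
        x = rng.standard_normal(4000)
        rec = np.roll(x, 100)
        assert estimate_delay(rec, x) == 100
        assert estimate_delay(np.roll(x, -50), x) == -50
        assert estimate_delay(x, x) == 0

    def test_noisy_copy_at_0db(self):
        hits = 0
        for s in range(10):
            r = np.random.default_rng(s)
            x = r.standard_normal(8000)
            rec = np.roll(x, 137) + r.standard_normal(8000)  # 0 dB SNR
            hits += estimate_delay(rec, x) == 137
        assert hits >= 9

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_delay(np.ones(100), np.random.default_rng(0).standard_normal(100))


class TestSplitFragments:
    def _manifest(self, rows):
        return ConditionManifest(pd.DataFrame(
            rows, columns=["participant", "task", "background", "topic",
                           "start_s", "stop_s"]))

    def test_sample_counts(self, rng):
        rec = _rec(rng, fs=512, dur=400)
        man = self._manifest([("P1", "BA", "MT", None, 0.0, 180.0),
                              ("P1", "BA", "HW", None, 180.0, 360.0)])
        frags = split_fragments(rec, man)
        assert len(frags) == 2
        for frag, tags in frags:
            assert frag.n_samples == 92160

    def test_roundtrip_concatenation(self, rng):
        rec = _rec(rng, fs=128, dur=30)
        man = self._manifest([("P1", "BA", "MT", None, 0.0, 10.0),
                              ("P1", "BA", "MT", None, 10.0, 30.0)])
        frags = split_fragments(rec, man)
        joined = np.concatenate([f.data for f, _ in frags], axis=1)
        np.testing.assert_array_equal(joined, rec.data)

    def test_empty_manifest_and_out_of_range(self, rng):
        rec = _rec(rng, fs=128, dur=10)
        empty = self._manifest([])
        assert split_fragments(rec, empty) == []
        bad = self._manifest([("P1", "BA", "MT", None, 5.0, 20.0)])
        with pytest.raises(ValueError, match="outside"):
            split_fragments(rec, bad)


class TestEdfIO:
    @pytest.mark.parametrize("ext", ["edf", "bdf"])
    def test_roundtrip(self, rng, tmp_path, ext):
        rec = _rec(rng, n_ch=3, fs=128, dur=4.5)
        rec.data *= 100.0
        path = tmp_path / f"test.{ext}"
        write_edf(path, rec)
        back = read_edf(path)
        assert back.labels == rec.labels
        assert back.fs == rec.fs
        got = back.data[:, : rec.n_samples]
        tol = 0.01 if ext == "edf" else 1e-4  # quantization of the format
        assert np.max(np.abs(got - rec.data)) < tol * 100 * 4

    def test_non_integer_fs_rejected(self, rng, tmp_path):
        rec = _rec(rng, fs=100.5, dur=2)
        with pytest.raises(ValueError):
            write_edf(tmp_path / "x.edf", rec)


class TestSubregions:
    def test_partition_of_64_channels(self):
        mapping = default_subregion_map()
        assert set(mapping) == set(BIOSEMI64)
        validate_subregion_map(mapping, BIOSEMI64)
        counts = {sr: 0 for sr in SUBREGIONS}
        for sr in mapping.values():
            counts[sr] += 1
        assert all(c > 0 for c in counts.values())
        assert sum(counts.values()) == 64

    def test_hemispheric_temporal_split(self):
        mapping = default_subregion_map()
        assert mapping["T7"] == "left_temporal"
        assert mapping["T8"] == "right_temporal"
        assert mapping["Cz"] == "central"
        assert mapping["Oz"] == "occipital"
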