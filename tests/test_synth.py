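"""Generator correctness: fGn statistics, planted spectra and envelopes,
sync channel, cohort design and exam construction."""

import numpy as np
import pandas as pd
import pytest

from eeglisten.dfa import dfa
from eeglisten.spectral import welch_psd, band_power
from eeglisten.synth import (CohortSpec, EffectPlan, OscillatorSpec,
                             cohort_truth_table, fgn, generate_cohort,
                             generate_exam_table, generate_recording,
                             generate_sync_channel, manifest_for,
                             spectral_noise, synthetic_audio)


class TestFgn:
    @pytest.mark.parametrize("hurst", [0.3, 0.5, 0.7, 0.9])
    def test_lag1_autocorrelation_matches_closed_form(self, hurst):
        # fGn lag-1 autocorrelation is 2^(2H-1) - 1; estimated without
        # demeaning (the mean is known to be zero) because sample-mean
        # subtraction is badly biased under long-range dependence
        acs = []
        for s in range(30):
            x = fgn(8192, hurst, np.random.default_rng(s))
            acs.append(np.sum(x[:-1] * x[1:]) / np.sum(x * x))
        assert np.mean(acs) == pytest.approx(2 ** (2 * hurst - 1) - 1,
                                             abs=0.02)

    def test_unit_variance(self):
        xs = np.concatenate([fgn(4096, 0.7, np.random.default_rng(s))
                             for s in range(20)])
        assert xs.std() == pytest.approx(1.0, rel=0.05)

    def test_dfa_oracle_recovers_planted_hurst(self):
        # independent check of the generator against the DFA estimator on
        # the raw (pre-modulation) fGn, averaged over seeds
        for hurst in (0.55, 0.8):
            sevs = [dfa(fgn(512 * 180, hurst, np.random.default_rng(s)),
                        512).SEV for s in range(10)]
            assert abs(np.mean(sevs) - hurst) <= 0.03

    def test_reproducible_and_validates(self):
        a = fgn(1000, 0.7, np.random.default_rng(3))
        b = fgn(1000, 0.7, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            fgn(100, 1.0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            fgn(100, 0.0, np.random.default_rng(0))


class TestSpectralNoise:
    def test_flat_spectrum_when_exponent_zero(self, rng):
        x = spectral_noise(512 * 120, 512, 0.0, rng, total_power=44.0)
        psd = welch_psd(x, 512)
        sel = (psd.freqs >= 1) & (psd.freqs < 45)
        logp = np.log(psd.power[sel])
        slope = np.polyfit(np.log(psd.freqs[sel]), logp, 1)[0]
        assert abs(slope) <= 0.05
        # flat over 1-45 with total power 44 -> density ~ 1
        assert np.median(psd.power[sel]) == pytest.approx(1.0, rel=0.1)

    def test_band_gains_plant_band_power(self, rng):
        gains = {(4.0, 8.0): 4.0}
        x = spectral_noise(512 * 120, 512, 0.0, rng, total_power=44.0,
                           band_gains=gains)
        psd = welch_psd(x, 512)
        theta = band_power(psd, 4, 8) / 4.0
        alpha = band_power(psd, 8, 13) / 5.0
        assert theta / alpha == pytest.approx(4.0, rel=0.15)


class TestGenerateRecording:
    def test_psd_shows_background_plus_bump(self, tiny_cohort):
        osc = OscillatorSpec(center_hz=10.4, peak_power=30.0)
        rec, truth = generate_recording(tiny_cohort, [osc], 1.0, seed=5,
                                        duration_s=60)
        psd = welch_psd(rec.data[0], tiny_cohort.fs, nfft=2 ** 13)
        # alpha-band power exceeds planted background + bump lower bound
        ap_alpha = band_power(psd, 8, 13)
        assert ap_alpha > 25.0
        # bump location
        sel = (psd.freqs >= 8) & (psd.freqs <= 13)
        fpeak = psd.freqs[sel][np.argmax(psd.power[sel])]
        assert fpeak == pytest.approx(10.4, abs=0.3)

    def test_planted_envelope_has_requested_hurst(self, tiny_cohort):
        sevs = []
        for s in range(5):
            _, truth = generate_recording(
                tiny_cohort, [OscillatorSpec(envelope_hurst=0.75)], 1.0,
                seed=s, duration_s=120)
            env = truth["oscillators"][0]["envelope"]
            sevs.append(dfa(env, tiny_cohort.fs).SEV)
        assert abs(np.mean(sevs) - 0.75) <= 0.05

    def test_region_weights_scale_alpha_power(self, tiny_cohort):
        osc = OscillatorSpec(region_weights={"occipital": 2.0,
                                             "frontal": 0.5})
        rec, _ = generate_recording(tiny_cohort, [osc], 0.0, seed=2,
                                    duration_s=60, background_power=1.0)
        from eeglisten.montage import default_subregion_map

        sub = default_subregion_map(rec.labels, require_all=False)
        occ = [i for i, lab in enumerate(rec.labels)
               if sub[lab] == "occipital"]
        fro = [i for i, lab in enumerate(rec.labels) if sub[lab] == "frontal"]
        p_occ = np.mean([band_power(welch_psd(rec.data[i], rec.fs,
                                              nfft=2 ** 12), 8, 13)
                         for i in occ])
        p_fro = np.mean([band_power(welch_psd(rec.data[i], rec.fs,
                                              nfft=2 ** 12), 8, 13)
                         for i in fro])
        assert p_occ / p_fro == pytest.approx(16.0, rel=0.25)

    def test_rejects_bad_parameters(self, tiny_cohort):
        with pytest.raises(ValueError):
            generate_recording(tiny_cohort,
                               [OscillatorSpec(center_hz=100.0)], 1.0, 0,
                               duration_s=10)  # >= Nyquist at fs 128
        with pytest.raises(ValueError):
            OscillatorSpec(envelope_hurst=1.2)
        with pytest.raises(ValueError):
            generate_recording(tiny_cohort, [], 3.0, 0, duration_s=10)

    def test_reproducibility_bit_identical(self, tiny_cohort):
        a, _ = generate_recording(tiny_cohort, [OscillatorSpec()], 1.0, 9,
                                  duration_s=20)
        b, _ = generate_recording(tiny_cohort, [OscillatorSpec()], 1.0, 9,
                                  duration_s=20)
        np.testing.assert_array_equal(a.data, b.data)


class TestSyncChannel:
    def test_exact_delay_roundtrip(self, tiny_cohort, rng):
        from eeglisten.preprocess import estimate_delay

        rec, _ = generate_recording(tiny_cohort, [], 1.0, 1, duration_s=20)
        audio = synthetic_audio(18, rec.fs, rng)
        for delay in (0, 100):
            out = generate_sync_channel(rec, audio, delay)
            assert out.labels[-1] == "Sound"
            est = estimate_delay(out.channel("Sound"), audio)
            assert est == delay

    def test_rejects_delay_beyond_length(self, tiny_cohort, rng):
        rec, _ = generate_recording(tiny_cohort, [], 1.0, 1, duration_s=5)
        with pytest.raises(ValueError):
            generate_sync_channel(rec, synthetic_audio(1, rec.fs, rng),
                                  rec.n_samples)


class TestCohortDesign:
    def test_manifest_covers_all_cells(self, tiny_cohort):
        man = manifest_for(tiny_cohort)
        df = man.fragments
        for task in ("LA", "BA", "BUA"):
            for bg in ("PK", "MT"):
                if task != "LA" and bg == "PK":
                    continue
                assert ((df["task"] == task) & (df["background"] == bg)).any()

    def test_truth_has_pink_reference_per_topic(self, tiny_cohort):
        truth = cohort_truth_table(tiny_cohort)
        la = truth[truth["task"] == "LA"]
        for _, grp in la.groupby("topic"):
            assert (grp["background"] == "PK").sum() >= 2

    def test_latents_shift_with_plan(self, tiny_cohort):
        plan = EffectPlan(fixed_shifts={("LA", "MT", "hurst"): 0.15},
                          participant_sd=0.0, fragment_sd=0.0)
        truth = cohort_truth_table(tiny_cohort, plan)
        la = truth[truth["task"] == "LA"]
        h_mt = la[la["background"] == "MT"]["hurst"].mean()
        h_pk = la[la["background"] == "PK"]["hurst"].mean()
        assert h_mt - h_pk == pytest.approx(0.15, abs=1e-12)


class TestExamTable:
    def _truth(self, tiny_cohort):
        return cohort_truth_table(tiny_cohort)

    def test_zero_weights_zero_noise_gives_degenerate_or_constant(
            self, tiny_cohort):
        from eeglisten.stats import exam_zscores

        plan = EffectPlan(exam_weights={}, exam_noise_sd=0.0,
                          participant_sd=0.0)
        exam = generate_exam_table(plan, self._truth(tiny_cohort), seed=1)
        ez = exam_zscores(exam)
        # constant scores per topic -> sigma_pink = 0 -> flagged degenerate
        stats = ez.attrs["pink_stats"]
        assert all(v["degenerate"] for v in stats.values())
        assert ez["z"].isna().all()

    def test_planted_weight_correlates_with_scores(self, tiny_cohort):
        truth = self._truth(tiny_cohort)
        plan = EffectPlan(exam_weights={"hurst": -3.0}, exam_noise_sd=0.3,
                          participant_sd=0.0)
        exam = generate_exam_table(plan, truth, seed=2)
        la = truth[truth["task"] == "LA"].reset_index(drop=True)
        merged = exam.merge(la[["participant", "topic", "hurst"]],
                            on=["participant", "topic"])
        r = np.corrcoef(merged["hurst"], merged["keywords_correct"])[0, 1]
        assert r < -0.5

    def test_missing_pink_cells_rejected(self, tiny_cohort):
        truth = self._truth(tiny_cohort)
        no_pink = truth[truth["background"] != "PK"]
        with pytest.raises(ValueError, match="pink"):
            generate_exam_table(EffectPlan(), no_pink, seed=0)

    def test_reproducible(self, tiny_cohort):
        truth = self._truth(tiny_cohort)
        a = generate_exam_table(EffectPlan(), truth, seed=5)
        b = generate_exam_table(EffectPlan(), truth, seed=5)
        pd.testing.assert_frame_equal(a, b)
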