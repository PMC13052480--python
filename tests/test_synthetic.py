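"""Synthetic cohort generator: ground truth, determinism, monotonicity."""

import numpy as np
import pandas as pd
import pytest

from polarppg.signal_io import CHANNEL_KEYS
from polarppg.skin_tone import compute_ita
from polarppg.synthetic import (
    BeatModel,
    ChannelModel,
    CohortConfig,
    SyntheticParticipant,
    design_participant,
    generate_cohort,
    generate_colorimeter_scans,
    generate_recording,
)


def participant_with(amp=0.01, offsets_co=0.0, melanin=1.0, **beat_kw):
    beat = BeatModel(systolic_amp=amp, **beat_kw)
    channels = tuple(
        ChannelModel(
            wavelength_nm=wl,
            polarization=pol,
            baseline_dc=40000.0,
            surface_offset=offsets_co if pol == "co" else 0.0,
            melanin_atten=melanin,
        )
        for wl, pol in CHANNEL_KEYS
    )
    return SyntheticParticipant("P", 58.0, 16.0, channels, beat)


class TestTypes:
    def test_beat_model_validation(self):
        with pytest.raises(ValueError):
            BeatModel(heart_rate_bpm=20.0)
        with pytest.raises(ValueError):
            BeatModel(dicrotic_amp=1.0)

    def test_channel_model_validation(self):
        with pytest.raises(ValueError):
            ChannelModel(655, "cross", 40000.0, surface_offset=10.0)
        with pytest.raises(ValueError):
            ChannelModel(655, "co", -5.0)
        with pytest.raises(ValueError):
            ChannelModel(655, "co", 40000.0, melanin_atten=1.5)

    def test_participant_ita_consistency(self):
        p = participant_with()
        assert p.true_ita_deg == pytest.approx(compute_ita(58.0, 16.0), abs=1e-12)
        with pytest.raises(ValueError):
            SyntheticParticipant("P", 58.0, 16.0, p.channels, p.beat,
                                 true_ita_deg=12.345)

    def test_participant_requires_four_channels(self):
        p = participant_with()
        with pytest.raises(ValueError):
            SyntheticParticipant("P", 58.0, 16.0, p.channels[:3], p.beat)


class TestGenerateRecording:
    def test_determinism(self):
        p1, p2 = participant_with(), participant_with()
        r1 = generate_recording(p1, 30.0, 25.0, seed=42)
        r2 = generate_recording(p2, 30.0, 25.0, seed=42)
        for k in CHANNEL_KEYS:
            assert np.array_equal(r1.channels[k], r2.channels[k])

    def test_ground_truth_matches_brute_force(self):
        """Noise-free per-beat truth equals a dense brute-force scan."""
        p = participant_with(amp=0.01)
        generate_recording(p, 20.0, 250.0, seed=3)
        key = (940, "cross")
        x = generate_recording(p, 20.0, 250.0, seed=3).channels[key]
        onsets = p.true_beat_onsets
        brute = []
        for a, b in zip(onsets, onsets[1:]):
            if b > 20.0:
                break
            seg = x[int(a * 250) : int(b * 250)]
            brute.append(100.0 * (seg.max() - seg.min()) / seg.min())
        assert np.allclose(p.true_pi_per_beat[key][: len(brute)], brute, rtol=0.02)

    def test_zero_amplitude_flat_truth(self):
        p = participant_with(amp=0.0)
        rec = generate_recording(p, 30.0, 25.0, seed=0)
        for k in CHANNEL_KEYS:
            assert p.true_pi_by_channel[k] == pytest.approx(0.0, abs=1e-12)
            assert np.ptp(rec.channels[k]) == pytest.approx(0.0, abs=1e-9)

    def test_surface_offset_strictly_lowers_pi(self):
        p0 = participant_with(offsets_co=0.0)
        p1 = participant_with(offsets_co=4000.0)
        generate_recording(p0, 30.0, 25.0, seed=1)
        generate_recording(p1, 30.0, 25.0, seed=1)
        key_co, key_cross = (655, "co"), (655, "cross")
        assert p1.true_pi_by_channel[key_co] < p0.true_pi_by_channel[key_co]
        # same AC, larger DC on co: co PI strictly below cross PI
        assert p1.true_pi_by_channel[key_co] < p1.true_pi_by_channel[key_cross]

    def test_melanin_attenuation_strictly_raises_pi(self):
        lo = participant_with(melanin=0.4)
        hi = participant_with(melanin=0.9)
        generate_recording(lo, 30.0, 25.0, seed=1)
        generate_recording(hi, 30.0, 25.0, seed=1)
        for k in CHANNEL_KEYS:
            assert hi.true_pi_by_channel[k] > lo.true_pi_by_channel[k]

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            generate_recording(participant_with(), 30.0, 8.0, seed=0)


class TestColorimeterScans:
    def test_zero_noise_exact(self):
        scans = generate_colorimeter_scans(58.0, 16.0, 20, 0.0, 0.0, seed=1)
        assert np.all(scans["L_star"] == 58.0)
        assert np.all(scans["b_star"] == 16.0)

    def test_reproducible(self):
        a = generate_colorimeter_scans(58.0, 16.0, seed=4)
        b = generate_colorimeter_scans(58.0, 16.0, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_b_rejected(self):
        with pytest.raises(ValueError):
            generate_colorimeter_scans(58.0, 0.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            generate_colorimeter_scans(58.0, 16.0, noise_sd_L=-0.1)

    def test_mean_scan_ita_near_truth(self):
        """Monte-Carlo: aggregated ITA stays within 3 propagated SEs."""
        from polarppg.skin_tone import aggregate_scans

        true_ita = compute_ita(58.0, 16.0)
        errs = []
        for seed in range(1000):
            scans = generate_colorimeter_scans(58.0, 16.0, seed=seed)
            errs.append(aggregate_scans(scans).mean_ita_deg - true_ita)
        errs = np.array(errs)
        se = errs.std()
        assert np.mean(np.abs(errs) <= 3 * se) > 0.99
        assert abs(errs.mean()) < 3 * se / np.sqrt(len(errs)) + 0.02


class TestGenerateCohort:
    def test_linear_effect_structure(self):
        cfg = CohortConfig(
            pi_intercept=0.66, pi_ita_slope=0.006,
            effect_cross=0.83, effect_interaction=-0.015,
            duration_s=30.0, seed=5,
        )
        cohort = generate_cohort(cfg)
        gt = cohort.ground_truth
        darkest = gt[gt["true_ita_deg"] == gt["true_ita_deg"].min()]
        co = darkest[darkest["condition"] == "co"]["target_pi"].iloc[0]
        cross = darkest[darkest["condition"] == "cross"]["target_pi"].iloc[0]
        ita = darkest["true_ita_deg"].iloc[0]
        assert cross - co == pytest.approx(0.83 - 0.015 * ita, abs=1e-10)
        assert cross > co  # uplift largest for darkest tone

    def test_uplift_shrinks_with_lighter_tone(self):
        cohort = generate_cohort(CohortConfig(duration_s=30.0, seed=5))
        gt = cohort.ground_truth.pivot_table(
            index="true_ita_deg", columns="condition", values="target_pi"
        )
        uplift = (gt["cross"] - gt["co"]).sort_index()
        assert np.all(np.diff(uplift.values) < 0)  # decreasing with ITA

    def test_no_effect_means_identical_conditions(self):
        cfg = CohortConfig(effect_cross=0.0, effect_interaction=0.0,
                           duration_s=30.0, seed=2)
        gt = generate_cohort(cfg).ground_truth
        piv = gt.pivot_table(index=["participant_id", "wavelength_nm"],
                             columns="condition", values="target_pi")
        assert np.allclose(piv["co"], piv["cross"], atol=1e-12)

    def test_determinism(self):
        a = generate_cohort(CohortConfig(duration_s=30.0, seed=9))
        b = generate_cohort(CohortConfig(duration_s=30.0, seed=9))
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)
        for pid in a.recordings:
            for k in CHANNEL_KEYS:
                assert np.array_equal(
                    a.recordings[pid].channels[k], b.recordings[pid].channels[k]
                )

    def test_realized_pi_tracks_target(self):
        gt = generate_cohort(CohortConfig(duration_s=30.0, seed=5)).ground_truth
        assert np.allclose(gt["true_pi"], gt["target_pi"], rtol=0.02)

    def test_nonpositive_pi_rejected_with_diagnostic(self):
        cfg = CohortConfig(pi_intercept=0.1, effect_cross=-2.0, duration_s=30.0)
        with pytest.raises(ValueError, match="nonpositive"):
            generate_cohort(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(duration_s=10.0)
        with pytest.raises(ValueError):
            CohortConfig(n_participants=0)
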