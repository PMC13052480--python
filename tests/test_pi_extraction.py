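"""Peak/trough detection, rate validation and AC/DC/PI computation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from polarppg.pi_extraction import (
    aggregate_pi,
    compute_segment_pi,
    detect_peaks_troughs,
    validate_rate,
)
from polarppg.signal_io import CHANNEL_KEYS
from polarppg.synthetic import (
    BeatModel,
    ChannelModel,
    SyntheticParticipant,
    generate_recording,
)


def make_clean_participant(systolic_amp=0.01, noise_sd=0.0, wander_amp=0.0,
                           surface_offsets=(0.0, 0.0), hr=72.0, jitter=0.03):
    """Four-channel noise-free participant; co channels get the offsets."""
    beat = BeatModel(heart_rate_bpm=hr, systolic_amp=systolic_amp, hr_jitter_cv=jitter)
    channels = []
    for i, (wl, pol) in enumerate(CHANNEL_KEYS):
        channels.append(
            ChannelModel(
                wavelength_nm=wl,
                polarization=pol,
                baseline_dc=40000.0,
                surface_offset=surface_offsets[0] if pol == "co" else 0.0,
                noise_sd=noise_sd,
                wander_amp=wander_amp,
            )
        )
    return SyntheticParticipant(
        participant_id="T01", true_L=58.0, true_b=16.0,
        channels=tuple(channels), beat=beat,
    )


class TestDetection:
    def test_sinusoid_counts(self):
        t = np.arange(250) / 25.0
        x = np.sin(2 * np.pi * 1.2 * t)
        f = detect_peaks_troughs(x, 25.0)
        assert len(f.peak_indices) == 12
        assert len(f.trough_indices) == 12

    def test_constant_signal_yields_empty(self):
        f = detect_peaks_troughs(np.full(250, 7.0), 25.0)
        assert f.n_beats == 0 and len(f.peak_indices) == 0

    def test_beat_count_matches_generator(self):
        part = make_clean_participant()
        rec = generate_recording(part, duration_s=10.0, fs=25.0, seed=5)
        x = rec.channels[(655, "cross")]
        f = detect_peaks_troughs(x, 25.0)
        onsets = part.true_beat_onsets
        n_complete = np.sum(onsets[1:] <= 10.0)  # systoles with a full beat
        assert abs(f.n_beats - n_complete) <= 1

    def test_pairing_invariants(self):
        part = make_clean_participant()
        rec = generate_recording(part, duration_s=10.0, fs=25.0, seed=5)
        x = rec.channels[(940, "co")]
        f = detect_peaks_troughs(x, 25.0)
        for t_idx, p_idx in f.beat_pairs:
            assert t_idx < p_idx
            assert x[p_idx] > x[t_idx]


class TestRateValidation:
    def _features_from_rate(self, rate_bpm, duration=10.0, fs=25.0):
        t = np.arange(int(duration * fs)) / fs
        x = np.sin(2 * np.pi * rate_bpm / 60.0 * t)
        return detect_peaks_troughs(x, fs)

    def test_plausible_rate_valid(self):
        f = self._features_from_rate(72.0)
        _, valid, median = validate_rate(f)
        assert valid and median == pytest.approx(72.0, rel=0.06)

    def test_tachycardic_rate_flagged(self):
        # construct features implying ~110 bpm directly: the detector's
        # minimum-separation rule (one beat at the band maximum) cannot
        # itself resolve rates above the band, so validation is tested on
        # its own input contract
        fs = 100.0
        spacing = int(round(fs * 60.0 / 110.0))
        from polarppg.pi_extraction import PulseFeatureSet

        peaks = np.arange(10) * spacing + 20
        troughs = peaks - 10
        f = PulseFeatureSet(
            fs=fs,
            peak_indices=peaks,
            trough_indices=troughs,
            peak_values=np.ones(10),
            trough_values=np.zeros(10),
            beat_pairs=list(zip(troughs, peaks)),
        )
        _, valid, median = validate_rate(f)
        assert not valid and median > 100.0

    def test_spurious_double_peak_dropped(self):
        f = self._features_from_rate(72.0)
        # inject a duplicate peak 5 samples (300 bpm) after a real one
        t_idx, p_idx = f.beat_pairs[3]
        f.beat_pairs.insert(4, (t_idx, p_idx + 5))
        kept, valid, _ = validate_rate(f)
        assert (t_idx, p_idx + 5) not in kept.beat_pairs
        assert valid


class TestSegmentPI:
    def test_single_beat_formula(self):
        x = np.array([100.0, 101.0])
        f = detect_peaks_troughs(np.zeros(10), 25.0)  # empty scaffold
        f.beat_pairs = [(0, 1)]
        s = compute_segment_pi(x, f)
        assert s.per_beat_ac[0] == pytest.approx(1.0)
        assert s.per_beat_dc[0] == pytest.approx(100.0)
        assert s.segment_pi == pytest.approx(1.0, abs=1e-9)

    def test_identical_beats_zero_variance(self):
        x = np.tile([45900.0, 46400.0], 8)
        f = detect_peaks_troughs(np.zeros(10), 25.0)
        f.beat_pairs = [(2 * k, 2 * k + 1) for k in range(8)]
        s = compute_segment_pi(x, f)
        assert np.var(s.per_beat_pi) == 0.0

    def test_nonpositive_dc_rejected(self):
        x = np.array([-1.0, 5.0])
        f = detect_peaks_troughs(np.zeros(10), 25.0)
        f.beat_pairs = [(0, 1)]
        with pytest.raises(ValueError, match="DC"):
            compute_segment_pi(x, f)

    @given(scale=st.floats(0.1, 50.0))
    def test_scale_invariance(self, scale):
        """PI is unchanged when AC and DC scale together."""
        t = np.arange(250) / 25.0
        x = 1000.0 - 10.0 * np.sin(2 * np.pi * 1.2 * t)
        f1 = detect_peaks_troughs(x, 25.0)
        f2 = detect_peaks_troughs(scale * x, 25.0)
        s1 = compute_segment_pi(x, f1)
        s2 = compute_segment_pi(scale * x, f2)
        assert np.allclose(s1.per_beat_pi, s2.per_beat_pi, rtol=1e-9)

    @given(offset=st.floats(1.0, 5000.0))
    def test_additive_offset_lowers_pi(self, offset):
        """Adding nonpulsatile counts inflates DC only, so PI must drop —
        the co- vs cross-polarization mechanism."""
        t = np.arange(250) / 25.0
        x = 1000.0 - 10.0 * np.sin(2 * np.pi * 1.2 * t)
        s1 = compute_segment_pi(x, detect_peaks_troughs(x, 25.0))
        s2 = compute_segment_pi(x + offset, detect_peaks_troughs(x + offset, 25.0))
        assert np.all(s2.per_beat_pi < s1.per_beat_pi)


class TestAggregation:
    def _seg(self, pi, valid=True):
        z = np.array([pi])
        from polarppg.pi_extraction import SegmentPI

        return SegmentPI(z, z, z, pi, 1, valid)

    def test_mean_of_three(self):
        res = aggregate_pi([self._seg(1.0), self._seg(1.2), self._seg(1.1)])
        assert res.mean_pi == pytest.approx(1.1)

    def test_invalid_segment_skipped(self):
        res = aggregate_pi(
            [self._seg(1.0), self._seg(99.0, valid=False), self._seg(1.2)]
        )
        assert res.mean_pi == pytest.approx(1.1)
        assert res.n_invalid_segments == 1

    def test_all_invalid_marks_missing(self):
        res = aggregate_pi([self._seg(1.0, valid=False)])
        assert res.missing and np.isnan(res.mean_pi)

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            aggregate_pi([self._seg(1.0)] * 4)


class TestOracleEquivalence:
    def test_pipeline_matches_brute_force_on_clean_beats(self, run_config):
        """On dense noise-free synthetic beats the pipeline AC/DC agrees
        with a brute-force per-beat (max-min)/min scan within 2% relative."""
        from polarppg.pipeline import extract_channel_pi

        part = make_clean_participant(systolic_amp=0.01)
        rec = generate_recording(part, duration_s=60.0, fs=250.0, seed=9)
        key = (655, "cross")
        x = rec.channels[key]
        # independent brute-force oracle straight off the samples
        onsets = part.true_beat_onsets
        oracle = []
        for a, b in zip(onsets, onsets[1:]):
            if b > 60.0:
                break
            seg = x[int(a * 250) : int(b * 250)]
            oracle.append(100.0 * (seg.max() - seg.min()) / seg.min())
        oracle_pi = float(np.mean(oracle))
        res, _, _ = extract_channel_pi(x, 250.0, run_config, channel=key)
        assert res.mean_pi == pytest.approx(oracle_pi, rel=0.02)
        assert part.true_pi_by_channel[key] == pytest.approx(oracle_pi, rel=0.02)
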