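"""Synthetic PPG cohorts with analytically known ground truth.

The generator emulates the measurement this pipeline analyses: a wrist-worn
reflectance sensor recording four intensity channels (655/940 nm, co-/
cross-polarized) at 25 samples/s for two minutes per participant, plus 20
repeated colorimeter scans per participant for ITA skin-tone assessment.

Signal model, per channel (detector counts, non-inverted convention —
intensity dips at systole):

    I(t) = baseline_dc + surface_offset
           + melanin_atten * systolic_amp * baseline_dc * (1 - pulse(t))
           + wander_amp * sin(2*pi*wander_freq*t + phase) + noise

``pulse(t)`` is a peak-normalised per-beat template in [0, 1]: a Gaussian
systolic lobe plus a smaller delayed Gaussian dicrotic lobe, repeated at
lognormally jittered beat intervals.  Polarization is modelled
phenomenologically: co-polarized channels carry an additive nonpulsatile
``surface_offset`` (superficial surface reflection inflating DC) and a
pulsatile attenuation < 1, which is exactly the mechanism by which
cross-polarized detection raises the perfusion index.

Cohort generation inverts that model: given regression coefficients
(beta0..beta3) for PI on ITA, condition and their interaction, channel
parameters are solved so that each participant/condition's noise-free PI
equals the linear-model value plus a per-participant random offset.  The
noise-free per-beat ground truth PI, 100*(beat max - beat min)/(beat min)
evaluated on a densely sampled clean signal, is recorded for every channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .signal_io import CHANNEL_KEYS, PPGRecording
from .skin_tone import compute_ita

#: Dense sampling rate (Hz) for noise-free ground-truth evaluation.
DENSE_FS = 250.0

#: Default per-channel DC baselines (detector counts), echoing the signal
#: ranges of a 19-bit charge-integrating front end on light skin.
DEFAULT_BASELINES: Dict[Tuple[int, str], float] = {
    (655, "co"): 46000.0,
    (655, "cross"): 38500.0,
    (940, "co"): 45300.0,
    (940, "cross"): 30500.0,
}


@dataclass(frozen=True)
class BeatModel:
    """Pulse morphology and rhythm for one participant."""

    heart_rate_bpm: float = 72.0
    systolic_amp: float = 0.04
    dicrotic_amp: float = 0.35
    systolic_width_s: float = 0.12
    dicrotic_delay_s: float = 0.30
    hr_jitter_cv: float = 0.03

    def __post_init__(self) -> None:
        if not 30.0 < self.heart_rate_bpm < 220.0:
            raise ValueError("heart_rate_bpm must lie in (30, 220)")
        if not 0.0 <= self.dicrotic_amp < 1.0:
            raise ValueError("dicrotic_amp must lie in [0, 1)")
        if self.systolic_amp < 0.0:
            raise ValueError("systolic_amp must be >= 0")
        if self.hr_jitter_cv < 0.0:
            raise ValueError("hr_jitter_cv must be >= 0")

    @property
    def period_s(self) -> float:
        return 60.0 / self.heart_rate_bpm


@dataclass(frozen=True)
class ChannelModel:
    """Phenomenological optical channel: no radiative transfer, just the
    PI-level structure (additive surface reflection on co-polarized
    detection, multiplicative pulsatile attenuation, wander and noise)."""

    wavelength_nm: int
    polarization: str
    baseline_dc: float
    surface_offset: float = 0.0
    melanin_atten: float = 1.0
    noise_sd: float = 0.0
    wander_amp: float = 0.0
    wander_freq_hz: float = 0.25

    def __post_init__(self) -> None:
        if self.wavelength_nm not in (655, 940):
            raise ValueError("wavelength_nm must be 655 or 940")
        if self.polarization not in ("co", "cross"):
            raise ValueError("polarization must be 'co' or 'cross'")
        if self.baseline_dc <= 0.0:
            raise ValueError("baseline_dc must be positive")
        if self.surface_offset < 0.0:
            raise ValueError("surface_offset must be >= 0")
        if self.polarization == "cross" and self.surface_offset != 0.0:
            raise ValueError("cross-polarized channels have no surface offset")
        if not 0.0 < self.melanin_atten <= 1.0:
            raise ValueError("melanin_atten must lie in (0, 1]")

    @property
    def key(self) -> Tuple[int, str]:
        return (self.wavelength_nm, self.polarization)


@dataclass
class SyntheticParticipant:
    """One simulated participant: colour ground truth, four optical
    channels and a beat model.  ``true_pi_by_channel`` (mean noise-free
    per-beat PI, %) is filled in by :func:`generate_recording`."""

    participant_id: str
    true_L: float
    true_b: float
    channels: Tuple[ChannelModel, ...]
    beat: BeatModel
    true_ita_deg: float = field(default=None)  # type: ignore[assignment]
    true_pi_by_channel: Dict[Tuple[int, str], float] = field(default_factory=dict)
    true_pi_per_beat: Dict[Tuple[int, str], np.ndarray] = field(default_factory=dict)
    true_beat_onsets: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        ita = compute_ita(self.true_L, self.true_b)
        if self.true_ita_deg is None:
            self.true_ita_deg = ita
        elif abs(self.true_ita_deg - ita) > 1e-9:
            raise ValueError("true_ita_deg inconsistent with (true_L, true_b)")
        keys = sorted(ch.key for ch in self.channels)
        if keys != sorted(CHANNEL_KEYS):
            raise ValueError("exactly one channel per (wavelength, polarization) required")

    def channel(self, key: Tuple[int, str]) -> ChannelModel:
        for ch in self.channels:
            if ch.key == key:
                return ch
        raise KeyError(key)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated cohort.

    The PI structure follows the marginal model the analysis fits:
    PI = beta0 + beta1*ITA + beta2*[cross] + beta3*ITA*[cross] + u_i, with
    u_i ~ N(0, participant_sd) inducing within-participant correlation.
    Defaults mirror the eight-participant wrist study: ITA spanning
    -25..+50 deg, 120 s at 25 samples/s, a ~0.83% PI cross-polarized uplift
    that shrinks with lighter tone.
    """

    n_participants: int = 8
    ita_range_deg: Tuple[float, float] = (-25.0, 50.0)
    pi_intercept: float = 0.66
    pi_ita_slope: float = 0.006
    effect_cross: float = 0.83
    effect_interaction: float = -0.015
    participant_sd: float = 0.1
    duration_s: float = 120.0
    fs: float = 25.0
    seed: int = 0
    heart_rate_bpm: float = 72.0
    hr_jitter_cv: float = 0.03
    noise_sd: float = 2.0
    wander_amp: float = 8.0
    wander_freq_hz: float = 0.25

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.duration_s < 30.0:
            raise ValueError("duration_s must be >= 30 s")
        if self.fs < 20.0:
            raise ValueError("fs must be >= 20 samples/s")

    def betas(self) -> Tuple[float, float, float, float]:
        return (self.pi_intercept, self.pi_ita_slope,
                self.effect_cross, self.effect_interaction)


@dataclass
class CohortResult:
    """Everything :func:`generate_cohort` produces."""

    config: CohortConfig
    participants: List[SyntheticParticipant]
    recordings: Dict[str, PPGRecording]
    scans: Dict[str, pd.DataFrame]
    ground_truth: pd.DataFrame


# --------------------------------------------------------------------------
# Beat template machinery


def _beat_onsets(beat: BeatModel, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Systole onset times covering [0, duration], lognormal jittered."""
    period = beat.period_s
    n_max = int(np.ceil(duration_s / period)) + 4
    if beat.hr_jitter_cv > 0.0:
        sigma2 = math.log(1.0 + beat.hr_jitter_cv**2)
        mu = math.log(period) - sigma2 / 2.0
        intervals = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n_max)
    else:
        intervals = np.full(n_max, period)
    onsets = np.concatenate(([0.0], np.cumsum(intervals)))
    return onsets[onsets <= duration_s + period]


def _template_norm(beat: BeatModel) -> float:
    """Peak value of one un-normalised two-Gaussian beat template."""
    t = np.arange(-0.5, beat.dicrotic_delay_s + 0.5, 1e-4)
    g = np.exp(-(t**2) / (2 * beat.systolic_width_s**2))
    g += beat.dicrotic_amp * np.exp(
        -((t - beat.dicrotic_delay_s) ** 2) / (2 * beat.systolic_width_s**2)
    )
    return float(g.max())


def pulse_train(t: np.ndarray, onsets: np.ndarray, beat: BeatModel) -> np.ndarray:
    """Peak-normalised pulse waveform in [0, 1] on the time grid ``t``.

    Each beat contributes a systolic Gaussian centred on its onset plus a
    delayed dicrotic Gaussian; contributions are summed locally (lobes decay
    to numerical zero well within one beat period) and scaled by the single-
    template peak so the train's maximum is 1 up to negligible overlap.
    """
    sigma = beat.systolic_width_s
    tau = beat.dicrotic_delay_s
    span = tau + 6.0 * sigma
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    out = np.zeros_like(t)
    n = len(t)
    for onset in onsets:
        i0 = max(0, int((onset - 6.0 * sigma - t[0]) / dt))
        i1 = min(n, int((onset + span - t[0]) / dt) + 2)
        if i0 >= i1:
            continue
        tt = t[i0:i1] - onset
        out[i0:i1] += np.exp(-(tt**2) / (2 * sigma**2))
        out[i0:i1] += beat.dicrotic_amp * np.exp(-((tt - tau) ** 2) / (2 * sigma**2))
    out /= _template_norm(beat)
    return np.clip(out, 0.0, None)


def template_extrema(beat: BeatModel) -> Tuple[float, float]:
    """(max, min) of the normalised pulse over one steady-state beat.

    Evaluated densely on the middle beat of a three-beat train at the
    nominal period; used to solve channel amplitudes for target PIs.
    """
    period = beat.period_s
    onsets = np.array([0.0, period, 2 * period])
    t = np.arange(0.0, 3 * period, 1e-3)
    p = pulse_train(t, onsets, beat)
    mid = (t >= period) & (t < 2 * period)
    return float(p[mid].max()), float(p[mid].min())


def _clean_channel_signal(
    t: np.ndarray, pulse: np.ndarray, ch: ChannelModel, beat: BeatModel
) -> np.ndarray:
    amp = ch.melanin_atten * beat.systolic_amp * ch.baseline_dc
    return ch.baseline_dc + ch.surface_offset + amp * (1.0 - pulse)


# --------------------------------------------------------------------------
# Recording / scan / cohort generation


def generate_recording(
    participant: SyntheticParticipant,
    duration_s: float,
    fs: float,
    seed: int,
) -> PPGRecording:
    """Simulate one four-channel recording and record its ground truth.

    Side effects on ``participant``: ``true_pi_by_channel`` (mean noise-free
    per-beat PI per channel), ``true_pi_per_beat`` and ``true_beat_onsets``
    are (re)filled.  Identical arguments produce bit-identical output.
    """
    if fs < 10.0:
        raise ValueError("fs must be at least 10 samples/s (2x the 5 Hz band)")
    beat = participant.beat
    if duration_s < 2.0 * beat.period_s:
        raise ValueError("duration must cover at least two beats")
    for ch in participant.channels:
        if ch.baseline_dc <= 0.0:
            raise ValueError("baseline_dc must be positive")

    rng = np.random.default_rng(seed)
    onsets = _beat_onsets(beat, duration_s, rng)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    pulse = pulse_train(t, onsets, beat)

    dense_fs = max(DENSE_FS, 4.0 * fs)
    t_dense = np.arange(int(round(duration_s * dense_fs))) / dense_fs
    pulse_dense = pulse_train(t_dense, onsets, beat)

    # per-beat windows fully inside the record
    inside = onsets[onsets <= duration_s]
    windows = [
        (inside[k], inside[k + 1])
        for k in range(len(inside) - 1)
        if inside[k + 1] <= duration_s
    ]

    channels: Dict[Tuple[int, str], np.ndarray] = {}
    participant.true_beat_onsets = inside
    for key in CHANNEL_KEYS:
        ch = participant.channel(key)
        clean_dense = _clean_channel_signal(t_dense, pulse_dense, ch, beat)
        pis = []
        for t0, t1 in windows:
            i0, i1 = int(t0 * dense_fs), int(t1 * dense_fs)
            seg = clean_dense[i0:i1]
            lo, hi = seg.min(), seg.max()
            pis.append(100.0 * (hi - lo) / lo)
        per_beat = np.asarray(pis)
        participant.true_pi_per_beat[key] = per_beat
        participant.true_pi_by_channel[key] = (
            float(per_beat.mean()) if len(per_beat) else 0.0
        )

        x = _clean_channel_signal(t, pulse, ch, beat)
        if ch.wander_amp > 0.0:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            x = x + ch.wander_amp * np.sin(2.0 * np.pi * ch.wander_freq_hz * t + phase)
        else:
            rng.uniform(0.0, 2.0 * np.pi)  # keep the draw order fixed
        if ch.noise_sd > 0.0:
            x = x + rng.normal(0.0, ch.noise_sd, size=n)
        else:
            rng.normal(0.0, 1.0, size=n)
        channels[key] = x

    return PPGRecording(
        participant_id=participant.participant_id,
        fs=float(fs),
        duration_s=float(duration_s),
        channels=channels,
    )


def generate_colorimeter_scans(
    true_L: float,
    true_b: float,
    n_scans: int = 20,
    noise_sd_L: float = 0.2,
    noise_sd_b: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated (L*, b*) colorimeter scans with independent Gaussian noise."""
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if true_b == 0.0:
        raise ValueError("true_b must be nonzero (ITA undefined at b* = 0)")
    if noise_sd_L < 0.0 or noise_sd_b < 0.0:
        raise ValueError("noise SDs must be >= 0")
    rng = np.random.default_rng(seed)
    L = true_L + rng.normal(0.0, noise_sd_L, size=n_scans) if noise_sd_L else np.full(n_scans, true_L)
    if noise_sd_L == 0.0:
        rng.normal(0.0, 1.0, size=n_scans)
    b = true_b + rng.normal(0.0, noise_sd_b, size=n_scans) if noise_sd_b else np.full(n_scans, true_b)
    return pd.DataFrame({"scan_idx": np.arange(n_scans), "L_star": L, "b_star": b})


def design_participant(
    participant_id: str,
    ita_deg: float,
    pi_targets: Dict[Tuple[int, str], float],
    b_star: float = 16.0,
    beat: Optional[BeatModel] = None,
    baselines: Optional[Dict[Tuple[int, str], float]] = None,
    surface_offset_frac: float = 0.08,
    noise_sd: float = 2.0,
    wander_amp: float = 8.0,
    wander_freq_hz: float = 0.25,
) -> SyntheticParticipant:
    """Build a participant whose noise-free channel PIs hit ``pi_targets``.

    The CIELAB point is placed at the requested ITA along fixed b*; the
    melanin attenuation of each channel is solved from the target PI given
    the beat template's pulse excursion, the channel baseline and the
    co-polarized surface offset.
    """
    beat = beat or BeatModel()
    baselines = baselines or DEFAULT_BASELINES
    L = 50.0 + b_star * math.tan(math.radians(ita_deg))
    if not 0.0 <= L <= 100.0:
        raise ValueError(f"ITA {ita_deg} deg maps outside the CIELAB L* range")
    p_max, p_min = template_extrema(beat)
    excursion = p_max - p_min
    channels = []
    for key in CHANNEL_KEYS:
        wavelength, polarization = key
        target = pi_targets[key]
        if target <= 0.0:
            raise ValueError(
                f"nonpositive target PI {target}% for {participant_id}/{key}"
            )
        B = baselines[key]
        S = surface_offset_frac * B if polarization == "co" else 0.0
        frac = target / 100.0
        amp = frac * (B + S) / (excursion - frac * (1.0 - p_max))
        melanin = amp / (beat.systolic_amp * B)
        if not 0.0 < melanin <= 1.0:
            raise ValueError(
                f"target PI {target}% for {participant_id}/{key} needs pulsatile "
                f"attenuation {melanin:.3f} outside (0, 1]; raise systolic_amp"
            )
        channels.append(
            ChannelModel(
                wavelength_nm=wavelength,
                polarization=polarization,
                baseline_dc=B,
                surface_offset=S,
                melanin_atten=melanin,
                noise_sd=noise_sd,
                wander_amp=wander_amp,
                wander_freq_hz=wander_freq_hz,
            )
        )
    return SyntheticParticipant(
        participant_id=participant_id,
        true_L=L,
        true_b=b_star,
        channels=tuple(channels),
        beat=beat,
    )


def generate_cohort(config: CohortConfig) -> CohortResult:
    """Simulate a full cohort: recordings, colorimeter scans, ground truth.

    True ITA values are spread evenly (lightest participant first) over
    ``ita_range_deg``; per-participant/condition noise-free PI follows the
    configured linear model plus the Gaussian participant offset.  Effect
    sizes that would demand a nonpositive PI or an out-of-range pulsatile
    amplitude are rejected with a diagnostic.
    """
    master = np.random.default_rng(config.seed)
    b0, b1, b2, b3 = config.betas()
    n = config.n_participants
    lo, hi = config.ita_range_deg
    itas = np.linspace(hi, lo, n) if n > 1 else np.array([(lo + hi) / 2.0])
    offsets = master.normal(0.0, config.participant_sd, size=n)
    rec_seeds = master.integers(0, 2**31 - 1, size=n)
    scan_seeds = master.integers(0, 2**31 - 1, size=n)

    beat = BeatModel(
        heart_rate_bpm=config.heart_rate_bpm, hr_jitter_cv=config.hr_jitter_cv
    )
    participants: List[SyntheticParticipant] = []
    recordings: Dict[str, PPGRecording] = {}
    scans: Dict[str, pd.DataFrame] = {}
    rows = []
    for i in range(n):
        pid = f"S{i + 1:02d}"
        ita = float(itas[i])
        pi_co = b0 + b1 * ita + offsets[i]
        pi_cross = pi_co + b2 + b3 * ita
        if pi_co <= 0.0 or pi_cross <= 0.0:
            raise ValueError(
                f"configured effects give nonpositive PI for {pid} "
                f"(ITA {ita:.1f} deg): co={pi_co:.3f}%, cross={pi_cross:.3f}%"
            )
        targets = {
            key: (pi_cross if key[1] == "cross" else pi_co) for key in CHANNEL_KEYS
        }
        participant = design_participant(
            pid,
            ita,
            targets,
            beat=beat,
            noise_sd=config.noise_sd,
            wander_amp=config.wander_amp,
            wander_freq_hz=config.wander_freq_hz,
        )
        recordings[pid] = generate_recording(
            participant, config.duration_s, config.fs, seed=int(rec_seeds[i])
        )
        scans[pid] = generate_colorimeter_scans(
            participant.true_L, participant.true_b, seed=int(scan_seeds[i])
        )
        participants.append(participant)
        for key in CHANNEL_KEYS:
            ch = participant.channel(key)
            rows.append(
                {
                    "participant_id": pid,
                    "true_ita_deg": ita,
                    "true_L": participant.true_L,
                    "true_b": participant.true_b,
                    "wavelength_nm": key[0],
                    "condition": key[1],
                    "target_pi": targets[key],
                    "true_pi": participant.true_pi_by_channel[key],
                    "baseline_dc": ch.baseline_dc,
                    "surface_offset": ch.surface_offset,
                    "melanin_atten": ch.melanin_atten,
                    "systolic_amp": beat.systolic_amp,
                    "participant_offset": offsets[i],
                }
            )
    ground_truth = pd.DataFrame(rows)
    return CohortResult(
        config=config,
        participants=participants,
        recordings=recordings,
        scans=scans,
        ground_truth=ground_truth,
    )
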