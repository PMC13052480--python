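"""Per-beat perfusion-index extraction from filtered PPG segments.

Detected light intensity is analysed *without inversion*: in reflectance
PPG, systole adds arterial blood and absorption, so the intensity dips at
systole (local minima = troughs) and recovers through diastole (local
maxima = peaks).  Per beat,

    DC = preceding trough value,  AC = peak - preceding trough,
    PI = 100 * AC / DC   [%]

Within a segment the per-beat PI values are averaged (or a median taken,
see ``mode``), and the participant/channel perfusion index is the mean over
the three segment values P1, P2, P3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

#: Hard physiological band (bpm); inter-peak intervals outside it are
#: treated as detection artifacts and removed, independent of the narrower
#: validity band used to flag whole segments.
HARD_RATE_BAND_BPM: Tuple[float, float] = (40.0, 180.0)

#: Peak/trough prominence threshold as a fraction of the segment IQR.
PROMINENCE_IQR_FRACTION = 0.25


@dataclass
class PulseFeatureSet:
    """Peaks, troughs and paired beats detected in one segment."""

    fs: float
    peak_indices: np.ndarray
    trough_indices: np.ndarray
    peak_values: np.ndarray
    trough_values: np.ndarray
    beat_pairs: List[Tuple[int, int]]  # (preceding trough idx, peak idx)

    @property
    def n_beats(self) -> int:
        return len(self.beat_pairs)

    def implied_rates_bpm(self) -> np.ndarray:
        """Heart rate implied by each interval between consecutive paired peaks."""
        peaks = np.array([p for _, p in self.beat_pairs])
        if len(peaks) < 2:
            return np.empty(0)
        return 60.0 * self.fs / np.diff(peaks)


@dataclass
class SegmentPI:
    """Per-beat AC/DC/PI values and their within-segment summary."""

    per_beat_ac: np.ndarray
    per_beat_dc: np.ndarray
    per_beat_pi: np.ndarray
    segment_pi: float
    n_beats: int
    valid: bool
    median_rate_bpm: float = float("nan")
    label: str = ""


@dataclass
class PIResult:
    """Segment PIs and their mean for one participant/channel."""

    participant_id: str
    channel: Tuple[int, str]
    segment_pis: Tuple[float, ...]
    mean_pi: float
    n_valid_segments: int
    n_invalid_segments: int

    @property
    def missing(self) -> bool:
        return self.n_valid_segments == 0


def _empty_features(fs: float) -> PulseFeatureSet:
    z = np.empty(0, dtype=int)
    return PulseFeatureSet(
        fs=fs,
        peak_indices=z,
        trough_indices=z.copy(),
        peak_values=np.empty(0),
        trough_values=np.empty(0),
        beat_pairs=[],
    )


def detect_peaks_troughs(
    x,
    fs: float,
    hr_band_bpm: Sequence[float] = (60.0, 100.0),
) -> PulseFeatureSet:
    """Detect diastolic peaks and systolic troughs in a filtered segment.

    Local extrema must have prominence of at least a quarter of the segment
    interquartile range (a unit-free threshold that behaves identically
    across channels and skin tones) and be separated by at least one beat at
    the band's upper heart rate.  Each peak is paired with the nearest
    preceding trough; leading peaks without one are dropped.  A flat segment
    (zero IQR) yields an empty feature set rather than an error.
    """
    x = np.asarray(x, dtype=float)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0.0:
        return _empty_features(fs)
    prominence = PROMINENCE_IQR_FRACTION * iqr
    distance = max(1, int(round(fs * 60.0 / hr_band_bpm[1])))
    peaks, _ = find_peaks(x, prominence=prominence, distance=distance)
    troughs, _ = find_peaks(-x, prominence=prominence, distance=distance)
    pairs: List[Tuple[int, int]] = []
    for p in peaks:
        prior = troughs[troughs < p]
        if len(prior) == 0:
            continue
        t = int(prior[-1])
        if x[p] > x[t]:
            pairs.append((t, int(p)))
    return PulseFeatureSet(
        fs=fs,
        peak_indices=peaks,
        trough_indices=troughs,
        peak_values=x[peaks],
        trough_values=x[troughs],
        beat_pairs=pairs,
    )


def validate_rate(
    features: PulseFeatureSet,
    hr_band_bpm: Sequence[float] = (60.0, 100.0),
    hard_band_bpm: Sequence[float] = HARD_RATE_BAND_BPM,
) -> Tuple[PulseFeatureSet, bool, float]:
    """Drop artifact beats and flag whether the segment rate is plausible.

    Beat pairs whose interval from the previous retained peak implies a rate
    outside ``hard_band_bpm`` are removed (e.g. a spurious double peak
    implying 300 bpm).  The segment is valid iff the median implied rate of
    the survivors lies inside ``hr_band_bpm``.  Returns
    ``(features', valid, median_rate_bpm)``.
    """
    pairs = list(features.beat_pairs)
    if not pairs:
        return features, False, float("nan")
    kept = [pairs[0]]
    rates = []
    for t, p in pairs[1:]:
        rate = 60.0 * features.fs / (p - kept[-1][1])
        if hard_band_bpm[0] <= rate <= hard_band_bpm[1]:
            kept.append((t, p))
            rates.append(rate)
    filtered = PulseFeatureSet(
        fs=features.fs,
        peak_indices=features.peak_indices,
        trough_indices=features.trough_indices,
        peak_values=features.peak_values,
        trough_values=features.trough_values,
        beat_pairs=kept,
    )
    if not rates:
        return filtered, False, float("nan")
    median_rate = float(np.median(rates))
    valid = hr_band_bpm[0] <= median_rate <= hr_band_bpm[1]
    return filtered, valid, median_rate


def compute_segment_pi(
    x,
    features: PulseFeatureSet,
    valid: bool = True,
    mode: str = "per_beat_mean",
    label: str = "",
    median_rate_bpm: float = float("nan"),
) -> SegmentPI:
    """Per-beat AC/DC/PI and the segment summary.

    ``mode`` selects the within-segment summary: mean of per-beat PI
    (default, robust to single-beat artifacts when averaged over ~10 beats)
    or the median beat.  Detector counts cannot be nonpositive, so any
    DC <= 0 is rejected.
    """
    if mode not in ("per_beat_mean", "median_beat"):
        raise ValueError("mode must be per_beat_mean|median_beat")
    x = np.asarray(x, dtype=float)
    if features.n_beats == 0:
        z = np.empty(0)
        return SegmentPI(z, z.copy(), z.copy(), float("nan"), 0, False,
                         median_rate_bpm, label)
    troughs = np.array([t for t, _ in features.beat_pairs])
    peaks = np.array([p for _, p in features.beat_pairs])
    dc = x[troughs]
    if np.any(dc <= 0.0):
        raise ValueError("nonpositive trough (DC) value: counts must be > 0")
    ac = x[peaks] - dc
    pi = 100.0 * ac / dc
    summary = float(np.mean(pi)) if mode == "per_beat_mean" else float(np.median(pi))
    return SegmentPI(
        per_beat_ac=ac,
        per_beat_dc=dc,
        per_beat_pi=pi,
        segment_pi=summary,
        n_beats=len(pi),
        valid=valid and len(pi) > 0,
        median_rate_bpm=median_rate_bpm,
        label=label,
    )


def aggregate_pi(
    segment_pis: Sequence[SegmentPI],
    participant_id: str = "",
    channel: Tuple[int, str] = (0, ""),
) -> PIResult:
    """Mean PI over the valid segments (P1, P2, P3).

    All-invalid input yields a missing marker (``mean_pi`` NaN,
    ``n_valid_segments`` 0) so the participant/channel can be excluded
    downstream with a logged reason rather than silently averaged.
    """
    if not 1 <= len(segment_pis) <= 3:
        raise ValueError("expected between 1 and 3 segment PI values")
    vals = [s.segment_pi for s in segment_pis if s.valid]
    return PIResult(
        participant_id=participant_id,
        channel=channel,
        segment_pis=tuple(s.segment_pi for s in segment_pis),
        mean_pi=float(np.mean(vals)) if vals else float("nan"),
        n_valid_segments=len(vals),
        n_invalid_segments=len(segment_pis) - len(vals),
    )
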