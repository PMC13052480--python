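"""Reading and writing PPG recordings, colorimeter scans and result tables.

File dialects
-------------
Recording CSV: header ``time_s,ch655_co,ch655_cross,ch940_co,ch940_cross``,
one row per sample, with a YAML sidecar (same path, ``.yaml`` suffix)
carrying ``participant_id``, ``fs`` and ``duration_s``.  Intensities stay in
native detector counts throughout: the perfusion index is a ratio of AC to
DC and both must share a scale, so no normalisation happens at I/O time.

Scan CSV: header ``scan_idx,L_star,b_star``.

Missing-sample policy: runs of at most 3 NaN samples are linearly
interpolated on read; longer runs are interpolated too (so filtering stays
finite) but the affected spans are recorded in ``bad_masks`` and invalidate
any analysis window that touches them.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

#: Canonical channel order: (wavelength_nm, polarization).
CHANNEL_KEYS: Tuple[Tuple[int, str], ...] = (
    (655, "co"),
    (655, "cross"),
    (940, "co"),
    (940, "cross"),
)

#: Maximum NaN run length that is silently repaired by interpolation.
MAX_INTERP_RUN = 3


def channel_column(key: Tuple[int, str]) -> str:
    """CSV column name for a channel key, e.g. ``(655, 'co') -> 'ch655_co'``."""
    wavelength, polarization = key
    return f"ch{wavelength}_{polarization}"


class FormatError(ValueError):
    """Raised when an input file does not match the declared dialect."""


@dataclass
class PPGRecording:
    """Multi-channel raw intensity time series for one participant.

    ``channels`` maps ``(wavelength_nm, polarization)`` to a 1-D float array
    of detector counts.  ``bad_masks`` (same keys, boolean arrays) marks
    samples that were repaired from NaN runs longer than
    :data:`MAX_INTERP_RUN` and must not contribute to any analysis window.
    """

    participant_id: str
    fs: float
    duration_s: float
    channels: Dict[Tuple[int, str], np.ndarray]
    bad_masks: Dict[Tuple[int, str], np.ndarray] = field(default_factory=dict)
    n_interpolated: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n_expected = int(round(self.fs * self.duration_s))
        lengths = {len(x) for x in self.channels.values()}
        if len(lengths) != 1:
            raise FormatError(f"channel lengths differ: {sorted(lengths)}")
        (n,) = lengths
        if n != n_expected:
            raise FormatError(
                f"length {n} inconsistent with fs*duration = {n_expected}"
            )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def time(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return np.arange(self.n_samples) / self.fs


def _interpolate_nans(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray, int]:
    """Fill NaN runs by linear interpolation.

    Returns ``(filled, bad_mask, n_interpolated)`` where ``bad_mask`` marks
    samples belonging to runs longer than :data:`MAX_INTERP_RUN`.
    """
    x = np.asarray(x, dtype=float).copy()
    isnan = ~np.isfinite(x)
    bad = np.zeros_like(isnan)
    if not isnan.any():
        return x, bad, 0
    if isnan.all():
        raise FormatError("channel contains no finite samples")
    idx = np.arange(len(x))
    x[isnan] = np.interp(idx[isnan], idx[~isnan], x[~isnan])
    # locate runs to apply the length policy
    edges = np.flatnonzero(np.diff(np.concatenate(([0], isnan.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start > MAX_INTERP_RUN:
            bad[start:stop] = True
    return x, bad, int(isnan.sum())


def read_recording(path) -> PPGRecording:
    """Read a recording CSV plus its YAML sidecar into a :class:`PPGRecording`."""
    path = Path(path)
    sidecar = path.with_suffix(".yaml")
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError("missing column 'time_s'")
    channels: Dict[Tuple[int, str], np.ndarray] = {}
    bad_masks: Dict[Tuple[int, str], np.ndarray] = {}
    n_interp = 0
    for key in CHANNEL_KEYS:
        col = channel_column(key)
        if col not in df.columns:
            raise FormatError(f"missing channel column '{col}'")
        filled, bad, k = _interpolate_nans(df[col].to_numpy(dtype=float))
        channels[key] = filled
        if bad.any():
            bad_masks[key] = bad
        n_interp += k
    return PPGRecording(
        participant_id=str(meta["participant_id"]),
        fs=float(meta["fs"]),
        duration_s=float(meta["duration_s"]),
        channels=channels,
        bad_masks=bad_masks,
        n_interpolated=n_interp,
    )


def write_recording(recording: PPGRecording, path) -> Path:
    """Write a recording and its sidecar; returns the CSV path."""
    path = Path(path)
    data = {"time_s": recording.time()}
    for key in CHANNEL_KEYS:
        data[channel_column(key)] = recording.channels[key]
    pd.DataFrame(data).to_csv(path, index=False)
    sidecar = path.with_suffix(".yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {
                "participant_id": recording.participant_id,
                "fs": recording.fs,
                "duration_s": recording.duration_s,
            },
            sort_keys=True,
        )
    )
    return path


def read_scans(path) -> pd.DataFrame:
    """Read a colorimeter scan CSV (``scan_idx,L_star,b_star``)."""
    df = pd.read_csv(path)
    for col in ("scan_idx", "L_star", "b_star"):
        if col not in df.columns:
            raise FormatError(f"missing scan column '{col}'")
    return df


def write_scans(scans: pd.DataFrame, path) -> Path:
    path = Path(path)
    scans.to_csv(path, index=False)
    return path


# --------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Analysis-stage parameters with the pipeline defaults.

    cutoff_hz
        Low-pass -3 dB cutoff (Hz); the cardiac pulse lives near 1-2 Hz.
    fs_param_candidates
        Candidate values for the filter's assumed-sampling-rate parameter
        swept by :func:`polarppg.preprocessing.select_fs_parameter`.
    window_s, n_segments
        Segmentation: three 10-s windows by default.
    hr_band_bpm
        Plausible adult resting heart-rate band used to validate beats.
    ita_cutoffs_deg
        Skin-tone category cutoffs (brown/medium, medium/light).
    alpha
        Significance level for the regression stage.
    working_correlation
        GEE working correlation: ``exchangeable`` or ``independence``.
    segment_pi_mode
        ``per_beat_mean`` (default) or ``median_beat`` within-segment summary.
    """

    cutoff_hz: float = 5.0
    fs_param_candidates: Tuple[int, ...] = tuple(range(20, 51))
    window_s: float = 10.0
    n_segments: int = 3
    hr_band_bpm: Tuple[float, float] = (60.0, 100.0)
    ita_cutoffs_deg: Tuple[float, float] = (-5.0, 23.0)
    alpha: float = 0.05
    working_correlation: str = "exchangeable"
    segment_pi_mode: str = "per_beat_mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs_param_candidates:
            raise ValueError("fs_param_candidates must be non-empty")
        if not self.cutoff_hz < min(self.fs_param_candidates) / 2:
            raise ValueError("cutoff_hz must be below half the smallest fs candidate")
        if not self.ita_cutoffs_deg[0] < self.ita_cutoffs_deg[1]:
            raise ValueError("ita_cutoffs_deg must be strictly increasing")
        if self.working_correlation not in ("independence", "exchangeable"):
            raise ValueError("working_correlation must be independence|exchangeable")
        if self.segment_pi_mode not in ("per_beat_mean", "median_beat"):
            raise ValueError("segment_pi_mode must be per_beat_mean|median_beat")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fs_param_candidates"] = list(self.fs_param_candidates)
        d["hr_band_bpm"] = list(self.hr_band_bpm)
        d["ita_cutoffs_deg"] = list(self.ita_cutoffs_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("fs_param_candidates", "hr_band_bpm", "ita_cutoffs_deg"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def config_hash(self) -> str:
        """Stable sha256 of the canonical JSON form, for provenance logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# --------------------------------------------------------------------------
# Results and logging


def format_coefficient_table(table: pd.DataFrame) -> pd.DataFrame:
    """Render a numeric coefficient table with the report formatting.

    Estimate and SE at 5 dp, CI bounds at 3 dp, Wald at 2 dp, p at 4 dp
    (scientific below 1e-4) with significance stars at 0.05 / 0.01 / 0.001.
    """
    def stars(p: float) -> str:
        return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""

    def fmt_p(p: float) -> str:
        return f"{p:.1e}" if p < 1e-4 else f"{p:.4f}"

    out = pd.DataFrame(
        {
            "Coefficients": table["name"],
            "Estimate": [f"{v:.5f}" for v in table["estimate"]],
            "Standard error": [f"{v:.5f}" for v in table["se"]],
            "95% CI": [
                f"{lo:.3f}, {hi:.3f}"
                for lo, hi in zip(table["ci_lower"], table["ci_upper"])
            ],
            "Wald": [f"{v:.2f}" for v in table["wald"]],
            "Pr(>|W|)": [fmt_p(p) + stars(p) for p in table["p"]],
        }
    )
    return out


def write_results(cohort_table: pd.DataFrame, gee_fits, outdir) -> List[Path]:
    """Write the long-format PI table and one coefficient table per wavelength.

    ``gee_fits`` is a mapping wavelength -> GEEFit (may be empty: then only
    the PI table is written and a warning is logged).
    Returns the list of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    pi_path = outdir / "pi_long.csv"
    cohort_table.to_csv(pi_path, index=False)
    written.append(pi_path)
    if not gee_fits:
        warnings.warn("no GEE fits supplied; writing PI table only")
        return written
    for wavelength, fit in sorted(gee_fits.items()):
        path = outdir / f"gee_{wavelength}.csv"
        format_coefficient_table(fit.to_frame()).to_csv(path, index=False)
        written.append(path)
    return written


class JsonlLogger:
    """Append-only JSON-lines structured log for pipeline stages."""

    def __init__(self, path: Optional[Path] = None):
        self.path = Path(path) if path is not None else None
        self.records: List[dict] = []

    def log(self, stage: str, **fields) -> None:
        rec = {"stage": stage, **fields}
        self.records.append(rec)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")
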