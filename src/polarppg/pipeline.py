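"""End-to-end orchestration: simulate/load -> filter -> segment -> PI ->
ITA -> per-wavelength GEE, under one configuration and one seed."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import pi_extraction, preprocessing, skin_tone
from .gee_stats import GEEFit, build_design, fit_gee, wald_table
from .signal_io import (
    CHANNEL_KEYS,
    JsonlLogger,
    PPGRecording,
    RunConfig,
    read_recording,
    read_scans,
    write_recording,
    write_results,
    write_scans,
)
from .synthetic import CohortConfig, generate_cohort

#: Outlier rule: participant mean PI above Q3 + 3*IQR of the cohort.
OUTLIER_IQR_MULTIPLIER = 3.0


@dataclass
class RunManifest:
    """Provenance record: every input participant is accounted for either
    under ``analyzed`` or in ``exclusions`` with a reason."""

    config_hash: str
    seed: int
    analyzed: List[str] = field(default_factory=list)
    exclusions: List[Dict[str, str]] = field(default_factory=list)
    stage_counts: Dict[str, int] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)
    failed_stage: Optional[str] = None

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True, default=str))
        return path


def extract_channel_pi(
    x: np.ndarray,
    fs: float,
    config: RunConfig,
    participant_id: str = "",
    channel: Tuple[int, str] = (0, ""),
    bad_mask: Optional[np.ndarray] = None,
):
    """Run one raw channel through filter selection, segmentation and PI
    extraction.  Returns ``(PIResult, segment PIs, FsSelection)``."""
    selection = preprocessing.select_fs_parameter(
        x, fs, config.fs_param_candidates, cutoff_hz=config.cutoff_hz
    )
    spec = preprocessing.design_lowpass(config.cutoff_hz, selection.fs_used)
    filtered = preprocessing.apply_zero_phase(x, spec)
    segments = preprocessing.segment(
        filtered, fs, config.window_s, config.n_segments, bad_mask=bad_mask
    )
    seg_pis = []
    for seg in segments:
        features = pi_extraction.detect_peaks_troughs(
            seg.samples, fs, config.hr_band_bpm
        )
        features, valid, median_rate = pi_extraction.validate_rate(
            features, config.hr_band_bpm
        )
        seg_pis.append(
            pi_extraction.compute_segment_pi(
                seg.samples,
                features,
                valid=valid,
                mode=config.segment_pi_mode,
                label=seg.label,
                median_rate_bpm=median_rate,
            )
        )
    if not seg_pis:
        raise ValueError("no valid analysis windows in recording")
    result = pi_extraction.aggregate_pi(seg_pis, participant_id, channel)
    return result, seg_pis, selection


def extract_recording(recording: PPGRecording, config: RunConfig) -> pd.DataFrame:
    """Per-segment PI rows for all four channels of one recording."""
    rows = []
    for key in CHANNEL_KEYS:
        result, seg_pis, selection = extract_channel_pi(
            recording.channels[key],
            recording.fs,
            config,
            participant_id=recording.participant_id,
            channel=key,
            bad_mask=recording.bad_masks.get(key),
        )
        for seg in seg_pis:
            rows.append(
                {
                    "participant_id": recording.participant_id,
                    "wavelength_nm": key[0],
                    "condition": key[1],
                    "segment": seg.label,
                    "pi": seg.segment_pi,
                    "n_beats": seg.n_beats,
                    "segment_valid": seg.valid,
                    "median_rate_bpm": seg.median_rate_bpm,
                    "fs_param_used": selection.fs_used,
                    "quality_index": selection.quality_index,
                    "low_quality": selection.low_quality,
                }
            )
    return pd.DataFrame(rows)


def exclude_outliers(
    participant_pi: pd.DataFrame,
    enabled: bool = True,
    iqr_multiplier: float = OUTLIER_IQR_MULTIPLIER,
) -> Tuple[pd.DataFrame, List[Dict[str, str]]]:
    """Flag participants whose cohort-relative mean PI is extreme.

    ``participant_pi`` needs columns ``participant_id`` and ``pi``.  The
    rule — mean PI above Q3 + ``iqr_multiplier``*IQR of the per-participant
    means — is an
    algorithmic stand-in for the judgment call of dropping a participant
    whose perfusion was elevated by recent exercise; disable it with
    ``enabled=False``.  Excluding more than half the cohort aborts.
    """
    if participant_pi["participant_id"].nunique() < 3:
        raise ValueError("outlier rule needs at least 3 participants")
    ledger: List[Dict[str, str]] = []
    if not enabled:
        return participant_pi, ledger
    means = participant_pi.groupby("participant_id")["pi"].mean()
    q1, q3 = means.quantile([0.25, 0.75])
    threshold = q3 + iqr_multiplier * (q3 - q1)
    outliers = means[means > threshold]
    if len(outliers) > 0.5 * len(means):
        raise RuntimeError(
            f"outlier rule would exclude {len(outliers)}/{len(means)} participants; "
            "aborting — check the cohort or disable exclusion"
        )
    for pid, value in outliers.items():
        ledger.append(
            {
                "participant_id": str(pid),
                "reason": (
                    f"mean PI {value:.3f}% above cohort Q3+3*IQR threshold "
                    f"{threshold:.3f}%"
                ),
            }
        )
    keep = ~participant_pi["participant_id"].isin(outliers.index)
    return participant_pi[keep].reset_index(drop=True), ledger


def load_input_dir(input_dir) -> Tuple[Dict[str, PPGRecording], Dict[str, pd.DataFrame]]:
    """Read recordings (``<pid>.csv`` + sidecar) and scans (``<pid>_scans.csv``)."""
    input_dir = Path(input_dir)
    recordings: Dict[str, PPGRecording] = {}
    scans: Dict[str, pd.DataFrame] = {}
    for csv in sorted(input_dir.glob("*.csv")):
        if csv.stem.endswith("_scans") or csv.stem == "ground_truth":
            continue
        rec = read_recording(csv)
        recordings[rec.participant_id] = rec
        scan_path = input_dir / f"{csv.stem}_scans.csv"
        if scan_path.exists():
            scans[rec.participant_id] = read_scans(scan_path)
    if not recordings:
        raise FileNotFoundError(f"no recordings found in {input_dir}")
    return recordings, scans


def simulate_to_dir(config: CohortConfig, out_dir) -> Path:
    """Materialise a synthetic cohort as CSV files (CLI ``simulate``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    for pid, rec in cohort.recordings.items():
        write_recording(rec, out_dir / f"{pid}.csv")
        write_scans(cohort.scans[pid], out_dir / f"{pid}_scans.csv")
    cohort.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return out_dir


def analyze_cohort(
    recordings: Dict[str, PPGRecording],
    scans: Dict[str, pd.DataFrame],
    run_config: RunConfig,
    exclusion: bool = True,
) -> Tuple[pd.DataFrame, Dict[int, GEEFit], List[Dict[str, str]]]:
    """In-memory analysis: extraction -> ITA -> exclusion -> per-wavelength GEE.

    Returns ``(cohort_table, fits, exclusion_ledger)`` without touching disk.
    """
    pi_long = pd.concat(
        [extract_recording(recordings[pid], run_config) for pid in sorted(recordings)],
        ignore_index=True,
    )
    ita_rows = [
        {
            "participant_id": pid,
            "ita_deg": skin_tone.aggregate_scans(
                scans[pid], run_config.ita_cutoffs_deg
            ).mean_ita_deg,
        }
        for pid in sorted(recordings)
        if pid in scans
    ]
    valid_pi = pi_long[pi_long["segment_valid"]].copy()
    valid_pi, ledger = exclude_outliers(valid_pi, enabled=exclusion)
    table = valid_pi.merge(pd.DataFrame(ita_rows), on="participant_id")
    cohort_table = table[
        ["participant_id", "wavelength_nm", "condition", "segment", "pi", "ita_deg"]
    ].reset_index(drop=True)
    fits = {
        int(wl): fit_gee(*build_design(cohort_table, wl), run_config.working_correlation)
        for wl in sorted(cohort_table["wavelength_nm"].unique())
    }
    return cohort_table, fits, ledger


def run_all(
    run_config: RunConfig,
    cohort_config: Optional[CohortConfig] = None,
    input_dir=None,
    out_dir="results",
    exclusion: bool = True,
) -> RunManifest:
    """Execute the whole pipeline and write result files + manifest.

    Exactly one of ``cohort_config`` (simulate) or ``input_dir`` (load real
    CSVs) must be given.  Deterministic under a fixed configuration/seed.
    Writes ``pi_long.csv``, ``ita_summary.csv``, ``gee_<wavelength>.csv``,
    ``manifest.json`` and a JSON-lines log under ``out_dir``.
    """
    if (cohort_config is None) == (input_dir is None):
        raise ValueError("provide exactly one of cohort_config or input_dir")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger = JsonlLogger(out_dir / "run.log.jsonl")
    manifest = RunManifest(config_hash=run_config.config_hash(), seed=run_config.seed)
    stage = "simulate"
    try:
        if cohort_config is not None:
            cohort = generate_cohort(cohort_config)
            recordings, scans = cohort.recordings, cohort.scans
            logger.log(stage, n_participants=len(recordings))
        else:
            recordings, scans = load_input_dir(input_dir)
            logger.log("load", n_participants=len(recordings))

        stage = "extract_pi"
        pi_frames = []
        for pid in sorted(recordings):
            frame = extract_recording(recordings[pid], run_config)
            pi_frames.append(frame)
            logger.log(
                stage,
                participant=pid,
                n_rows=len(frame),
                n_invalid=int((~frame["segment_valid"]).sum()),
            )
        pi_long = pd.concat(pi_frames, ignore_index=True)
        manifest.stage_counts["pi_rows"] = len(pi_long)

        stage = "ita"
        ita_rows = []
        for pid in sorted(recordings):
            if pid not in scans:
                manifest.exclusions.append(
                    {"participant_id": pid, "reason": "no colorimeter scans"}
                )
                continue
            res = skin_tone.aggregate_scans(scans[pid], run_config.ita_cutoffs_deg)
            ita_rows.append(
                {
                    "participant_id": pid,
                    "mean_ita_deg": res.mean_ita_deg,
                    "sd_ita_deg": res.sd_ita_deg,
                    "n_scans": res.n_scans,
                    "category": res.category,
                }
            )
        ita_summary = pd.DataFrame(ita_rows)
        manifest.stage_counts["ita_rows"] = len(ita_summary)

        stage = "exclusion"
        valid_pi = pi_long[pi_long["segment_valid"]].copy()
        for pid in sorted(set(pi_long["participant_id"]) - set(valid_pi["participant_id"])):
            manifest.exclusions.append(
                {"participant_id": pid, "reason": "no valid segments in any channel"}
            )
        valid_pi, outlier_ledger = exclude_outliers(valid_pi, enabled=exclusion)
        manifest.exclusions.extend(outlier_ledger)
        for entry in outlier_ledger:
            logger.log(stage, **entry)

        stage = "gee"
        table = valid_pi.merge(
            ita_summary[["participant_id", "mean_ita_deg"]], on="participant_id"
        ).rename(columns={"mean_ita_deg": "ita_deg"})
        cohort_table = table[
            ["participant_id", "wavelength_nm", "condition", "segment", "pi", "ita_deg"]
        ].reset_index(drop=True)
        fits: Dict[int, GEEFit] = {}
        for wavelength in sorted(cohort_table["wavelength_nm"].unique()):
            y, X, ids = build_design(cohort_table, wavelength)
            fit = fit_gee(y, X, ids, run_config.working_correlation)
            fits[wavelength] = fit
            logger.log(
                stage,
                wavelength=wavelength,
                n_obs=fit.n_obs,
                n_clusters=fit.n_clusters,
                alpha_hat=fit.alpha_hat,
            )

        stage = "write"
        written = write_results(cohort_table, fits, out_dir)
        ita_path = out_dir / "ita_summary.csv"
        ita_summary.to_csv(ita_path, index=False)
        written.append(ita_path)
        manifest.analyzed = sorted(set(cohort_table["participant_id"]))
        excluded_ids = {e["participant_id"] for e in manifest.exclusions}
        for pid in sorted(recordings):
            if pid not in manifest.analyzed and pid not in excluded_ids:
                manifest.exclusions.append(
                    {"participant_id": pid, "reason": "dropped before regression"}
                )
        manifest.outputs = {p.name: str(p) for p in written}
        manifest.stage_counts["gee_models"] = len(fits)
        manifest.to_json(out_dir / "manifest.json")
        manifest.outputs["manifest.json"] = str(out_dir / "manifest.json")
        return manifest
    except Exception:
        manifest.failed_stage = stage
        manifest.to_json(out_dir / "manifest.json")
        raise
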