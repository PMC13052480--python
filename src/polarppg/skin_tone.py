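"""Individual typology angle (ITA) skin-tone metrics.

ITA summarises constitutive skin pigmentation from CIELAB colorimetry:

    ITA = arctan((L* - 50) / b*) * 180 / pi   [degrees]

Larger (more positive) angles correspond to lighter skin.  Repeated
colorimeter scans of the same site are aggregated scan-wise: the per-scan
ITA values are computed first and their mean and sample standard deviation
reported, matching how handheld colorimeters are used in dermatology
protocols (many quick scans, one summary angle per site).

Two category schemes are provided.  The default three-way scheme
(light > 23 deg, medium in [-5, 23] deg, brown < -5 deg) is tuned for
cohorts with few very dark participants; the classic six-way literature
scheme is available for comparison via :func:`classify_classic`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

#: Default three-way category cutoffs in degrees: (brown/medium, medium/light).
DEFAULT_CUTOFFS_DEG: Tuple[float, float] = (-5.0, 23.0)

#: Classic six-way ITA scheme cutoffs (degrees) and labels, lightest first.
CLASSIC_SCHEME = (
    (55.0, "very light"),
    (41.0, "light"),
    (28.0, "intermediate"),
    (10.0, "tan"),
    (-30.0, "brown"),
    (-math.inf, "dark"),
)


@dataclass(frozen=True)
class ColorMeasurement:
    """One colorimeter scan: CIELAB lightness L* and yellow-blue b*."""

    L_star: float
    b_star: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.L_star <= 100.0:
            raise ValueError(f"L* must lie in [0, 100], got {self.L_star}")


@dataclass(frozen=True)
class ITAResult:
    """Scan-aggregated ITA for one participant."""

    mean_ita_deg: float
    sd_ita_deg: float
    n_scans: int
    category: str

    def __post_init__(self) -> None:
        if self.sd_ita_deg < 0:
            raise ValueError("ITA standard deviation must be >= 0")


def compute_ita(L_star, b_star):
    """Individual typology angle in degrees from CIELAB (L*, b*).

    Accepts scalars or arrays (broadcast).  ``b* = 0`` puts the angle on the
    +/-90 deg branch point where ITA is undefined; it is rejected.

    >>> compute_ita(60.0, 10.0)
    45.0
    """
    L = np.asarray(L_star, dtype=float)
    b = np.asarray(b_star, dtype=float)
    if np.any(b == 0.0):
        raise ValueError("ITA is undefined for b* = 0")
    ita = np.degrees(np.arctan((L - 50.0) / b))
    return float(ita) if ita.ndim == 0 else ita


def classify(ita_deg: float, cutoffs: Sequence[float] = DEFAULT_CUTOFFS_DEG) -> str:
    """Assign the three-way skin-tone category for an ITA value.

    Boundaries are inclusive to ``medium``: ``classify(-5) == classify(23)
    == "medium"``.
    """
    lo, hi = cutoffs
    if not lo < hi:
        raise ValueError("cutoffs must be strictly increasing")
    if not np.isfinite(ita_deg):
        raise ValueError("ITA must be finite")
    if ita_deg > hi:
        return "light"
    if ita_deg < lo:
        return "brown"
    return "medium"


def classify_classic(ita_deg: float) -> str:
    """Classic six-way ITA category (very light ... dark)."""
    if not np.isfinite(ita_deg):
        raise ValueError("ITA must be finite")
    for lower, label in CLASSIC_SCHEME:
        if ita_deg > lower:
            return label
    return CLASSIC_SCHEME[-1][1]


def aggregate_scans(
    scans,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS_DEG,
) -> ITAResult:
    """Aggregate repeated colorimeter scans into one :class:`ITAResult`.

    ``scans`` may be a DataFrame with ``L_star``/``b_star`` columns, an
    iterable of ``(L*, b*)`` pairs, or of :class:`ColorMeasurement`.  Per-scan
    ITA is computed first; the mean and sample SD (ddof=1; 0 for a single
    scan) are taken over scans, and the category is assigned from the mean.
    Scans with ``b* = 0`` are dropped as invalid; if none survive an error is
    raised.
    """
    if isinstance(scans, pd.DataFrame):
        pairs = scans[["L_star", "b_star"]].to_numpy(dtype=float)
    else:
        rows = []
        for s in scans:
            if isinstance(s, ColorMeasurement):
                rows.append((s.L_star, s.b_star))
            else:
                rows.append((float(s[0]), float(s[1])))
        pairs = np.asarray(rows, dtype=float)
    if pairs.size == 0:
        raise ValueError("no scans provided")
    valid = pairs[pairs[:, 1] != 0.0]
    if valid.shape[0] == 0:
        raise ValueError("all scans invalid (b* = 0)")
    ita = compute_ita(valid[:, 0], valid[:, 1])
    ita = np.atleast_1d(ita)
    mean = float(np.mean(ita))
    sd = float(np.std(ita, ddof=1)) if ita.size > 1 else 0.0
    return ITAResult(
        mean_ita_deg=mean,
        sd_ita_deg=sd,
        n_scans=int(ita.size),
        category=classify(mean, cutoffs),
    )
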