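"""Published reference values for the eight-participant wrist cohort.

These are the summary numbers reported for the dual-wavelength,
polarization-gated wrist PPG validation study this package models: the
per-participant mean ITA (with its scan SD) and the two per-wavelength GEE
coefficient tables.  They serve as cross-check inputs for tests and the
acceptance script — the package never fits to them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

#: Participant number -> (mean ITA deg, scan SD deg).
REFERENCE_COHORT_ITA: Dict[int, Tuple[float, float]] = {
    1: (50.4, 0.4),
    2: (38.9, 1.5),
    3: (32.2, 0.6),
    4: (22.8, 0.3),
    5: (7.4, 0.2),
    6: (-5.3, 0.2),
    7: (-21.3, 0.4),
    8: (-24.3, 0.1),
}


@dataclass(frozen=True)
class ReferenceRow:
    """One printed coefficient row: estimate, robust SE, CI, Wald, p."""

    name: str
    estimate: float
    se: float
    ci: Tuple[float, float]
    wald: float
    p: float


#: Per-wavelength GEE outputs as printed (estimates/SEs at 5 dp).
REFERENCE_GEE: Dict[int, Tuple[ReferenceRow, ...]] = {
    655: (
        ReferenceRow("Intercept", 0.66246, 0.10416, (0.409, 0.916), 40.45, 2e-10),
        ReferenceRow("ITA", 0.00584, 0.00281, (-0.001, 0.013), 4.33, 0.0374),
        ReferenceRow("Cross-polarized", 0.82845, 0.26958, (0.226, 1.431), 9.44, 0.0021),
        ReferenceRow("ITA*Cross-polarized", -0.01531, 0.00968, (-0.035, 0.004), 2.50, 0.1139),
    ),
    940: (
        ReferenceRow("Intercept", 0.59084, 0.09359, (0.351, 0.831), 39.86, 2.7e-10),
        ReferenceRow("ITA", 0.00548, 0.00257, (-0.002, 0.013), 4.55, 0.033),
        ReferenceRow("Cross-polarized", 0.78920, 0.31869, (0.145, 1.43), 6.13, 0.013),
        ReferenceRow("ITA*Cross-polarized", -0.01253, 0.01151, (-0.036, 0.010), 1.19, 0.276),
    ),
}
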