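"""Published summary data and safety thresholds for lag-screw position.

Per-group cut-out counts from the 109-patient DHS cohort in which the
modified tip-apex distance was introduced, kept here so the analysis
tables (cut-out rate by AO/OTA pattern, the pattern association test)
can be recomputed from counts rather than copied as percentages, plus
the cut-off recommendations of the key lag-screw placement studies.
"""

from __future__ import annotations

import numpy as np

from .stats import ContingencyTable

__all__ = [
    "AO_PATTERNS",
    "CUTOUT_BY_PATTERN",
    "COHORT_SIZE",
    "CUTOUT_TOTAL",
    "REDUCTION_PCT",
    "SAFE_CLEVELAND_ZONES",
    "THRESHOLD_RULES",
]

AO_PATTERNS = ["A1.2", "A1.3", "A2.2", "A2.3"]

#: Cut-out (yes, no) counts per AO/OTA pattern; rows sum to the 109 cases.
CUTOUT_BY_PATTERN = ContingencyTable(
    row_labels=AO_PATTERNS,
    col_labels=["cutout", "no_cutout"],
    counts=np.array([[0, 56], [3, 25], [6, 12], [4, 3]]),
)

COHORT_SIZE = 109
CUTOUT_TOTAL = 13

#: Reduction-quality prevalence (percent of patients) in the same cohort.
REDUCTION_PCT = {"Good": 53.2, "Acceptable": 42.2, "Poor": 4.6}

#: Cleveland zones considered safe for the lag-screw tip.
SAFE_CLEVELAND_ZONES = frozenset({5, 6, 8, 9})

#: Protective placement rules: metric column -> (operator, threshold).
#: TAD < 25 mm (Baumgaertner), modified TAD <= 25 mm, ABA > -10 degrees,
#: tip in a safe Cleveland zone.
THRESHOLD_RULES = {
    "tad_mm": ("<", 25.0),
    "mtad_mm": ("<=", 25.0),
    "aba_deg": (">", -10.0),
    "cleveland_zone": ("in", SAFE_CLEVELAND_ZONES),
}
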