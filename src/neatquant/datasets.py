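"""Packaged screening-cohort data.

The 74-patient breast cancer screening cohort's published score-by-variable
cross-tabulations (ordinal NEAT1_2 FISH score 0-3 against eight
clinicopathological variables), plus the benign (n=27) and lactating (n=8)
comparison groups' score tallies.  Two accessors expose the data:

* :func:`screening_cohort_tables` — the cross-tabulations themselves, and
* :func:`screening_cohort_records` — a synthetic patient-level
  reconstruction whose per-variable margins reproduce every published
  cross-tabulation exactly.  The joint distribution across variables is not
  identifiable from the published margins, so within each score group the
  variable levels are assigned independently; any analysis that only uses
  one variable at a time (as the chi-square battery does) is unaffected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from neatquant.assoc_stats import ContingencyTable

#: Score-group sizes for the 74 cancer patients: n(score 0..3).
SCORE_TOTALS = (25, 20, 23, 6)

#: Per-variable cross-tabulations: level -> counts for scores 0..3.
#: Diameter and lymph-node status have missing patients (n=69 and n=71).
SCREENING_COHORT_COUNTS: dict[str, dict[str, tuple[int, int, int, int]]] = {
    "age_group": {"<55": (10, 8, 8, 3), ">=55": (15, 12, 15, 3)},
    "grade": {"1": (10, 5, 3, 0), "2": (8, 9, 5, 1), "3": (7, 6, 15, 5)},
    "tumor_type": {
        "NST": (20, 20, 22, 5),
        "ILC": (3, 0, 0, 0),
        "other": (2, 0, 1, 1),
    },
    "diameter_group": {"<20mm": (14, 12, 7, 4), ">=20mm": (11, 6, 13, 2)},
    "lymph_node": {"neg": (17, 14, 13, 4), "pos": (8, 6, 7, 2)},
    "er": {"neg": (4, 7, 11, 2), "pos": (21, 13, 12, 4)},
    "pgr": {"neg": (6, 8, 12, 3), "pos": (19, 12, 11, 3)},
    "her2": {"neg": (22, 13, 15, 2), "pos": (3, 7, 8, 4)},
}

#: Benign breast tissue (n=27): 25 score-0, 2 score-1.
BENIGN_SCORES = (25, 2, 0, 0)
#: Lactating breast tissue (n=8): 6 of 8 positive.
LACTATING_SCORES = (2, 2, 3, 1)


def scores_from_totals(totals: tuple[int, int, int, int]) -> np.ndarray:
    """Expand per-score tallies into an ordinal score vector."""
    return np.repeat(np.arange(4), totals)


def screening_cohort_tables() -> dict[str, ContingencyTable]:
    """The eight published variable-by-score contingency tables."""
    out = {}
    for var, levels in SCREENING_COHORT_COUNTS.items():
        out[var] = ContingencyTable.from_array(
            np.array(list(levels.values())),
            row_labels=list(levels),
            col_labels=["0", "1", "2", "3"],
        )
    return out


def screening_cohort_records() -> pd.DataFrame:
    """Synthetic patient-level reconstruction of the screening cohort.

    One row per patient with the ordinal score and all eight variables;
    every variable-by-score cross-tabulation matches the published table
    exactly (missing values as NaN where patients lack a measurement).
    """
    score = scores_from_totals(SCORE_TOTALS)
    df = pd.DataFrame(
        {"patient_id": [f"SC{i:03d}" for i in range(len(score))], "score": score}
    )
    for var, levels in SCREENING_COHORT_COUNTS.items():
        col = np.full(len(score), None, dtype=object)
        for s in range(4):
            idx = np.flatnonzero(score == s)
            values: list[object] = []
            for level, counts in levels.items():
                values.extend([level] * counts[s])
            # pad with missing when fewer measured patients than score-group size
            values.extend([None] * (len(idx) - len(values)))
            col[idx] = values
        df[var] = col
    return df
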