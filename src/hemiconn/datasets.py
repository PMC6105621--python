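"""Bundled worked-example data: the published eight-patient stroke cohort.

The table reproduces the patient-characteristics table of the study this
pipeline models: per patient, the manually outlined lesion volume (mm^3),
the weighted corticospinal-tract lesion load (mm^3), time since stroke
(months), the NIHSS neurological-deficit score (0 = normal) and the four
Chedoke-McMaster stage-of-recovery components (7 = normal).  One foot
score is missing ('md' in print): that patient could not complete
clinical testing.

Transcription note: the source table was recovered from a text rendering
whose numeric cell separators were partially lost; the values below are
the most plausible consistent reading and reproduce the published
correlation structure in sign and approximate magnitude.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["load_stroke_cohort", "published_table2"]

_ROWS = [
    # id, sex, age, side, cortical, location, lesion_volume, wcst_ll, months, nihss, arm, hand, leg, foot
    ("S1", "M", 63, "L", "subcortical", "Subcortical",                  3548,   868,  3, 1, 6, 6, 6, 5),
    ("S2", "M", 66, "R", "subcortical", "Subcortical",                  5412,    68, 10, 1, 6, 6, 5, 5),
    ("S3", "F", 57, "R", "cortical",    "Central",                      5445,  2209,  3, 1, 6, 6, 6, 7),
    ("S4", "F", 67, "R", "subcortical", "Posterior limb int. capsule",  3252,    65,  6, 2, 7, 7, 6, np.nan),
    ("S5", "M", 60, "L", "subcortical", "Basal ganglia",                4339,  1550, 20, 4, 5, 3, 6, 5),
    ("S6", "M", 69, "L", "subcortical", "Basal ganglia",               13583,  3350, 23, 6, 3, 2, 6, 4),
    ("S7", "M", 61, "R", "cortical",    "MCA",                         34274,  1792,  6, 6, 2, 2, 5, 3),
    ("S8", "M", 57, "R", "subcortical", "MCA",                         28204,  3611, 72, 7, 2, 2, 5, 2),
]


def load_stroke_cohort():
    """The eight-patient cohort as a DataFrame (missing cells are NaN)."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "id", "sex", "age", "lesion_side", "lesion_type", "location",
            "lesion_volume", "wcst_ll", "months_since_stroke", "nihss",
            "chedoke_arm", "chedoke_hand", "chedoke_leg", "chedoke_foot",
        ],
    )


def published_table2():
    """Published marker-outcome Pearson correlations (3 decimals as printed).

    Keys are (marker, outcome).  The lesion-size / leg cell is printed
    as 0.616; the sign is questionable in the source rendering and the
    cell is included here exactly as printed.
    """
    return {
        ("wcst_ll", "nihss"): 0.764,
        ("wcst_ll", "chedoke_hand"): -0.823,
        ("wcst_ll", "chedoke_arm"): -0.768,
        ("wcst_ll", "chedoke_foot"): -0.459,
        ("wcst_ll", "chedoke_leg"): 0.072,
        ("lesion_volume", "nihss"): 0.844,
        ("lesion_volume", "chedoke_hand"): -0.804,
        ("lesion_volume", "chedoke_arm"): -0.935,
        ("lesion_volume", "chedoke_foot"): -0.803,
        ("lesion_volume", "chedoke_leg"): 0.616,
    }
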