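"""Bundled reference data.

A small 12-subject cross-validation table of per-subject heart rates:
one column from automated PCG time-label segmentation, one from a
fingertip pulse-oximeter readout taken during the same recording sessions.
Used to demonstrate method agreement via a paired t-test.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_hr_crossvalidation"]

_HR_CROSSVALIDATION = [
    # (subject_id, segmentation bpm, oximeter bpm)
    ("Subject 01", 73, 73),
    ("Subject 02", 74, 73),
    ("Subject 03", 73, 73),
    ("Subject 04", 72, 72),
    ("Subject 05", 73, 73),
    ("Subject 06", 72, 73),
    ("Subject 07", 73, 73),
    ("Subject 08", 73, 73),
    ("Subject 09", 73, 73),
    ("Subject 10", 73, 73),
    ("Subject 11", 73, 73),
    ("Subject 12", 71, 72),
]


def load_hr_crossvalidation() -> pd.DataFrame:
    """The 12-subject heart-rate cross-validation table.

    Columns: ``subject_id``, ``hr_segmentation`` (bpm from automated PCG
    segmentation), ``hr_oximeter`` (bpm from a fingertip pulse oximeter).
    """
    return pd.DataFrame(
        _HR_CROSSVALIDATION,
        columns=["subject_id", "hr_segmentation", "hr_oximeter"],
    )
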