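"""Published cohort summaries used as fixed inputs.

These are the printed per-aneurysm mean +/- SD volume summaries, the 2x2
pulsation-vs-size-change contingency tables, and the group summaries of
the growth-risk score from the source study's result tables. They are
inputs (printed numbers), not outputs of this package; the pipeline
re-derives every verdict and statistic from them.
"""

from __future__ import annotations

import pandas as pd

from .dynamics import SizeChangeVerdict, assess_size_change_from_summaries
from .stats import ContingencyTable2x2

__all__ = [
    "cohort_table",
    "swp_size_change_table",
    "gvp_size_change_table",
    "elapss_by_size_change",
    "classify_cohort_size_change",
]

# Per-aneurysm baseline/follow-up summaries: maximal size and sac volume as
# mean +/- phase-wise SD over the 20 cardiac phases, follow-up interval in
# years, and the 3-year growth-risk score (ELAPSS, %).
_COHORT_ROWS = [
    # id, location, size_bl, size_bl_sd, vol_bl, vol_bl_sd, size_fu, size_fu_sd, vol_fu, vol_fu_sd, interval_y, elapss
    (1, "MCA", 6.64, 0.12, 65.05, 2.41, 6.85, 0.09, 81.59, 1.40, 6, 17.5),
    (2, "AComA", 7.49, 0.14, 87.79, 1.96, 6.92, 0.04, 91.72, 0.76, 3, 17.5),
    (3, "MCA", 4.60, 0.07, 22.04, 0.44, 5.19, 0.10, 27.53, 0.72, 4, 42.7),
    (4, "MCA", 3.49, 0.17, 12.41, 1.21, 3.87, 0.12, 14.26, 0.85, 5, 11.7),
    (5, "PComA", 6.71, 0.16, 58.13, 2.02, 6.33, 0.08, 57.56, 1.80, 5, 11.7),
    (6, "MCA", 4.09, 0.10, 17.89, 0.77, 4.42, 0.06, 23.42, 0.49, 4, 17.5),
    (7, "VA", 9.80, 0.11, 203.73, 3.87, 10.38, 0.14, 220.85, 3.20, 5, 7.8),
    (8, "ICA bifur", 4.91, 0.09, 31.08, 0.59, 4.64, 0.13, 31.01, 1.27, 5, 25.8),
    (9, "MCA", 5.06, 0.04, 36.36, 1.01, 5.06, 0.09, 36.89, 1.41, 4, 17.5),
    (10, "BA", 7.84, 0.20, 62.20, 2.32, 8.95, 0.07, 164.27, 4.20, 2, 17.5),
    (11, "ICA bifur", 7.99, 0.10, 102.07, 0.98, 8.04, 0.12, 90.82, 0.93, 4, 11.7),
]

_COHORT_COLUMNS = [
    "aneurysm_id", "location",
    "size_bl_mm", "size_bl_sd", "vol_bl_mm3", "vol_bl_sd",
    "size_fu_mm", "size_fu_sd", "vol_fu_mm3", "vol_fu_sd",
    "fu_interval_years", "elapss_3y_risk",
]


def cohort_table() -> pd.DataFrame:
    """Per-aneurysm baseline/follow-up summaries (11 aneurysms)."""
    return pd.DataFrame(_COHORT_ROWS, columns=_COHORT_COLUMNS)


def classify_cohort_size_change() -> list[SizeChangeVerdict]:
    """Apply the size-change criterion to every printed volume summary."""
    df = cohort_table()
    return [
        assess_size_change_from_summaries(
            r.vol_bl_mm3, r.vol_bl_sd, r.vol_fu_mm3, r.vol_fu_sd
        )
        for r in df.itertuples()
    ]


def swp_size_change_table() -> ContingencyTable2x2:
    """Spatial wall pulsation (present/absent) vs size change (yes/no)."""
    return ContingencyTable2x2(a=6, b=3, c=0, d=2)


def gvp_size_change_table() -> ContingencyTable2x2:
    """Global volumetric pulsation (present/absent) vs size change."""
    return ContingencyTable2x2(a=4, b=4, c=2, d=1)


def elapss_by_size_change() -> dict:
    """Growth-risk score summaries by size-change group (mean, SD, n)."""
    return {
        "changed": {"mean": 19.1, "sd": 11.6, "n": 6},
        "stable": {"mean": 16.8, "sd": 5.6, "n": 5},
    }
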