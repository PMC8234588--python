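"""Cohort demographics carried alongside the imaging analysis.

A 13-patient demographics table in the style of a small prospective ICH
cohort: age decade, sex, T2*-derived hematoma volume (mL, with the
post-ictus day of the measurement), and the latest modified Rankin Scale
(mRS) score. Two patients have two volume measurements (days 1 and 3); the
earliest is taken as the patient's hematoma size. These records are
metadata only — no outcome modelling is built on them — but the summary
helpers derive the cohort-level descriptors an analysis report quotes, such
as the hematoma size range.
"""

from __future__ import annotations

import pandas as pd

# patient_id, age_decade, sex, [(volume_ml, day), ...], latest mRS
_RECORDS = [
    ("01", "60s", "F", [(39.036, 14)], 4),
    ("02", "50s", "M", [(2.354, 14)], 1),
    ("03", "40s", "F", [(8.932, 3)], 1),
    ("04", "50s", "M", [(0.308, 3)], 1),
    ("05", "60s", "M", [(5.2325, 3)], 3),
    ("07", "60s", "F", [(11.4862, 1)], 0),
    ("08", "20s", "F", [(18.9037, 3)], 2),
    ("09", "30s", "F", [(5.4602, 3)], 0),
    ("10", "70s", "F", [(2.1022, 3)], 0),
    ("11", "80s", "F", [(6.578, 3)], 2),
    ("12", "60s", "M", [(14.973, 3)], 1),
    ("13", "60s", "F", [(10.8767, 1), (10.8146, 3)], 1),
    ("15", "60s", "M", [(13.7747, 1), (12.6063, 3)], 4),
]


def demographics() -> pd.DataFrame:
    """The cohort demographics table, one row per patient.

    ``hematoma_ml`` is the earliest available T2* volume; any day-3
    re-measurement is kept in ``hematoma_ml_day3``.
    """
    rows = []
    for pid, age, sex, volumes, mrs in _RECORDS:
        volumes = sorted(volumes, key=lambda v: v[1])
        day3 = next((v for v, d in volumes if d == 3), None)
        rows.append({
            "patient_id": pid,
            "age_decade": age,
            "sex": sex,
            "hematoma_ml": volumes[0][0],
            "hematoma_day": volumes[0][1],
            "hematoma_ml_day3": day3,
            "latest_mrs": mrs,
        })
    return pd.DataFrame(rows)


def _round_as_reported(v: float) -> float:
    """Round a volume the way cohort prose reports it: 1 decimal below 1 mL,
    whole millilitres otherwise."""
    return round(v, 1) if v < 1 else float(round(v))


def hematoma_size_range(df: pd.DataFrame | None = None) -> tuple[float, float]:
    """(min, max) hematoma volume across patients, rounded as reported."""
    df = demographics() if df is None else df
    return (_round_as_reported(df["hematoma_ml"].min()),
            _round_as_reported(df["hematoma_ml"].max()))
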