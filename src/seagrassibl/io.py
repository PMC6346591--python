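"""Reading and writing observation tables.

The exchange format is plain CSV with a header: columns ``study_id``,
``species``, ``day`` (numeric) or ``date`` (ISO-8601), ``biomass``
(g DW m^-2) and ``density`` (shoots m^-2).  Raw values must be strictly
positive (the analysis is in log10 space); offending rows are reported by
file row number.  Dates are converted to days since each series' first
observation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import StandSeries

__all__ = ["read_observations", "write_observations", "series_to_frame"]

_REQUIRED = ("study_id", "species", "biomass", "density")


def read_observations(path) -> tuple[pd.DataFrame, list[StandSeries]]:
    """Load a CSV of raw observations into (table, series collection).

    Rows are grouped by (study_id, species), sorted by time, and
    log10-transformed.  Errors name the offending file row (header = row 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if "day" not in df.columns and "date" not in df.columns:
        raise ValueError("need a 'day' (numeric) or 'date' (ISO-8601) column")

    for col in ("biomass", "density"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals <= 0)
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header is file row 1
            raise ValueError(
                f"row {row}: {col} must be a positive number, "
                f"got {df[col][bad].iloc[0]!r}"
            )
        df[col] = vals

    if "day" in df.columns:
        day = pd.to_numeric(df["day"], errors="coerce")
        if day.isna().any():
            row = int(df.index[day.isna()][0]) + 2
            raise ValueError(f"row {row}: unparseable day value")
        df["_day"] = day
    else:
        date = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
        if date.isna().any():
            row = int(df.index[date.isna()][0]) + 2
            raise ValueError(f"row {row}: unparseable ISO-8601 date")
        df["_date"] = date

    series: list[StandSeries] = []
    for (sid, species), grp in df.groupby(["study_id", "species"], sort=True):
        if "_day" in grp.columns:
            t = grp["_day"].to_numpy(dtype=float)
        else:
            t = (grp["_date"] - grp["_date"].min()).dt.days.to_numpy(dtype=float)
        order = np.argsort(t)
        t = t[order]
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(
                f"series ({sid!r}, {species!r}): duplicate observation times"
            )
        series.append(StandSeries(
            study_id=str(sid),
            species=str(species),
            times=t,
            b=np.log10(grp["biomass"].to_numpy(dtype=float)[order]),
            d=np.log10(grp["density"].to_numpy(dtype=float)[order]),
        ))
    return df.drop(columns=[c for c in ("_day", "_date") if c in df.columns]), series


def series_to_frame(series: list[StandSeries]) -> pd.DataFrame:
    """Flatten series into the observation-table layout (raw scales)."""
    rows = []
    for s in series:
        for t, B, D in zip(s.times, s.biomass, s.density):
            rows.append({
                "study_id": s.study_id,
                "species": s.species,
                "day": t,
                "biomass": B,
                "density": D,
            })
    return pd.DataFrame(rows, columns=["study_id", "species", "day", "biomass", "density"])


def write_observations(series: list[StandSeries], path) -> None:
    """Write series as the CSV dialect read back by :func:`read_observations`.

    Twelve significant digits keep the write/read round trip lossless for
    practical purposes.
    """
    series_to_frame(series).to_csv(path, index=False, float_format="%.12g")
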