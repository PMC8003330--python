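"""Shared table readers and writers.

CSV dialect, package-wide: comma-separated, UTF-8, '.' decimal, mandatory
header row, units embedded in column names (``gly_mM``, ``benz_uM``,
``time_s``).
"""

from __future__ import annotations

from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd

from .assay_processing import RATE_TABLE_COLUMNS, TimeCourse
from .exceptions import ValidationError

__all__ = [
    "TIME_COURSE_COLUMNS",
    "read_rate_table",
    "write_rate_table",
    "read_time_courses",
    "write_time_courses",
]

TIME_COURSE_COLUMNS = ("well", "replicate", "time_s", "a412", "gly_mM",
                       "benz_uM", "enzyme_ug", "volume_uL")


def _read_csv(path: str | PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, float_precision="round_trip")


def read_rate_table(path: str | PathLike) -> pd.DataFrame:
    df = _read_csv(path)
    missing = {"gly_mM", "benz_uM", "rate"} - set(df.columns)
    if missing:
        raise ValidationError(
            f"rate table {path} lacks columns {sorted(missing)}"
        )
    return df


def write_rate_table(df: pd.DataFrame, path: str | PathLike) -> None:
    cols = [c for c in RATE_TABLE_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, index=False)


def read_time_courses(path: str | PathLike) -> list[TimeCourse]:
    """Long-format time-course CSV -> one TimeCourse per (well, replicate)."""
    df = _read_csv(path)
    missing = set(TIME_COURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(
            f"time-course table {path} lacks columns {sorted(missing)}"
        )
    out = []
    for (well, rep), grp in df.groupby(["well", "replicate"], sort=True):
        grp = grp.sort_values("time_s")
        context = grp.iloc[0]
        out.append(TimeCourse(
            well_id=str(well), replicate=int(rep),
            times=grp["time_s"].to_numpy(float),
            a412=grp["a412"].to_numpy(float),
            gly_mM=float(context["gly_mM"]),
            benz_uM=float(context["benz_uM"]),
            enzyme_mass_ug=float(context["enzyme_ug"]),
            volume_uL=float(context["volume_uL"]),
            blank_a412=(float(context["blank_a412"])
                        if "blank_a412" in grp.columns
                        and np.isfinite(context.get("blank_a412", np.nan))
                        else None),
        ))
    if not out:
        raise ValidationError(f"no time courses found in {path}")
    return out


def write_time_courses(time_courses: list[TimeCourse],
                       path: str | PathLike) -> None:
    frames = []
    for tc in time_courses:
        frame = pd.DataFrame({
            "well": tc.well_id, "replicate": tc.replicate,
            "time_s": tc.times, "a412": tc.a412,
            "gly_mM": tc.gly_mM, "benz_uM": tc.benz_uM,
            "enzyme_ug": tc.enzyme_mass_ug, "volume_uL": tc.volume_uL,
        })
        if tc.blank_a412 is not None:
            frame["blank_a412"] = tc.blank_a412
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
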