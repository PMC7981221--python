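"""Covariate attachment: the modelling table.

Each labelled movement becomes one model row carrying the binary response
plus species, sex, log total length, diel period and season, and the two
grouping factors (individual tag and receiver).  Diel period and season
are derived from the movement's start instant in a configured local zone —
the site is near-equatorial, so fixed clock times (07:00–19:00 day) and
fixed month blocks (October–March wet, April–September dry) stand in for
ephemeris calculations.
"""

from __future__ import annotations

import logging
from datetime import datetime, timedelta, timezone, tzinfo
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Local zone of the study site (Indian Ocean atoll archipelago).
DEFAULT_TZ = "+06:00"
DEFAULT_DAY_START = 7  # hour, inclusive
DEFAULT_DAY_END = 19  # hour, exclusive
DEFAULT_WET_MONTHS = (10, 11, 12, 1, 2, 3)

MODEL_COLUMNS = ["label", "species", "sex", "log_size", "diel", "season", "tag_id", "receiver_id"]

__all__ = [
    "DEFAULT_TZ",
    "parse_tz",
    "assign_diel",
    "assign_season",
    "build_model_table",
    "MODEL_COLUMNS",
]


def parse_tz(tz: str | tzinfo) -> tzinfo:
    """Accept an IANA zone name or a fixed ``±HH:MM`` offset."""
    if isinstance(tz, tzinfo):
        return tz
    if tz and tz[0] in "+-":
        sign = 1 if tz[0] == "+" else -1
        hh, _, mm = tz[1:].partition(":")
        return timezone(sign * timedelta(hours=int(hh), minutes=int(mm or 0)))
    return ZoneInfo(tz)


def _local(t: pd.Series | pd.DatetimeIndex, tz) -> pd.Series:
    s = pd.Series(t)
    if s.dt.tz is None:  # naive timestamps are taken as UTC
        s = s.dt.tz_localize("UTC")
    return s.dt.tz_convert(parse_tz(tz))


def assign_diel(
    t,
    tz: str | tzinfo = DEFAULT_TZ,
    day_start: int = DEFAULT_DAY_START,
    day_end: int = DEFAULT_DAY_END,
) -> pd.Series:
    """"day" if local clock time in [day_start, day_end), else "night"."""
    if isinstance(t, datetime):
        return assign_diel(pd.Series(pd.to_datetime([t])), tz, day_start, day_end).iloc[0]
    loc = _local(t, tz)
    frac = loc.dt.hour + loc.dt.minute / 60 + loc.dt.second / 3600
    return pd.Series(np.where((frac >= day_start) & (frac < day_end), "day", "night"),
                     index=loc.index)


def assign_season(t, tz: str | tzinfo = DEFAULT_TZ, wet_months=DEFAULT_WET_MONTHS) -> pd.Series:
    """"wet" if the local month is in ``wet_months``, else "dry"."""
    if isinstance(t, datetime):
        return assign_season(pd.Series(pd.to_datetime([t])), tz, wet_months).iloc[0]
    loc = _local(t, tz)
    return pd.Series(np.where(loc.dt.month.isin(list(wet_months)), "wet", "dry"), index=loc.index)


def build_model_table(
    labelled: pd.DataFrame,
    individuals: pd.DataFrame,
    tz: str | tzinfo = DEFAULT_TZ,
    anchor: str = "start",
    receiver_role: str = "dest",
    day_start: int = DEFAULT_DAY_START,
    day_end: int = DEFAULT_DAY_END,
    wet_months=DEFAULT_WET_MONTHS,
) -> pd.DataFrame:
    """Join covariates onto labelled movements.

    ``anchor`` selects which instant (``start`` = departure detection,
    ``end`` = arrival) drives the diel/season assignment; ``receiver_role``
    selects which receiver (``origin`` | ``dest``) is the grouping factor.
    Rows with missing sex or size are dropped with a logged count.
    """
    if anchor not in ("start", "end"):
        raise ValueError("anchor must be 'start' or 'end'")
    if receiver_role not in ("origin", "dest"):
        raise ValueError("receiver_role must be 'origin' or 'dest'")
    meta = individuals.set_index("tag_id")
    unknown = sorted(set(labelled["tag_id"]) - set(meta.index))
    if unknown:
        raise KeyError(f"movements from tags without metadata: {unknown[:5]}")
    t = labelled["t_start" if anchor == "start" else "t_end"]
    df = pd.DataFrame(
        {
            "label": labelled["label"].astype(int),
            "species": labelled["tag_id"].map(meta["species"]),
            "sex": labelled["tag_id"].map(meta["sex"]),
            "log_size": np.log(labelled["tag_id"].map(meta["total_length_cm"]).astype(float)),
            "diel": assign_diel(t, tz, day_start, day_end).to_numpy(),
            "season": assign_season(t, tz, wet_months).to_numpy(),
            "tag_id": labelled["tag_id"],
            "receiver_id": labelled["origin_receiver" if receiver_role == "origin" else "dest_receiver"],
        }
    )
    missing = df["sex"].isna() | (df["sex"] == "unknown") | ~np.isfinite(df["log_size"])
    if missing.any():
        logger.info("build_model_table: dropped %d rows with missing sex/size", int(missing.sum()))
        df = df[~missing]
    return df.reset_index(drop=True)
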