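"""Reading, validation and writing of the three telemetry input tables.

Detections (tag, receiver, timestamp), receivers (id, latitude, longitude)
and individual metadata (tag, species, sex, total length) arrive as CSV.
Column names are configurable so both VEMCO VUE exports ("Date and Time
(UTC)", "Receiver", "Transmitter") and generic CSVs load without code
changes.  Timestamps are normalised to UTC at ingest; diel/season
assignment later uses a configured local zone.

Exact duplicate detections are kept (with a warning): the six-minute
recursion filter is the only detection-thinning step the method defines.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = {"tag_id": "tag_id", "receiver_id": "receiver_id", "timestamp": "timestamp"}
RECEIVER_COLUMNS = {"receiver_id": "receiver_id", "latitude": "latitude", "longitude": "longitude"}
INDIVIDUAL_COLUMNS = {
    "tag_id": "tag_id",
    "species": "species",
    "sex": "sex",
    "total_length_cm": "total_length_cm",
}

__all__ = [
    "read_detections",
    "read_receivers",
    "read_individuals",
    "filter_known_tags",
    "write_detections",
]


def _read_csv(path, columns: dict, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if df.empty:
        raise ValueError(f"{kind} file {path} is empty")
    missing = [src for src in columns.values() if src not in df.columns]
    if missing:
        raise ValueError(f"{kind} file {path} lacks columns {missing}; has {list(df.columns)}")
    return df.rename(columns={src: dst for dst, src in columns.items()})[list(columns)]


def read_detections(path, tz: str = "UTC", columns: dict | None = None) -> pd.DataFrame:
    """Load detections, normalise timestamps to UTC, sort by (tag, time).

    ``tz`` is the zone the file's timestamps are recorded in (naive
    timestamps are localised to it; zone-aware ones are simply converted).
    Unparseable timestamps are a hard error naming the offending CSV line
    numbers.  Exact duplicate rows are retained with a warning.
    """
    cols = {**DETECTION_COLUMNS, **(columns or {})}
    df = _read_csv(path, cols, "detections")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed", utc=False)
    bad = ts.isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # 1-based, + header
        raise ValueError(f"unparseable timestamps at CSV lines {lines[:10]}"
                         + (" ..." if len(lines) > 10 else ""))
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(tz)
    df["timestamp"] = ts.dt.tz_convert("UTC")
    empty = df["tag_id"].isna() | df["receiver_id"].isna() | (df["tag_id"] == "") | (df["receiver_id"] == "")
    if empty.any():
        raise ValueError(f"empty tag/receiver ids at CSV lines {(df.index[empty] + 2).tolist()[:10]}")
    ndup = int(df.duplicated().sum())
    if ndup:
        logger.warning("detections: %d exact duplicate rows retained", ndup)
    df = df.sort_values(["tag_id", "timestamp"], kind="stable").reset_index(drop=True)
    logger.info("detections: read %d rows from %s", len(df), path)
    return df


def read_receivers(path, columns: dict | None = None) -> pd.DataFrame:
    """Load and validate the receiver table (unique ids, WGS84 bounds)."""
    cols = {**RECEIVER_COLUMNS, **(columns or {})}
    df = _read_csv(path, cols, "receivers")
    df["latitude"] = pd.to_numeric(df["latitude"], errors="raise")
    df["longitude"] = pd.to_numeric(df["longitude"], errors="raise")
    bad = ~(df["latitude"].between(-90, 90) & df["longitude"].between(-180, 180))
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(f"receiver {row['receiver_id']!r}: coordinates out of range "
                         f"({row['latitude']}, {row['longitude']})")
    dup = df["receiver_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate receiver ids: {sorted(df.loc[dup, 'receiver_id'].unique())}")
    return df.reset_index(drop=True)


def read_individuals(path, columns: dict | None = None) -> pd.DataFrame:
    """Load tag metadata: species, sex, total length (cm, > 0 when present)."""
    cols = {**INDIVIDUAL_COLUMNS, **(columns or {})}
    df = _read_csv(path, cols, "individuals")
    dup = df["tag_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate tag ids: {sorted(df.loc[dup, 'tag_id'].unique())}")
    df["total_length_cm"] = pd.to_numeric(df["total_length_cm"], errors="coerce")
    nonpos = df["total_length_cm"] <= 0
    if nonpos.any():
        raise ValueError(f"non-positive total length for tags "
                         f"{sorted(df.loc[nonpos, 'tag_id'])}")
    return df.reset_index(drop=True)


def filter_known_tags(detections: pd.DataFrame, individuals: pd.DataFrame) -> pd.DataFrame:
    """Keep only detections whose tag id has metadata (known ID codes)."""
    known = set(individuals["tag_id"])
    keep = detections["tag_id"].isin(known)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_known_tags: removed %d of %d detections", removed, len(detections))
    if not keep.any():
        logger.warning("filter_known_tags: no detections from known tags remain")
    return detections[keep].reset_index(drop=True)


def write_detections(detections: pd.DataFrame, path) -> None:
    """Write detections with ISO-8601 UTC timestamps (round-trips at 1 s)."""
    out = detections.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)
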