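"""Movement extraction from per-individual detection sequences.

A movement is the gap between two consecutive detections of the same
individual: a *recursion* if both detections are at the same receiver (a
self-loop in the movement network), a *transition* otherwise.  Transitions
carry RDET — the relative deviation from expected time — computed as
(inter-receiver distance / species minimum sustainable swim speed) divided
by the observed gap.  RDET > 1 means faster than a direct swim, < 1 slower
or more tortuous.

Two filters protect the gap signal: recursions shorter than six minutes
are discarded (a missed ping rather than a real departure), and
transitions with RDET > 5 are discarded (implausibly fast, likely false
detections).  Both bounds are strict inequalities and configurable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

#: Minimum sustainable swim speed per species (m/s).
DEFAULT_SWIM_SPEEDS = {"gray_reef": 0.69, "silvertip": 0.73}

MOVEMENT_COLUMNS = [
    "tag_id",
    "kind",
    "origin_receiver",
    "dest_receiver",
    "t_start",
    "t_end",
    "gap_s",
    "distance_m",
    "expected_s",
    "rdet",
]

__all__ = [
    "EARTH_RADIUS_M",
    "DEFAULT_SWIM_SPEEDS",
    "MOVEMENT_COLUMNS",
    "haversine_m",
    "interreceiver_distances",
    "extract_movements",
    "filter_recursions",
    "compute_rdet",
    "filter_transitions",
]


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres (spherical Earth, R = 6371 km)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def interreceiver_distances(receivers: pd.DataFrame) -> pd.DataFrame:
    """Symmetric great-circle distance matrix between receivers (metres).

    Parameters
    ----------
    receivers : DataFrame with columns receiver_id, latitude, longitude.

    Returns
    -------
    DataFrame indexed and columned by receiver_id.
    """
    if len(receivers) < 1:
        raise ValueError("need at least one receiver")
    lat = receivers["latitude"].to_numpy()
    lon = receivers["longitude"].to_numpy()
    d = haversine_m(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    ids = receivers["receiver_id"].tolist()
    return pd.DataFrame(d, index=ids, columns=ids)


def extract_movements(detections: pd.DataFrame) -> pd.DataFrame:
    """One movement per consecutive detection pair per individual.

    Individuals with fewer than two detections yield no movements.  Pairs
    with non-positive gaps (clock collisions) are dropped with a warning —
    a zero gap has no defined RDET or log-duration.
    """
    det = detections.sort_values(["tag_id", "timestamp"], kind="stable")
    g = det.groupby("tag_id", sort=False)
    out = pd.DataFrame(
        {
            "tag_id": det["tag_id"],
            "origin_receiver": g["receiver_id"].shift(1),
            "dest_receiver": det["receiver_id"],
            "t_start": g["timestamp"].shift(1),
            "t_end": det["timestamp"],
        }
    ).dropna(subset=["origin_receiver"])
    out["gap_s"] = (out["t_end"] - out["t_start"]).dt.total_seconds()
    nonpos = out["gap_s"] <= 0
    if nonpos.any():
        logger.warning("dropping %d movements with non-positive gaps", int(nonpos.sum()))
        out = out[~nonpos]
    out["kind"] = np.where(out["origin_receiver"] == out["dest_receiver"], "recursion", "transition")
    for c in ("distance_m", "expected_s", "rdet"):
        out[c] = np.nan
    return out[MOVEMENT_COLUMNS].reset_index(drop=True)


def filter_recursions(movements: pd.DataFrame, min_gap_s: float = 360.0) -> pd.DataFrame:
    """Drop recursions with gap strictly below ``min_gap_s``; transitions untouched."""
    drop = (movements["kind"] == "recursion") & (movements["gap_s"] < min_gap_s)
    if drop.any():
        logger.info("recursion filter (<%.0f s): removed %d of %d recursions",
                    min_gap_s, int(drop.sum()), int((movements["kind"] == "recursion").sum()))
    return movements[~drop].reset_index(drop=True)


def compute_rdet(
    movements: pd.DataFrame,
    distances: pd.DataFrame,
    species_of: dict,
    swim_speeds: dict | None = None,
) -> pd.DataFrame:
    """Fill distance, expected time and RDET for transitions.

    expected_s = distance / species swim speed; rdet = expected_s / gap_s.
    Recursions pass through unchanged.  A zero distance between distinct
    receivers violates the no-overlap array premise and is a hard error.
    """
    swim_speeds = dict(DEFAULT_SWIM_SPEEDS if swim_speeds is None else swim_speeds)
    out = movements.copy()
    tr = out["kind"] == "transition"
    if not tr.any():
        return out
    o = out.loc[tr, "origin_receiver"]
    dst = out.loc[tr, "dest_receiver"]
    missing = sorted((set(o) | set(dst)) - set(distances.index))
    if missing:
        raise KeyError(f"receivers missing from distance matrix: {missing}")
    d = distances.to_numpy()[
        distances.index.get_indexer(o), distances.index.get_indexer(dst)
    ]
    if np.any(d <= 0):
        bad = o.to_numpy()[d <= 0]
        raise ValueError(f"zero distance between distinct receivers (e.g. at {bad[0]!r}); "
                         "receiver detection ranges must not overlap")
    speed = out.loc[tr, "tag_id"].map(species_of).map(swim_speeds).to_numpy(dtype=float)
    if np.any(~np.isfinite(speed)):
        raise KeyError("swim speed undefined for some species in the transition set")
    out.loc[tr, "distance_m"] = d
    out.loc[tr, "expected_s"] = d / speed
    # d / (v * gap) == expected / gap but avoids compounding rounding
    out.loc[tr, "rdet"] = d / (speed * out.loc[tr, "gap_s"])
    return out


def filter_transitions(movements: pd.DataFrame, rdet_max: float = 5.0) -> pd.DataFrame:
    """Drop transitions with RDET strictly above ``rdet_max``; recursions untouched."""
    drop = (movements["kind"] == "transition") & (movements["rdet"] > rdet_max)
    if drop.any():
        logger.info("RDET filter (>%g): removed %d of %d transitions",
                    rdet_max, int(drop.sum()), int((movements["kind"] == "transition").sum()))
    return movements[~drop].reset_index(drop=True)
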