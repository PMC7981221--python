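"""Threshold derivation and binary labelling of movements.

Gap durations (recursions) and RDET values (transitions) are strongly
right-skewed and, in arrays where animals alternate on-reef activity with
wider excursions, bimodal.  Each species' boundary between the two regimes
is found by Fisher's optimal univariate classification: an exact
dynamic-programming partition of the sorted, log-transformed values into
``k`` contiguous classes minimising the total within-class sum of squared
deviations from the class means.  The single internal boundary (k = 2) is
back-transformed and used as the species' classification threshold.

Labelling convention: "restricted" = 0 (on-reef activity), "out of range"
= 1 (wider, off-reef activity).  Long recursion gaps and slow/tortuous
transitions (low RDET) are out of range; ties fall to restricted, keeping
the classification conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSet",
    "fisher_breaks",
    "recursion_threshold",
    "transition_threshold",
    "derive_thresholds",
    "classify_movements",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Per-species classification boundaries.

    Attributes
    ----------
    species : str
    recursion_threshold_min : float
        Gap duration (minutes) above which a recursion is out of range.
    transition_rdet_threshold : float
        RDET below which a transition is out of range.
    """

    species: str
    recursion_threshold_min: float
    transition_rdet_threshold: float

    def __post_init__(self) -> None:
        if not (self.recursion_threshold_min > 0 and self.transition_rdet_threshold > 0):
            raise ValueError("thresholds must be positive")


def fisher_breaks(values, k: int = 2) -> np.ndarray:
    """Exact optimal partition of 1-D data into ``k`` contiguous classes.

    Minimises the total within-class sum of squared deviations from class
    means over all contiguous partitions of the sorted values (Fisher's
    dynamic-programming algorithm; the "fisher" style of classInt).

    Parameters
    ----------
    values : array-like of float
        Finite observations, n >= k.
    k : int
        Number of classes, >= 2.

    Returns
    -------
    numpy.ndarray
        The k-1 internal boundaries in increasing order, each reported as
        the maximum value of its lower class.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} values, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if x[0] == x[-1]:
        logger.warning("fisher_breaks: all %d values identical; degenerate partition", n)
        return np.full(k - 1, x[0])

    cs = np.concatenate([[0.0], np.cumsum(x)])
    css = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i, j):
        # within-class SSE of x[i:j] (half-open); i, j may be arrays
        m = j - i
        s = cs[j] - cs[i]
        return (css[j] - css[i]) - s * s / m

    if k == 2:
        left = np.arange(1, n)  # size of lower class
        tot = sse(0, left) + sse(left, n)
        split = int(np.argmin(tot)) + 1
        return np.array([x[split - 1]])

    # general k: DP over (class count, end index)
    cost = np.empty((k, n + 1))
    cost[0, 1:] = sse(0, np.arange(1, n + 1))
    back = np.zeros((k, n + 1), dtype=int)
    for c in range(1, k):
        for j in range(c + 1, n + 1):
            i = np.arange(c, j)
            cand = cost[c - 1, i] + sse(i, np.full(i.size, j))
            b = int(np.argmin(cand))
            cost[c, j] = cand[b]
            back[c, j] = i[b]
    # recover boundaries
    bounds = []
    j = n
    for c in range(k - 1, 0, -1):
        i = back[c, j]
        bounds.append(x[i - 1])
        j = i
    return np.array(bounds[::-1])


def _log_break_threshold(vals: np.ndarray, what: str, species: str) -> float:
    """Fisher 2-class break of log-transformed values, back-transformed."""
    vals = np.asarray(vals, dtype=float)
    if vals.size < 2:
        raise ValueError(f"need >=2 retained {what}s for species {species!r}, got {vals.size}")
    if np.any(vals <= 0):
        raise ValueError(f"{what} values must be positive for log transform")
    if vals.min() == vals.max():
        logger.warning("%s threshold for %s degenerate: all values equal", what, species)
        return float(vals[0])
    (b,) = fisher_breaks(np.log(vals), k=2)
    return float(np.exp(b))


def recursion_threshold(movements: pd.DataFrame, species: str, species_of: dict) -> float:
    """Recursion-gap threshold (minutes) for one species.

    Natural-log-transforms the retained recursion gap durations, takes the
    Fisher 2-class break and back-transforms it to minutes.
    """
    mask = (movements["kind"] == "recursion") & movements["tag_id"].map(species_of).eq(species)
    gaps_min = movements.loc[mask, "gap_s"].to_numpy() / 60.0
    return _log_break_threshold(gaps_min, "recursion", species)


def transition_threshold(movements: pd.DataFrame, species: str, species_of: dict) -> float:
    """RDET threshold for one species (original RDET scale)."""
    mask = (movements["kind"] == "transition") & movements["tag_id"].map(species_of).eq(species)
    rdet = movements.loc[mask, "rdet"].to_numpy()
    return _log_break_threshold(rdet, "transition", species)


def derive_thresholds(movements: pd.DataFrame, species_of: dict) -> dict[str, ThresholdSet]:
    """ThresholdSet per species present in the filtered movement table."""
    out = {}
    for sp in sorted(set(species_of.values())):
        out[sp] = ThresholdSet(
            species=sp,
            recursion_threshold_min=recursion_threshold(movements, sp, species_of),
            transition_rdet_threshold=transition_threshold(movements, sp, species_of),
        )
        logger.info(
            "thresholds[%s]: recursion %.1f min, RDET %.3f",
            sp,
            out[sp].recursion_threshold_min,
            out[sp].transition_rdet_threshold,
        )
    return out


def classify_movements(
    movements: pd.DataFrame,
    thresholds: dict[str, ThresholdSet],
    species_of: dict,
) -> pd.DataFrame:
    """Attach the binary label: restricted = 0, out of range = 1.

    A recursion is out of range iff its gap (minutes) strictly exceeds the
    species' recursion threshold; a transition is out of range iff its RDET
    is strictly below the species' RDET threshold.  Equality goes to
    restricted.
    """
    sp = movements["tag_id"].map(species_of)
    missing = sorted(set(sp.unique()) - set(thresholds))
    if missing:
        raise ValueError(f"no thresholds for species: {missing}")
    theta_rec = sp.map({s: t.recursion_threshold_min for s, t in thresholds.items()})
    theta_rdet = sp.map({s: t.transition_rdet_threshold for s, t in thresholds.items()})
    is_rec = movements["kind"] == "recursion"
    label = np.where(
        is_rec,
        movements["gap_s"] / 60.0 > theta_rec,
        movements["rdet"] < theta_rdet,
    )
    out = movements.copy()
    out["label"] = label.astype(int)
    return out
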