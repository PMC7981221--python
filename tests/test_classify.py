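"""Fisher optimal partitioning and the binary labelling rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefgap.classify import (
    ThresholdSet,
    classify_movements,
    fisher_breaks,
    recursion_threshold,
    transition_threshold,
)


def part_sse(x, i):
    """Within-class SSE of the 2-partition of sorted x at split index i."""
    lo, hi = x[:i], x[i:]
    sse = 0.0
    for part in (lo, hi):
        if len(part):
            sse += ((part - part.mean()) ** 2).sum()
    return sse


def brute_force_two_class(values):
    """Enumerate every contiguous 2-partition of the sorted values."""
    x = np.sort(np.asarray(values, dtype=float))
    best = (np.inf, None)
    for i in range(1, len(x)):
        sse = part_sse(x, i)
        if sse < best[0]:
            best = (sse, x[i - 1])
    return best


class TestFisherBreaks:
    def test_well_separated_clusters(self):
        (b,) = fisher_breaks([0.9, 1.0, 1.1, 9.8, 10.0, 10.2], k=2)
        assert 1.1 <= b < 9.8

    def test_three_points(self):
        # classes {1,2} | {10}: SSE 0.5 beats {1} | {2,10}: SSE 32
        (b,) = fisher_breaks([1.0, 2.0, 10.0], k=2)
        assert b == 2.0

    def test_degenerate_identical(self, caplog):
        with caplog.at_level("WARNING"):
            (b,) = fisher_breaks([3.0, 3.0, 3.0], k=2)
        assert b == 3.0
        assert any("identical" in r.message for r in caplog.records)

    def test_n_less_than_k_errors(self):
        with pytest.raises(ValueError):
            fisher_breaks([1.0], k=2)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1e4), min_size=2, max_size=60))
    def test_matches_brute_force(self, values):
        sse_bf, b_bf = brute_force_two_class(values)
        (b,) = fisher_breaks(values, k=2)
        x = np.sort(np.asarray(values))
        i = int(np.searchsorted(x, b, side="right"))
        assert part_sse(x, i) == pytest.approx(sse_bf, rel=1e-9, abs=1e-9)

    def test_three_classes_match_enumeration(self):
        rng = np.random.default_rng(42)
        x = np.sort(rng.uniform(0, 100, 12))
        best = (np.inf, None)
        for i in range(1, 11):
            for j in range(i + 1, 12):
                parts = [x[:i], x[i:j], x[j:]]
                sse = sum(((p - p.mean()) ** 2).sum() for p in parts)
                if sse < best[0]:
                    best = (sse, (x[i - 1], x[j - 1]))
        got = fisher_breaks(x, k=3)
        assert tuple(got) == pytest.approx(best[1])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(3, 1, 200)
        b1 = fisher_breaks(vals, k=2)
        b2 = fisher_breaks(rng.permutation(vals), k=2)
        assert b1 == pytest.approx(b2)


def _movements(kind, values, tag="A"):
    n = len(values)
    t0 = pd.Timestamp("2015-06-01T00:00:00Z")
    return pd.DataFrame(
        {
            "tag_id": tag,
            "kind": kind,
            "origin_receiver": "R1",
            "dest_receiver": "R1" if kind == "recursion" else "R2",
            "t_start": t0,
            "t_end": t0 + pd.Timedelta(hours=1),
            "gap_s": np.asarray(values) * 60.0 if kind == "recursion" else 3600.0,
            "distance_m": np.nan,
            "expected_s": np.nan,
            "rdet": np.asarray(values) if kind == "transition" else np.nan,
        }
    )


class TestThresholds:
    def test_recursion_threshold_between_modes(self):
        rng = np.random.default_rng(11)
        gaps_min = np.concatenate(
            [rng.lognormal(np.log(20), 0.3, 1000), rng.lognormal(np.log(600), 0.3, 1000)]
        )
        movs = _movements("recursion", gaps_min)
        theta = recursion_threshold(movs, "gray_reef", {"A": "gray_reef"})
        assert 40 < theta < 300

    def test_transition_threshold_between_modes(self):
        rng = np.random.default_rng(12)
        rdet = np.concatenate(
            [rng.lognormal(np.log(0.05), 0.3, 800), rng.lognormal(np.log(0.8), 0.3, 800)]
        )
        movs = _movements("transition", rdet)
        theta = transition_threshold(movs, "gray_reef", {"A": "gray_reef"})
        assert 0.05 < theta < 0.8

    def test_all_fast_transitions_still_classified(self):
        rng = np.random.default_rng(13)
        rdet = rng.lognormal(np.log(2.0), 0.4, 500)  # all faster than expected
        movs = _movements("transition", rdet)
        theta = transition_threshold(movs, "gray_reef", {"A": "gray_reef"})
        ts = {"gray_reef": ThresholdSet("gray_reef", 60.0, theta)}
        labelled = classify_movements(movs, ts, {"A": "gray_reef"})
        assert labelled["label"].mean() < 0.5  # most restricted

    def test_log_base_invariance(self):
        # contiguous optimal partitions survive positive scaling of the
        # transformed values, so the break is the same data point
        rng = np.random.default_rng(14)
        vals = np.concatenate([rng.lognormal(1, 0.3, 300), rng.lognormal(4, 0.3, 300)])
        (b_ln,) = fisher_breaks(np.log(vals), k=2)
        (b_log10,) = fisher_breaks(np.log10(vals), k=2)
        assert np.exp(b_ln) == pytest.approx(10 ** b_log10, rel=1e-9)

    def test_too_few_values_error_names_species(self):
        movs = _movements("recursion", [10.0])
        with pytest.raises(ValueError, match="silvertip"):
            recursion_threshold(movs, "silvertip", {"A": "silvertip"})


class TestLabelling:
    TS = {"gray_reef": ThresholdSet("gray_reef", 91.0, 0.164)}
    SP = {"A": "gray_reef"}

    def test_recursion_above_threshold_out_of_range(self):
        lab = classify_movements(_movements("recursion", [92.0]), self.TS, self.SP)
        assert lab.loc[0, "label"] == 1

    @pytest.mark.parametrize("gap_min,label", [(91.0, 0), (90.0, 0), (91.01, 1)])
    def test_recursion_tie_goes_restricted(self, gap_min, label):
        lab = classify_movements(_movements("recursion", [gap_min]), self.TS, self.SP)
        assert lab.loc[0, "label"] == label

    @pytest.mark.parametrize("rdet,label", [(0.10, 1), (1.0, 0), (0.164, 0)])
    def test_transition_rules(self, rdet, label):
        lab = classify_movements(_movements("transition", [rdet]), self.TS, self.SP)
        assert lab.loc[0, "label"] == label

    def test_missing_species_threshold_errors(self):
        with pytest.raises(ValueError, match="silvertip"):
            classify_movements(
                _movements("recursion", [10.0]), self.TS, {"A": "silvertip"}
            )

    def test_monotone_labelling(self):
        gaps = np.linspace(1, 300, 100)
        lab = classify_movements(_movements("recursion", gaps), self.TS, self.SP)
        assert lab["label"].is_monotonic_increasing
        rdets = np.linspace(0.01, 2.0, 100)
        lab2 = classify_movements(_movements("transition", rdets), self.TS, self.SP)
        assert lab2["label"].is_monotonic_decreasing
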