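import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from shwheb import (
    between_background_logfc,
    count_states,
    intersect_lines,
    transition_categories,
    trend_patterns,
    within_background_logfc,
)


def _ctx_frame(states, context_id="C66:shoot:SHW"):
    return pd.DataFrame({
        "triad_id": [f"T{i}" for i in range(len(states))],
        "context_id": context_id,
        "tissue": "shoot",
        "background": "SHW",
        "state": states,
    })


class TestCountStates:
    def test_exact_partition(self):
        s = count_states(_ctx_frame(["AB", "AB", "D", "UN", "NE"]))
        assert (s.n_AB, s.n_D, s.n_UN, s.n_NE) == (2, 1, 1, 1)

    def test_empty_context(self):
        s = count_states(_ctx_frame([]))
        assert (s.n_AB, s.n_D, s.n_UN, s.n_NE) == (0, 0, 0, 0)

    def test_all_one_state(self):
        s = count_states(_ctx_frame(["D"] * 7))
        assert s.n_D == 7 and s.n_AB == s.n_UN == s.n_NE == 0

    def test_duplicate_triad_rejected(self):
        df = _ctx_frame(["AB", "D"])
        df.loc[1, "triad_id"] = "T0"
        with pytest.raises(ValueError, match="duplicate"):
            count_states(df)


class TestLogfc:
    def test_equal_counts_give_zero(self):
        assert within_background_logfc(500, 500) == 0.0
        assert between_background_logfc(42, 42) == 0.0

    def test_zero_count_is_missing(self, caplog):
        with caplog.at_level("WARNING"):
            assert math.isnan(within_background_logfc(0, 10))
            assert math.isnan(between_background_logfc(10, 0))

    @given(a=st.integers(1, 10_000), d=st.integers(1, 10_000))
    def test_antisymmetry(self, a, d):
        assert within_background_logfc(a, d) == pytest.approx(
            -within_background_logfc(d, a))


class TestIntersectLines:
    def _frame(self, assign):
        rows = []
        for line, states in assign.items():
            for i, s in enumerate(states):
                rows.append({"triad_id": f"T{i}", "line": line, "state": s})
        return pd.DataFrame(rows)

    def test_pairwise_combinations(self):
        combo, sizes, n_ne = intersect_lines(
            self._frame({"C44": ["AB", "AB", "D"], "C45": ["AB", "D", "D"]}))
        assert n_ne == 0
        got = {(r["C44"], r["C45"]): r["n_triads"] for _, r in combo.iterrows()}
        assert got == {("AB", "AB"): 1, ("AB", "D"): 1, ("D", "D"): 1}

    def test_single_line_reduces_to_set_sizes(self):
        combo, sizes, _ = intersect_lines(self._frame({"C44": ["AB", "AB", "UN"]}))
        ab = sizes[(sizes["line"] == "C44") & (sizes["state"] == "AB")]["set_size"].iloc[0]
        assert ab == 2
        assert combo["n_triads"].sum() == 3

    def test_all_unbiased_collapses_to_one_combination(self):
        combo, _, _ = intersect_lines(
            self._frame({g: ["UN"] * 5 for g in ("C44", "C45", "C65", "C66")}))
        assert len(combo) == 1 and combo["n_triads"].iloc[0] == 5

    def test_ne_in_any_line_excluded_but_tallied(self):
        combo, _, n_ne = intersect_lines(
            self._frame({"C44": ["AB", "NE", "D"], "C45": ["AB", "AB", "D"]}))
        assert n_ne == 1
        assert combo["n_triads"].sum() == 2

    def test_differing_universes_rejected(self):
        df = self._frame({"C44": ["AB", "D"], "C45": ["AB", "D"]})
        df = df.drop(3)  # C45 loses T1
        with pytest.raises(ValueError, match="universes differ"):
            intersect_lines(df)


class TestTrendPatterns:
    def _frame(self, patterns):
        rows = []
        for i, states in enumerate(patterns):
            for t, s in zip(("shoot", "root", "anther"), states):
                rows.append({"triad_id": f"T{i}", "tissue": t, "state": s})
        return pd.DataFrame(rows)

    def test_top_pattern_and_conservation(self):
        df = self._frame([("UN", "UN", "UN")] * 5 + [("UN", "D", "UN")] * 2)
        patterns, marginals = trend_patterns(df, ("shoot", "root", "anther"))
        assert patterns.iloc[0]["pattern_key"] == "UN|UN|UN"
        assert patterns.iloc[0]["n_triads"] == 5
        assert patterns["n_triads"].sum() == 7
        assert marginals.set_index("state").loc["D", "root"] == 2

    def test_single_tissue_patterns_are_states(self):
        df = self._frame([("AB",), ("D",)])
        patterns, _ = trend_patterns(df, ("shoot",))
        assert set(patterns["pattern_key"]) == {"AB", "D"}

    def test_missing_tissue_for_triad_rejected(self):
        df = self._frame([("UN", "UN", "UN")]).iloc[:-1]
        with pytest.raises(ValueError):
            trend_patterns(df, ("shoot", "root", "anther"))


class TestTransitions:
    def test_categories(self):
        idx = ["T1", "T2", "T3", "T4", "T5"]
        s1 = pd.Series(["D", "D", "D", "UN", "D"], index=idx)
        s2 = pd.Series(["D", "D", "UN", "D", "AB"], index=idx)
        s3 = pd.Series(["D", "AB", "D", "D", "UN"], index=idx)
        out = transition_categories(s1, s2, s3).set_index("category")["n_triads"]
        assert out["same_in_all_three"] == 1  # (D,D,D)
        assert out["same_in_1_2_only"] == 1   # (D,D,AB)
        assert out["same_in_1_3_only"] == 1   # (D,UN,D) reversal
        assert out["same_in_2_3_only"] == 1   # (UN,D,D)
        assert out["all_different"] == 1      # (D,AB,UN)

    def test_percentages_sum_to_100(self):
        idx = list("abcd")
        s = pd.Series(["D", "AB", "UN", "D"], index=idx)
        out = transition_categories(s, s, s)
        assert out["percent"].sum() == pytest.approx(100.0)
        assert out.set_index("category")["n_triads"]["same_in_all_three"] == 4

    def test_misaligned_inputs_rejected(self):
        s1 = pd.Series(["D"], index=["T1"])
        s2 = pd.Series(["D"], index=["T2"])
        with pytest.raises(ValueError, match="misaligned"):
            transition_categories(s1, s2, s1)
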