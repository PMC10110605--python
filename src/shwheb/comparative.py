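"""Summaries over triad bias states.

Counts per state, the log2 count-ratio conventions used to compare bias
within one genomic background (D-biased vs AB-biased triads) and between
backgrounds (same state, hexaploid vs parental), cross-line state
intersections (UpSet-style), cross-tissue trend patterns (alluvial-ready),
and cross-genotype transition categories.

Note the LogFC here is a ratio of *numbers of biased triads*, not of
expression levels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass


import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class BiasCountSummary:
    context_id: str
    n_AB: int
    n_D: int
    n_UN: int
    n_NE: int

    @property
    def total(self) -> int:
        return self.n_AB + self.n_D + self.n_UN + self.n_NE


def count_states(results: pd.DataFrame) -> BiasCountSummary:
    """Exact state partition counts for one context's result rows."""
    ctx = results["context_id"].unique()
    if len(ctx) > 1:
        raise ValueError(f"expected one context, got {list(ctx)}")
    if len(ctx) == 0:
        ctx = [""]
    if results["triad_id"].duplicated().any():
        dup = results.loc[results["triad_id"].duplicated(), "triad_id"].iloc[0]
        raise ValueError(f"duplicate triad {dup!r} in context {ctx[0]!r}")
    c = results["state"].value_counts()
    return BiasCountSummary(
        context_id=str(ctx[0]),
        n_AB=int(c.get("AB", 0)),
        n_D=int(c.get("D", 0)),
        n_UN=int(c.get("UN", 0)),
        n_NE=int(c.get("NE", 0)),
    )


def summarize_counts(results: pd.DataFrame) -> pd.DataFrame:
    """State counts per context over a multi-context result table."""
    rows = []
    for ctx_id, grp in results.groupby("context_id", sort=True):
        s = count_states(grp)
        rows.append({
            "context_id": s.context_id,
            "tissue": grp["tissue"].iloc[0],
            "background": grp["background"].iloc[0],
            "line": grp["line"].iloc[0] if "line" in grp.columns else None,
            "n_AB": s.n_AB, "n_D": s.n_D, "n_UN": s.n_UN, "n_NE": s.n_NE,
        })
    return pd.DataFrame(rows)


def within_background_logfc(n_ab: int, n_d: int) -> float:
    """log2(n_D / n_AB) within one background; > 0 means more D-biased
    triads.  Missing (NaN, logged) when either count is zero."""
    if n_ab < 0 or n_d < 0:
        raise ValueError("counts must be non-negative")
    if n_ab == 0 or n_d == 0:
        logger.warning("within-background LogFC undefined for n_AB=%d, n_D=%d", n_ab, n_d)
        return float("nan")
    return math.log2(n_d / n_ab)


def between_background_logfc(n_state_shw: int, n_state_parental: int) -> float:
    """log2(count in SHW / count in parental) for one state; > 0 means the
    state is more frequent in the hexaploid background."""
    if n_state_shw < 0 or n_state_parental < 0:
        raise ValueError("counts must be non-negative")
    if n_state_shw == 0 or n_state_parental == 0:
        logger.warning("between-background LogFC undefined for counts %d, %d",
                       n_state_shw, n_state_parental)
        return float("nan")
    return math.log2(n_state_shw / n_state_parental)


def intersect_lines(results: pd.DataFrame, genotypes=None):
    """State-combination counts across lines for one tissue.

    ``results`` needs columns triad_id, line, state, all from the same
    tissue/background.  Triads NE in any line are excluded from the
    combinations (reported in the returned NE tally); the remaining triads
    are partitioned over the 3^k AB/D/UN combinations.

    Returns (combo_counts, set_sizes, n_ne_excluded).
    """
    if genotypes is None:
        genotypes = sorted(results["line"].unique())
    wide = results.pivot(index="triad_id", columns="line", values="state")[list(genotypes)]
    if wide.isna().any().any():
        missing = {
            g: list(wide.index[wide[g].isna()][:5]) for g in genotypes if wide[g].isna().any()
        }
        raise ValueError(f"triad universes differ between lines: {missing}")
    ne_mask = (wide == "NE").any(axis=1)
    n_ne = int(ne_mask.sum())
    kept = wide[~ne_mask]
    combo = (
        kept.groupby(list(genotypes), sort=True).size().rename("n_triads").reset_index()
        .sort_values("n_triads", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    sizes = []
    for g in genotypes:
        vc = kept[g].value_counts()
        for state in ("AB", "D", "UN"):
            sizes.append({"line": g, "state": state, "set_size": int(vc.get(state, 0))})
    return combo, pd.DataFrame(sizes), n_ne


def trend_patterns(results: pd.DataFrame, tissue_order) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tissue bias trend of each triad for one line/background.

    Returns (pattern counts sorted descending, per-tissue state marginals
    for alluvial plotting).  Pattern keys join the states in the configured
    tissue order, e.g. "UN|UN|D".
    """
    tissue_order = list(tissue_order)
    wide = results.pivot(index="triad_id", columns="tissue", values="state")
    missing_t = [t for t in tissue_order if t not in wide.columns]
    if missing_t:
        raise ValueError(f"tissues absent from results: {missing_t}")
    wide = wide[tissue_order]
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)][0]
        raise ValueError(f"triad {bad!r} lacks a state in some tissue")
    keys = wide.apply("|".join, axis=1)
    patterns = (
        keys.value_counts().rename_axis("pattern_key").rename("n_triads").reset_index()
    )
    marginals = (
        wide.apply(pd.Series.value_counts).fillna(0).astype(int)
        .rename_axis("state").reset_index()
    )
    return patterns, marginals


TRANSITION_CATEGORIES = (
    "same_in_all_three",
    "same_in_1_2_only",
    "same_in_1_3_only",  # reversal: outer backgrounds agree, middle differs
    "same_in_2_3_only",
    "all_different",
)


def transition_categories(states_1: pd.Series, states_2: pd.Series,
                          states_3: pd.Series) -> pd.DataFrame:
    """Categorise each triad's state across three aligned backgrounds and
    report counts and percentages per category."""
    if not (states_1.index.equals(states_2.index) and states_1.index.equals(states_3.index)):
        raise ValueError("state vectors are misaligned (different triad indices)")
    s1, s2, s3 = (s.to_numpy() for s in (states_1, states_2, states_3))
    eq12, eq13, eq23 = s1 == s2, s1 == s3, s2 == s3
    cat = np.select(
        [eq12 & eq13, eq12 & ~eq13, eq13 & ~eq12, eq23 & ~eq12, ~eq12 & ~eq13 & ~eq23],
        TRANSITION_CATEGORIES,
        default="all_different",
    )
    counts = pd.Series(cat).value_counts()
    n = len(cat)
    return pd.DataFrame({
        "category": TRANSITION_CATEGORIES,
        "n_triads": [int(counts.get(c, 0)) for c in TRANSITION_CATEGORIES],
        "percent": [100.0 * counts.get(c, 0) / n for c in TRANSITION_CATEGORIES],
    })
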