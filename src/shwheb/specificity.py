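"""Tau tissue-specificity index and its association with bias state.

Tau for a gene with mean expression x_1..x_n over n tissues:

    tau = sum_i (1 - x_i / max_j x_j) / (n - 1)

Tau is 0 for perfectly uniform expression, 1 for expression confined to a
single tissue, and is invariant to rescaling the whole vector.  A gene is
called tissue-specific when tau >= cutoff (0.8 by default), with the argmax
tissue as its specific tissue.  Triads are then categorised by how many of
their homoeologues are specific and whether the specific ones share a
tissue, and the association between these categories and the AB/D bias
state is measured with a chi-square test of independence and Cramer's V:

    V = sqrt(chi2 / (n * (min(r, c) - 1)))
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .io import ExpressionMatrix, mean_expression

logger = logging.getLogger(__name__)


def tau(mean_expression_per_tissue) -> float:
    """Tau index in [0, 1]; NaN for an all-zero vector."""
    x = np.asarray(mean_expression_per_tissue, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs expression over at least 2 tissues")
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    m = x.max()
    if m == 0:
        return float("nan")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def tissue_means(expr: ExpressionMatrix, genotype: str, tissues=None,
                 log2_transform: bool = False) -> pd.DataFrame:
    """Replicate-mean expression per tissue (genes x tissues) for one
    genotype; optionally log2(x+1)-transformed before Tau."""
    meta = expr.meta
    sel = meta[meta["genotype_id"] == genotype]
    if len(sel) == 0:
        raise ValueError(f"no samples for genotype {genotype!r}")
    if tissues is None:
        tissues = list(dict.fromkeys(sel["tissue"]))
    cols = {}
    for t in tissues:
        grp = sel.loc[sel["tissue"] == t, "sample_id"]
        if len(grp) == 0:
            raise ValueError(f"genotype {genotype!r} has no samples in tissue {t!r}")
        cols[t] = mean_expression(expr, list(grp))
    out = pd.DataFrame(cols)
    if log2_transform:
        out = np.log2(out + 1.0)
    return out


def tau_profiles(means: pd.DataFrame, cutoff: float = 0.8) -> pd.DataFrame:
    """Per-gene tau and specific tissue (argmax, set only when tau >= cutoff)."""
    x = means.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    m = x.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.sum(1.0 - x / m[:, None], axis=1) / (x.shape[1] - 1)
    t[m == 0] = np.nan
    arg = means.columns.to_numpy()[x.argmax(axis=1)].astype(object)
    specific = pd.Series(arg, index=means.index)
    specific[(m == 0) | ~(t >= cutoff)] = None
    return pd.DataFrame({"tau": t, "specific_tissue": specific}, index=means.index)


@dataclass
class TriadSpecificity:
    n_specific: int           # homoeologues with tau >= cutoff (0-3)
    same_tissue: bool | None  # shared specific tissue (None unless n >= 2)
    subgenomes: str           # e.g. "D", "A+B", "A+B+D", "none"

    @property
    def category(self) -> str:
        if self.n_specific == 0:
            return "0"
        if self.n_specific == 1:
            return f"1:{self.subgenomes}"
        suffix = "same" if self.same_tissue else "different"
        return f"{self.n_specific}:{self.subgenomes}:{suffix}"


def classify_specificity(taus, specific_tissues, cutoff: float = 0.8) -> TriadSpecificity:
    """Triad-level specificity category from the (A, B, D) homoeologues'
    tau values and specific tissues; a missing tau (all-zero gene) counts
    as non-specific."""
    taus = list(taus)
    tiss = list(specific_tissues)
    if len(taus) != 3 or len(tiss) != 3:
        raise ValueError("expected exactly three homoeologues (A, B, D)")
    flags = [bool(t >= cutoff) if t == t else False for t in taus]  # NaN-safe
    subg = [g for g, f in zip("ABD", flags) if f]
    n = len(subg)
    same = None
    if n >= 2:
        spec_t = {tiss[i] for i, f in enumerate(flags) if f}
        same = len(spec_t) == 1
    return TriadSpecificity(n, same, "+".join(subg) if subg else "none")


def triad_specificity_table(tri: pd.DataFrame, profiles: pd.DataFrame,
                            cutoff: float = 0.8) -> pd.DataFrame:
    rows = []
    for _, r in tri.iterrows():
        taus = [profiles["tau"].get(r[f"gene_{s}"], float("nan")) for s in "ABD"]
        tiss = [profiles["specific_tissue"].get(r[f"gene_{s}"]) for s in "ABD"]
        c = classify_specificity(taus, tiss, cutoff=cutoff)
        rows.append({
            "triad_id": r["triad_id"],
            "n_specific": c.n_specific,
            "same_tissue": c.same_tissue,
            "subgenomes": c.subgenomes,
            "category": c.category,
        })
    return pd.DataFrame(rows)


@dataclass
class AssociationResult:
    chi2: float
    p: float
    cramers_v: float
    table: pd.DataFrame


def contingency_association(bias_states: pd.Series, categories: pd.Series) -> AssociationResult:
    """Chi-square test of independence (no continuity correction) between
    the AB/D bias state and the specificity category, with Cramer's V.

    Only AB- and D-biased triads enter the table; rows/columns with zero
    marginals are dropped with a warning.
    """
    df = pd.DataFrame({"state": bias_states, "category": categories}).dropna()
    df = df[df["state"].isin(["AB", "D"])]
    table = pd.crosstab(df["state"], df["category"])
    empty_rows = table.index[table.sum(axis=1) == 0]
    empty_cols = table.columns[table.sum(axis=0) == 0]
    if len(empty_rows) or len(empty_cols):
        logger.warning("dropping empty categories: rows=%s cols=%s",
                       list(empty_rows), list(empty_cols))
        table = table.drop(index=empty_rows, columns=empty_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 non-empty categories on both axes")
    res = chi2_contingency(table.to_numpy(), correction=False)
    if (res.expected_freq < 5).any():
        logger.warning("chi-square approximation: %d expected cells < 5",
                       int((res.expected_freq < 5).sum()))
    n = int(table.to_numpy().sum())
    v = float(np.sqrt(res.statistic / (n * (min(table.shape) - 1))))
    return AssociationResult(float(res.statistic), float(res.pvalue), v, table)
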