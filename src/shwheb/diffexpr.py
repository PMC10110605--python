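"""Whole-gene-set differential expression between a hexaploid line and its
parents, per subgenome, within vegetative and reproductive tissue pools.

The engine is a negative-binomial likelihood-ratio test with a gene-wise
method-of-moments dispersion and library-size normalisation factors scaled
to geometric mean 1.  For a gene with counts x_i, size factors s_i and
fixed dispersion phi, the NB mean is mu_i = q * s_i; the null fits one
common q, the alternative one q per group, and 2*deltaLL is referred to
chi-square with 1 df.  phi = 0 reduces exactly to the Poisson LRT.

Calls use the conventional thresholds FDR < 0.05 and |log2FC| >= 2, with
log2FC = log2 of the fitted normalised group means after adding a prior
count (0.5).  A- and B-subgenome genes are contrasted hexaploid vs
tetraploid parent, D-subgenome genes hexaploid vs diploid parent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import xlogy
from scipy.stats import chi2

from .heb import bh_adjust

logger = logging.getLogger(__name__)

VEGETATIVE_TISSUES = frozenset({"shoot", "root", "hypocotyl", "glume", "lemma_palea"})
REPRODUCTIVE_TISSUES = frozenset(
    {"boot_head", "pistil_AI", "pistil_AM", "pistil_1DAA", "anther"}
)
POOLS = ("vegetative", "reproductive")


def pool_samples(meta: pd.DataFrame) -> dict[str, list[str]]:
    """Partition samples into the vegetative and reproductive tissue pools."""
    unknown = set(meta["tissue"]) - VEGETATIVE_TISSUES - REPRODUCTIVE_TISSUES
    if unknown:
        raise ValueError(f"unknown tissue label(s): {sorted(unknown)}")
    veg = meta.loc[meta["tissue"].isin(VEGETATIVE_TISSUES), "sample_id"]
    rep = meta.loc[meta["tissue"].isin(REPRODUCTIVE_TISSUES), "sample_id"]
    return {"vegetative": list(veg), "reproductive": list(rep)}


def size_factors(library_sizes) -> np.ndarray:
    """Library sizes scaled to geometric mean 1."""
    n = np.asarray(library_sizes, dtype=float)
    if (n <= 0).any():
        raise ValueError("library sizes must be positive")
    return n / np.exp(np.mean(np.log(n)))


def estimate_dispersion(x1, x2, s1, s2) -> float | None:
    """Method-of-moments NB dispersion from the two groups' normalised
    counts: phi = max(0, (s2 - m) / m^2) with m the grand mean and s2 the
    pooled within-group variance.  Returns None (untested) for an all-zero
    gene; requires >= 2 samples per group."""
    y1 = np.asarray(x1, dtype=float) / np.asarray(s1, dtype=float)
    y2 = np.asarray(x2, dtype=float) / np.asarray(s2, dtype=float)
    if y1.size < 2 or y2.size < 2:
        raise ValueError("need at least 2 samples per group")
    if y1.sum() + y2.sum() == 0:
        return None
    m = np.concatenate([y1, y2]).mean()
    ss = ((y1 - y1.mean()) ** 2).sum() + ((y2 - y2.mean()) ** 2).sum()
    var = ss / (y1.size + y2.size - 2)
    return max(0.0, float((var - m) / m**2))


def _nb_loglik(x: np.ndarray, s: np.ndarray, q: float, phi: float) -> float:
    """NB log-likelihood terms that depend on the mean (constants dropped;
    phi is fixed across null and alternative so they cancel in the LRT)."""
    mu = q * s
    if phi == 0.0:
        return float(xlogy(x, mu).sum() - mu.sum())
    r = 1.0 / phi
    return float(xlogy(x, mu).sum() - ((x + r) * np.log1p(phi * mu)).sum())


def _nb_mle(x: np.ndarray, s: np.ndarray, phi: float) -> float:
    """MLE of the common normalised mean q for fixed phi (unique root of a
    monotone score function; closed form when phi = 0)."""
    if x.sum() == 0:
        return 0.0
    q0 = x.sum() / s.sum()
    if phi == 0.0:
        return float(q0)

    def score(q: float) -> float:
        w = phi * q * s
        return float(x.sum() - ((x + 1.0 / phi) * w / (1.0 + w)).sum())

    lo, hi = q0 * 1e-6, q0 * 1e6
    while score(lo) < 0:
        lo *= 1e-3
    while score(hi) > 0:
        hi *= 1e3
    return float(brentq(score, lo, hi, rtol=8.9e-16, maxiter=200))


@dataclass
class NbTestResult:
    logfc: float  # log2, group1 over group2
    p: float
    stat: float
    mu1: float  # fitted normalised mean, group 1
    mu2: float


def nb_test(x1, x2, s1, s2, phi: float, prior_count: float = 0.5) -> NbTestResult:
    """NB likelihood-ratio test of group1 vs group2 means at fixed phi."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    q1 = _nb_mle(x1, s1, phi)
    q2 = _nb_mle(x2, s2, phi)
    q0 = _nb_mle(np.concatenate([x1, x2]), np.concatenate([s1, s2]), phi)
    ll_alt = _nb_loglik(x1, s1, q1, phi) + _nb_loglik(x2, s2, q2, phi)
    ll_null = _nb_loglik(x1, s1, q0, phi) + _nb_loglik(x2, s2, q0, phi)
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    p = float(chi2.sf(stat, df=1))
    logfc = math.log2((q1 + prior_count) / (q2 + prior_count))
    return NbTestResult(logfc, p, stat, q1, q2)


def run_de(counts, gene_subgenomes: pd.Series, shw_genotype: str,
           tetra_genotype: str, diploid_genotype: str,
           prior_count: float = 0.5) -> pd.DataFrame:
    """Test every gene hexaploid-vs-parent within each tissue pool.

    A/B genes are contrasted against the tetraploid parent, D genes against
    the diploid parent.  Returns one row per tested gene x pool with logFC
    (SHW over parent), p and BH q (family = pool x contrast); all-zero
    genes are reported untested (NaN statistics).
    """
    meta = counts.meta
    mat = counts.counts
    frames = []
    for pool in POOLS:
        for parent, subgs in ((tetra_genotype, ("A", "B")), (diploid_genotype, ("D",))):
            genes = gene_subgenomes.index[gene_subgenomes.isin(subgs)]
            genes = genes.intersection(mat.index)
            g1 = pool_samples(meta[meta["genotype_id"] == shw_genotype])[pool]
            g2 = pool_samples(meta[meta["genotype_id"] == parent])[pool]
            if len(g1) < 2 or len(g2) < 2:
                raise ValueError(f"fewer than 2 samples in pool {pool!r}")
            libs = meta.loc[list(g1) + list(g2), "library_size"]
            s = size_factors(libs.to_numpy())
            s1, s2 = s[: len(g1)], s[len(g1):]
            x1 = mat.loc[genes, g1].to_numpy(dtype=float)
            x2 = mat.loc[genes, g2].to_numpy(dtype=float)
            recs = []
            for i, g in enumerate(genes):
                phi = estimate_dispersion(x1[i], x2[i], s1, s2)
                if phi is None:
                    recs.append((g, np.nan, np.nan, np.nan, False))
                    continue
                r = nb_test(x1[i], x2[i], s1, s2, phi, prior_count=prior_count)
                recs.append((g, r.logfc, r.stat, r.p, True))
            df = pd.DataFrame(recs, columns=["gene_id", "logfc", "stat", "p", "tested"])
            df["subgenome"] = gene_subgenomes.loc[df["gene_id"]].to_numpy()
            df["pool"] = pool
            df["contrast"] = f"{shw_genotype}_vs_{parent}"
            df["q"] = np.nan
            tested = df["tested"].to_numpy()
            if tested.any():
                df.loc[tested, "q"] = bh_adjust(df.loc[tested, "p"].to_numpy())
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[["gene_id", "subgenome", "pool", "contrast",
                "logfc", "stat", "p", "q", "tested"]]


def call_de(results: pd.DataFrame, fdr: float = 0.05, lfc: float = 2.0):
    """Apply the FDR/logFC thresholds and summarise up/down counts.

    Returns (results with a ``call`` column in {up, down, ns}, summary
    counts per subgenome x pool x contrast).
    """
    out = results.copy()
    sig = out["tested"] & (out["q"] < fdr)
    out["call"] = "ns"
    out.loc[sig & (out["logfc"] >= lfc), "call"] = "up"
    out.loc[sig & (out["logfc"] <= -lfc), "call"] = "down"
    summary = (
        out.groupby(["subgenome", "pool", "contrast"])["call"]
        .value_counts().unstack(fill_value=0)
        .reindex(columns=["up", "down", "ns"], fill_value=0)
        .reset_index()
    )
    return out, summary
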