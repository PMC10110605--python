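"""Homoeologue expression bias (HEB) and the AB-vs-D likelihood-ratio test.

For each triad the bias statistic is

    HEB = log2( RPKM_D / RPKM_AB ),   RPKM_AB = (RPKM_A + RPKM_B) / 2

so HEB > 0 means the D homoeologue is expressed above the mean of its A and
B partners and HEB < 0 the opposite.  Significance is assessed with a
Poisson rate model: in each replicate r of a context,

    x_A,r ~ Poisson(e_A * l_A * N_AB,r)
    x_B,r ~ Poisson(e_B * l_B * N_AB,r)
    x_D,r ~ Poisson(e_D * l_D * N_D,r)

with e_g the per-base expression rate (reads per bp per mapped read),
shared across replicates; gene lengths l_g and library sizes N enter the
rate directly, so length and depth differences between homoeologues are
accounted for.  The null of no AB-vs-D difference constrains
e_D = (e_A + e_B) / 2; the statistic 2*(ll_alt - ll_null) is referred to a
chi-square with 1 df.

Contexts declare which libraries supply the AB side and the D side: in a
hexaploid (SHW) context both sides come from the same libraries, while the
"in-silico" parental context pairs tetraploid (AB) with diploid (D)
libraries replicate-by-replicate, emulating a hexaploid without
inter-subgenome interaction.
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
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, compute_rpkm, mean_expression

logger = logging.getLogger(__name__)

BIAS_STATES = ("AB", "D", "UN", "NE")


# ---------------------------------------------------------------------------
# HEB value

def compute_heb(rpkm_a: float, rpkm_b: float, rpkm_d: float, cap: float = 10.0) -> float:
    """log2(D / mean(A,B)); +-cap when exactly one side is zero, NaN when both are."""
    if rpkm_a < 0 or rpkm_b < 0 or rpkm_d < 0:
        raise ValueError("RPKM values must be non-negative")
    ab = 0.5 * (rpkm_a + rpkm_b)
    if ab == 0.0 and rpkm_d == 0.0:
        return float("nan")
    if rpkm_d == 0.0:
        return -cap
    if ab == 0.0:
        return cap
    return math.log2(rpkm_d / ab)


def _heb_vector(mean_a, mean_b, mean_d, cap: float) -> np.ndarray:
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    d = np.asarray(mean_d, dtype=float)
    ab = 0.5 * (a + b)
    out = np.full(a.shape, np.nan)
    both = (ab == 0) & (d == 0)
    dzero = (d == 0) & ~both
    abzero = (ab == 0) & ~both
    ok = ~(both | dzero | abzero)
    out[dzero] = -cap
    out[abzero] = cap
    out[ok] = np.log2(d[ok] / ab[ok])
    return out


# ---------------------------------------------------------------------------
# Contexts

@dataclass
class BiasContext:
    """Declares which samples supply the AB side and the D side of a test."""

    context_id: str
    background: str  # "SHW" | "parental_insilico" | "reference_hexaploid"
    tissue: str
    ab_samples: list[str]
    d_samples: list[str]
    replicate_pairing: list[tuple[str, str]]
    line: str | None = None  # SHW line (or parent pair) this context summarises


def build_shw_context(genotype: str, tissue: str, meta: pd.DataFrame,
                      background: str = "SHW") -> BiasContext:
    """Context where AB and D homoeologue counts come from the same hexaploid
    libraries."""
    sel = meta[(meta["genotype_id"] == genotype) & (meta["tissue"] == tissue)]
    if len(sel) == 0:
        raise ValueError(f"no samples for genotype {genotype!r}, tissue {tissue!r}")
    samples = list(sel.sort_values("replicate")["sample_id"])
    return BiasContext(
        context_id=f"{genotype}:{tissue}:{background}",
        background=background,
        tissue=tissue,
        ab_samples=samples,
        d_samples=samples,
        replicate_pairing=[(s, s) for s in samples],
        line=genotype,
    )


def build_insilico_context(tetra_genotype: str, diploid_genotype: str, tissue: str,
                           meta: pd.DataFrame) -> BiasContext:
    """Virtual hexaploid: tetraploid libraries supply A/B counts, diploid
    libraries supply D counts, paired by sorted replicate index; unpaired
    extras are dropped with a warning."""
    tet = meta[(meta["genotype_id"] == tetra_genotype) & (meta["tissue"] == tissue)]
    dip = meta[(meta["genotype_id"] == diploid_genotype) & (meta["tissue"] == tissue)]
    if len(tet) == 0 or len(dip) == 0:
        raise ValueError(
            f"tissue {tissue!r} has no replicates for "
            f"{tetra_genotype!r} and/or {diploid_genotype!r}"
        )
    tet_s = list(tet.sort_values("replicate")["sample_id"])
    dip_s = list(dip.sort_values("replicate")["sample_id"])
    k = min(len(tet_s), len(dip_s))
    if len(tet_s) != len(dip_s):
        logger.warning(
            "unequal replicate numbers (%d tetraploid, %d diploid) for %s x %s %s; "
            "using first %d pairs",
            len(tet_s), len(dip_s), tetra_genotype, diploid_genotype, tissue, k,
        )
    pairs = list(zip(tet_s[:k], dip_s[:k]))
    return BiasContext(
        context_id=f"{tetra_genotype}x{diploid_genotype}:{tissue}:parental",
        background="parental_insilico",
        tissue=tissue,
        ab_samples=[a for a, _ in pairs],
        d_samples=[d for _, d in pairs],
        replicate_pairing=pairs,
        line=f"{tetra_genotype}x{diploid_genotype}",
    )


def design_contexts(meta: pd.DataFrame, parent_map: dict[str, tuple[str, str]],
                    tissues=None) -> list[BiasContext]:
    """All SHW contexts plus the matching parental in-silico contexts for a
    full design; ``parent_map`` maps each hexaploid genotype to its
    (tetraploid, diploid) parents."""
    if tissues is None:
        tissues = list(dict.fromkeys(meta["tissue"]))
    ctxs: list[BiasContext] = []
    for hexa, (tetra, dip) in parent_map.items():
        for t in tissues:
            ctxs.append(build_shw_context(hexa, t, meta))
    seen = set()
    for hexa, (tetra, dip) in parent_map.items():
        for t in tissues:
            key = (tetra, dip, t)
            if key in seen:
                continue
            seen.add(key)
            ctxs.append(build_insilico_context(tetra, dip, t, meta))
    return ctxs


# ---------------------------------------------------------------------------
# Likelihood-ratio test

@dataclass
class TriadModelFit:
    e_A: float
    e_B: float
    e_D: float
    e_A0: float
    e_B0: float
    loglik_alt: float
    loglik_null: float


@dataclass
class LrtResult:
    lrt_stat: float
    p: float
    fit: TriadModelFit


def _null_objective(a: float, b: float, sa: float, sb: float, sd: float,
                    ca: float, cb: float) -> float:
    return (xlogy(sa, a) + xlogy(sb, b) + xlogy(sd, 0.5 * (a + b))
            - a * ca - b * cb)


def _null_mle(sa: float, sb: float, sd: float, ca: float, cb: float) -> tuple[float, float]:
    """Exact maximiser of the constrained Poisson log-likelihood
    f(a,b) = sa*ln a + sb*ln b + sd*ln((a+b)/2) - a*ca - b*cb over a,b >= 0.

    Interior stationary points satisfy a = sa/(ca-u), b = sb/(cb-u) with
    u = sd/(a+b), reducing the problem to a monotone 1-D root-find in u;
    boundary cases (any of the count sums zero) have closed forms.
    """
    if sd == 0.0:
        return (sa / ca if sa > 0 else 0.0, sb / cb if sb > 0 else 0.0)
    if sa == 0.0 and sb == 0.0:
        return (sd / ca, 0.0) if ca <= cb else (0.0, sd / cb)
    if sa == 0.0 or sb == 0.0:
        # one AB homoeologue unobserved: compare the axis optimum with the
        # interior KKT candidate (mass on the cheaper gene), both closed form
        if sb == 0.0:
            sa, sb, ca, cb, flip = 0.0, sa, cb, ca, True
        else:
            flip = False
        cands = [(0.0, (sb + sd) / cb)]
        if cb > ca and sd / ca > sb / (cb - ca):
            b1 = sb / (cb - ca)
            cands.append((sd / ca - b1, b1))
        a, b = max(cands, key=lambda ab: _null_objective(*ab, 0.0, sb, sd, ca, cb))
        return (b, a) if flip else (a, b)

    cmin = min(ca, cb)

    def g(u: float) -> float:
        return sa / (ca - u) + sb / (cb - u) - sd / u

    lo = cmin * 1e-12
    while g(lo) > 0 and lo > cmin * 1e-300:
        lo *= 1e-6
    hi = cmin * (1.0 - 1e-13)
    u = brentq(g, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    return sa / (ca - u), sb / (cb - u)


def _lrt_from_sums(sa: float, sb: float, sd: float, la: float, lb: float, ld: float,
                   t_ab: float, t_d: float):
    """Core LRT from replicate-summed counts; returns (stat, p, fit)."""
    ea = sa / (la * t_ab)
    eb = sb / (lb * t_ab)
    ed = sd / (ld * t_d)
    ll_alt = xlogy(sa, ea) + xlogy(sb, eb) + xlogy(sd, ed) - (sa + sb + sd)
    ca = la * t_ab + 0.5 * ld * t_d
    cb = lb * t_ab + 0.5 * ld * t_d
    a0, b0 = _null_mle(sa, sb, sd, ca, cb)
    ll_null = _null_objective(a0, b0, sa, sb, sd, ca, cb)
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    p = float(chi2.sf(stat, df=1))
    return stat, p, TriadModelFit(ea, eb, ed, a0, b0, ll_alt, ll_null)


def lrt_triad(x_a, x_b, x_d, lengths, lib_ab, lib_d) -> LrtResult | None:
    """AB-vs-D likelihood-ratio test for one triad in one context.

    Parameters are per-replicate count vectors for the A, B and D
    homoeologues, the (l_A, l_B, l_D) gene lengths in bp, and the library
    sizes of the AB-side and D-side samples.  Returns ``None`` (the
    not-expressed sentinel) when every count is zero.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    x_d = np.asarray(x_d, dtype=float)
    lib_ab = np.asarray(lib_ab, dtype=float)
    lib_d = np.asarray(lib_d, dtype=float)
    if x_a.size == 0 or x_a.size != lib_ab.size or x_d.size != lib_d.size:
        raise ValueError("need >=1 replicate with matching library sizes")
    for x in (x_a, x_b, x_d):
        if (x < 0).any() or (x % 1 != 0).any():
            raise ValueError("counts must be non-negative integers")
    la, lb, ld = (float(v) for v in lengths)
    if min(la, lb, ld) <= 0:
        raise ValueError("gene lengths must be positive")
    if x_a.sum() + x_b.sum() + x_d.sum() == 0:
        return None
    stat, p, fit = _lrt_from_sums(
        x_a.sum(), x_b.sum(), x_d.sum(), la, lb, ld, lib_ab.sum(), lib_d.sum()
    )
    return LrtResult(stat, p, fit)


# ---------------------------------------------------------------------------
# Multiple testing and classification

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "bh":
        return bh_adjust(p)
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "none":
        return p.copy()
    raise ValueError(f"unknown multiple-testing method {method!r}")


def classify_triads(heb, q, mean_a, mean_b, mean_d, alpha: float = 0.05,
                    ne_threshold: float = 0.5) -> np.ndarray:
    """Assign AB / D / UN / NE states.

    NE: all three homoeologues below the expression floor (mean RPKM <
    ne_threshold).  Otherwise D (q <= alpha, HEB > 0), AB (q <= alpha,
    HEB < 0), else UN.  A significant q with HEB exactly 0 has no direction
    and is classified UN (logged).
    """
    heb = np.asarray(heb, dtype=float)
    q = np.asarray(q, dtype=float)
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    d = np.asarray(mean_d, dtype=float)
    ne = (a < ne_threshold) & (b < ne_threshold) & (d < ne_threshold)
    sig = ~ne & ~np.isnan(q) & (q <= alpha)
    states = np.where(ne, "NE", "UN").astype(object)
    states[sig & (heb > 0)] = "D"
    states[sig & (heb < 0)] = "AB"
    tied = sig & (heb == 0)
    if tied.any():
        logger.warning("%d significant triads with HEB exactly 0 classified UN",
                       int(tied.sum()))
    return states.astype(str)


# ---------------------------------------------------------------------------
# Orchestration

@dataclass
class HebConfig:
    alpha: float = 0.05
    ne_threshold: float = 0.5  # mean RPKM floor for "not expressed"
    heb_cap: float = 10.0
    mtc: str = "bh"  # "bh" | "bonferroni" | "none"


RESULT_COLUMNS = ("triad_id", "context_id", "tissue", "background",
                  "heb", "lrt_stat", "p", "q", "state")


def run_heb(counts: CountMatrix, triads: pd.DataFrame, contexts: list[BiasContext],
            config: HebConfig | None = None) -> pd.DataFrame:
    """Run the full bias analysis: one result row per triad x context.

    The FDR family is each context separately (per tissue x background),
    with NE triads excluded from the family.  Deterministic for identical
    inputs.
    """
    config = config or HebConfig()
    expr = compute_rpkm(counts)
    meta = counts.meta
    out_frames = []
    for ctx in contexts:
        mean_a = mean_expression(expr, ctx.ab_samples).loc[triads["gene_A"]].to_numpy()
        mean_b = mean_expression(expr, ctx.ab_samples).loc[triads["gene_B"]].to_numpy()
        mean_d = mean_expression(expr, ctx.d_samples).loc[triads["gene_D"]].to_numpy()

        xa = counts.counts.loc[triads["gene_A"], ctx.ab_samples].to_numpy(dtype=float)
        xb = counts.counts.loc[triads["gene_B"], ctx.ab_samples].to_numpy(dtype=float)
        xd = counts.counts.loc[triads["gene_D"], ctx.d_samples].to_numpy(dtype=float)
        t_ab = float(meta.loc[ctx.ab_samples, "library_size"].sum())
        t_d = float(meta.loc[ctx.d_samples, "library_size"].sum())
        la = triads["len_A"].to_numpy(dtype=float)
        lb = triads["len_B"].to_numpy(dtype=float)
        ld = triads["len_D"].to_numpy(dtype=float)
        sa, sb, sd = xa.sum(axis=1), xb.sum(axis=1), xd.sum(axis=1)

        n = len(triads)
        heb = _heb_vector(mean_a, mean_b, mean_d, config.heb_cap)
        ne = ((mean_a < config.ne_threshold) & (mean_b < config.ne_threshold)
              & (mean_d < config.ne_threshold))
        stat = np.full(n, np.nan)
        p = np.full(n, np.nan)
        for i in np.nonzero(~ne)[0]:
            if sa[i] + sb[i] + sd[i] == 0:
                continue  # nothing observed; stays untested (classified NE below)
            stat[i], p[i], _ = _lrt_from_sums(
                sa[i], sb[i], sd[i], la[i], lb[i], ld[i], t_ab, t_d
            )
        ne = ne | np.isnan(p)
        q = np.full(n, np.nan)
        tested = ~ne
        if tested.any():
            q[tested] = _adjust(p[tested], config.mtc)
        states = classify_triads(heb, q, mean_a, mean_b, mean_d,
                                 alpha=config.alpha, ne_threshold=config.ne_threshold)
        states[ne] = "NE"
        heb = heb.copy()
        heb[ne] = np.nan
        stat[ne] = np.nan
        p[ne] = np.nan
        out_frames.append(pd.DataFrame({
            "triad_id": triads["triad_id"].to_numpy(),
            "context_id": ctx.context_id,
            "tissue": ctx.tissue,
            "background": ctx.background,
            "line": ctx.line,
            "heb": heb,
            "lrt_stat": stat,
            "p": p,
            "q": q,
            "state": states,
        }))
    out = pd.concat(out_frames, ignore_index=True)
    return out.sort_values(["context_id", "triad_id"], kind="mergesort").reset_index(drop=True)
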