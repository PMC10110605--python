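"""Synthetic allopolyploid triad counts with known ground truth.

The generator emulates the study design the analysis assumes: eight
genotypes (two diploid DD, two tetraploid AABB, four hexaploid AABBDD
lines, each hexaploid tied to one tetraploid x diploid parent pair), ten
tissues, three replicates, and a triad table of 1:1:1 homoeologue sets.

Per-base expression rates e_g (reads per bp per mapped read) are drawn
log-normally per triad and shared within a triad; bias is injected by
scaling the D homoeologue's rate by 2^(+-effect); the hexaploid background
additionally represses the D rate of a configurable fraction of triads by
a global factor, mimicking post-polyploidization suppression of the
D subgenome.  There are two truth backgrounds (parental and SHW):
genotypes of the same ploidy class share rates and differ only by
sampling noise.  Counts are negative binomial with mean e*l*N and shared
dispersion phi (Poisson when phi = 0).

The ground truth records, per triad x tissue x background, the three rates
and the implied bias state, so every pipeline stage can be scored without
external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TISSUES, CountMatrix

DIPLOIDS = ("AS2386", "AS2399")
TETRAPLOIDS = ("PI377655", "Langdon")
#: hexaploid line -> (tetraploid, diploid) parents
SHW_PARENTS = {
    "C44": ("Langdon", "AS2386"),
    "C45": ("Langdon", "AS2399"),
    "C65": ("PI377655", "AS2399"),
    "C66": ("PI377655", "AS2386"),
}


@dataclass
class SimConfig:
    """Study-condition knobs for the count simulator (seed is mandatory)."""

    seed: int
    n_triads: int = 18357
    tissues: tuple = TISSUES
    n_replicates: int = 3
    library_size: int | tuple[int, int] = 20_000_000
    length_meanlog: float = 7.3   # median ~1480 bp
    length_sdlog: float = 0.45
    rate_meanlog: float = -19.11  # ln(5e-9): median RPKM ~5 at any depth
    rate_sdlog: float = 1.0
    phi: float = 0.0              # NB dispersion; 0 = Poisson
    frac_d_biased: float = 0.0
    frac_ab_biased: float = 0.0
    effect_d: float = 2.0         # log2 D-over-AB effect for D-biased triads
    effect_ab: float = 2.0        # log2 AB-over-D effect for AB-biased triads
    d_repression_factor: float = 1.0  # multiplies hexaploid e_D of repressed triads
    repressed_fraction: float = 1.0
    tissue_sdlog: float = 0.3     # triad x tissue lognormal factor (ratio-preserving)
    tissue_specific_fraction: float = 0.0  # per-gene probability of specificity
    specificity_concentration: float = 0.95  # expression mass in the target tissue
    un_band: float = 0.25         # |log2 ratio| below this is "UN" truth

    def validate(self) -> None:
        for name in ("frac_d_biased", "frac_ab_biased", "repressed_fraction",
                     "tissue_specific_fraction", "specificity_concentration"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_d_biased + self.frac_ab_biased > 1.0:
            raise ValueError("bias fractions must sum to <= 1")
        if self.effect_d <= 0 or self.effect_ab <= 0:
            raise ValueError("effect sizes must be positive")
        if self.phi < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_triads < 1 or self.n_replicates < 1 or len(self.tissues) < 1:
            raise ValueError("need >= 1 triad, replicate and tissue")


@dataclass
class SimData:
    counts: CountMatrix
    triads: pd.DataFrame
    truth: pd.DataFrame       # triad x tissue x background rates and true state
    gene_truth: pd.DataFrame  # per-gene tissue-specificity target class
    config: SimConfig


def _truth_state(log2_ratio: np.ndarray, band: float) -> np.ndarray:
    return np.select([log2_ratio > band, log2_ratio < -band], ["D", "AB"], default="UN")


def generate(config: SimConfig) -> SimData:
    """Draw the full eight-genotype design described by ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_triads
    tissues = list(config.tissues)
    nt = len(tissues)

    triad_ids = np.array([f"T{i:05d}" for i in range(1, n + 1)])
    genes = {s: np.array([f"g{i:05d}{s}" for i in range(1, n + 1)]) for s in "ABD"}
    lengths = {
        s: np.maximum(
            200, rng.lognormal(config.length_meanlog, config.length_sdlog, n)
        ).round()
        for s in "ABD"
    }
    triads = pd.DataFrame({
        "triad_id": triad_ids,
        "gene_A": genes["A"], "gene_B": genes["B"], "gene_D": genes["D"],
        "len_A": lengths["A"].astype(int), "len_B": lengths["B"].astype(int),
        "len_D": lengths["D"].astype(int),
    })

    base = rng.lognormal(config.rate_meanlog, config.rate_sdlog, n)
    cls = rng.choice(
        ["D", "AB", "UN"], size=n,
        p=[config.frac_d_biased, config.frac_ab_biased,
           1.0 - config.frac_d_biased - config.frac_ab_biased],
    )
    e_par = {"A": base.copy(), "B": base.copy(), "D": base.copy()}
    e_par["D"][cls == "D"] *= 2.0 ** config.effect_d
    e_par["D"][cls == "AB"] *= 2.0 ** -config.effect_ab
    repressed = rng.random(n) < config.repressed_fraction
    e_shw = {s: e_par[s].copy() for s in "ABD"}
    e_shw["D"][repressed] *= config.d_repression_factor

    # triad x tissue factor shared by all three homoeologues (ratio-preserving)
    tissue_factor = rng.lognormal(0.0, config.tissue_sdlog, size=(n, nt))
    # per-gene specificity profile (can break the ratio in individual tissues)
    spec_mult = {}
    gene_truth_rows = []
    for s in "ABD":
        is_spec = rng.random(n) < config.tissue_specific_fraction
        target = rng.integers(0, nt, size=n)
        mult = np.ones((n, nt))
        c = config.specificity_concentration
        off = (1.0 - c) / max(nt - 1, 1)
        mult[is_spec] = off * nt
        mult[is_spec, target[is_spec]] = c * nt
        spec_mult[s] = mult
        gene_truth_rows.append(pd.DataFrame({
            "gene_id": genes[s],
            "subgenome": s,
            "tissue_specific": is_spec,
            "target_tissue": np.where(is_spec, np.array(tissues)[target], None),
        }))
    gene_truth = pd.concat(gene_truth_rows, ignore_index=True)

    # per-gene per-tissue rates for both truth backgrounds
    rates = {
        bg: {s: e[s][:, None] * tissue_factor * spec_mult[s] for s in "ABD"}
        for bg, e in (("parental", e_par), ("SHW", e_shw))
    }

    truth_frames = []
    for bg in ("parental", "SHW"):
        r = rates[bg]
        ratio = np.log2(r["D"] / (0.5 * (r["A"] + r["B"])))
        for j, t in enumerate(tissues):
            truth_frames.append(pd.DataFrame({
                "triad_id": triad_ids,
                "tissue": t,
                "background": bg,
                "e_A": r["A"][:, j], "e_B": r["B"][:, j], "e_D": r["D"][:, j],
                "log2_ratio": ratio[:, j],
                "true_state": _truth_state(ratio[:, j], config.un_band),
                "sim_class": cls,
                "repressed": repressed,
            }))
    truth = pd.concat(truth_frames, ignore_index=True)

    # samples: fixed genotype -> ploidy -> subgenome presence
    genotype_plan = (
        [(g, "diploid_DD", ("D",), "parental") for g in DIPLOIDS]
        + [(g, "tetraploid_AABB", ("A", "B"), "parental") for g in TETRAPLOIDS]
        + [(g, "hexaploid_AABBDD", ("A", "B", "D"), "SHW") for g in SHW_PARENTS]
    )
    gene_order = np.concatenate([genes[s] for s in "ABD"])
    len_order = np.concatenate([lengths[s] for s in "ABD"])

    meta_rows, columns = [], {}
    for geno, ploidy, present, bg in genotype_plan:
        for j, t in enumerate(tissues):
            for rep in range(1, config.n_replicates + 1):
                sid = f"{geno}_{t}_r{rep}"
                if isinstance(config.library_size, tuple):
                    lo, hi = config.library_size
                    lib = int(rng.integers(lo, hi + 1))
                else:
                    lib = int(config.library_size)
                mean = np.concatenate([
                    rates[bg][s][:, j] * lengths[s] * lib
                    if s in present else np.zeros(n)
                    for s in "ABD"
                ])
                if config.phi == 0.0:
                    x = rng.poisson(mean)
                else:
                    r_nb = 1.0 / config.phi
                    x = np.where(
                        mean > 0,
                        rng.negative_binomial(r_nb, r_nb / (r_nb + np.maximum(mean, 1e-300))),
                        0,
                    )
                columns[sid] = x.astype(np.int64)
                meta_rows.append({
                    "sample_id": sid, "genotype_id": geno, "ploidy": ploidy,
                    "tissue": t, "replicate": rep, "library_size": lib,
                })

    counts_df = pd.DataFrame(columns, index=pd.Index(gene_order, name="gene_id"))
    meta = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    gene_lengths = pd.Series(len_order, index=gene_order, dtype=float)
    return SimData(CountMatrix(counts_df, meta, gene_lengths), triads, truth,
                   gene_truth, config)


def preset_headline(seed: int, n_triads: int = 1000) -> SimConfig:
    """The headline study conditions: a parental background dominated by
    D-biased triads (30% D- vs 8% AB-biased at |log2 effect| 2) and a
    hexaploid background that represses e_D of 85% of triads 4-fold, so
    that D-bias largely disappears and AB-bias increases upon
    polyploidization.  A modest fraction (10%) of genes is tissue-specific.
    """
    return SimConfig(
        seed=seed,
        n_triads=n_triads,
        frac_d_biased=0.30,
        frac_ab_biased=0.08,
        effect_d=2.0,
        effect_ab=2.0,
        d_repression_factor=0.25,
        repressed_fraction=0.85,
        tissue_specific_fraction=0.10,
    )


def preset_null(seed: int, n_triads: int = 2000, tissues=("shoot",)) -> SimConfig:
    """All-null conditions for calibration checks: no bias, no repression,
    no tissue specificity, Poisson counts."""
    return SimConfig(seed=seed, n_triads=n_triads, tissues=tuple(tissues),
                     tissue_sdlog=0.0)


def preset_d_repression_de(seed: int, n_triads: int = 400) -> SimConfig:
    """Differential-expression conditions: no triad-level bias, but 20% of
    triads have their D homoeologue repressed ~6.7-fold in the hexaploid."""
    return SimConfig(seed=seed, n_triads=n_triads,
                     d_repression_factor=0.15, repressed_fraction=0.20)


def write_fixture(sim: SimData, outdir) -> dict[str, str]:
    """Write counts.tsv, meta.tsv, triads.tsv, truth.tsv and gene_truth.tsv
    in the formats the readers accept; byte-identical for the same seed."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    counts = sim.counts.counts.copy()
    counts.insert(0, "gene_id", counts.index)
    specs = {
        "counts": counts,
        "meta": sim.counts.meta.reset_index(drop=True),
        "triads": sim.triads,
        "truth": sim.truth,
        "gene_truth": sim.gene_truth,
    }
    for name, df in specs.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.10g", na_rep="NA")
        paths[name] = str(p)
    return paths


def score_calls(results: pd.DataFrame, truth: pd.DataFrame,
                effect: float | None = None, tol: float = 1e-9):
    """Sensitivity and false-direction rate of pipeline state calls against
    the simulator truth.

    Joins result rows to truth rows on (triad, tissue, background); when
    ``effect`` is given only truth rows whose |log2 ratio| equals that
    effect (within tol) are scored.  Sensitivity counts a truly biased
    triad as recovered only when called in the correct direction; a
    significant call in the opposite direction is a false direction.
    """
    res = results.copy()
    res["background"] = res["background"].replace({"parental_insilico": "parental"})
    merged = res.merge(truth, on=["triad_id", "tissue", "background"], how="inner",
                       suffixes=("", "_truth"))
    biased = merged[merged["true_state"].isin(["AB", "D"])]
    if effect is not None:
        biased = biased[(biased["log2_ratio"].abs() - effect).abs() <= tol]
    if len(biased) == 0:
        raise ValueError("no truth rows at the requested effect size")
    correct = (biased["state"] == biased["true_state"]).mean()
    opposite = biased["state"].isin(["AB", "D"]) & (biased["state"] != biased["true_state"])
    return {
        "sensitivity": float(correct),
        "false_direction_rate": float(opposite.mean()),
        "n_scored": int(len(biased)),
    }
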