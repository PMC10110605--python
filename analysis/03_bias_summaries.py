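"""Summarise the bias calls: LogFC ratios, line intersections, tissue
trends, and cross-line transitions.

Reproduces the comparative views of the bias landscape: within-background
log2(n_D/n_AB) per context, between-background log2 state-count ratios,
UpSet-style state intersections across the four SHW lines in one tissue,
cross-tissue trend patterns for one line, and transition categories of
each triad across three lines.
"""

import argparse

import pandas as pd

import shwheb as sw
from shwheb.comparative import (
    between_background_logfc,
    intersect_lines,
    summarize_counts,
    transition_categories,
    trend_patterns,
    within_background_logfc,
)

from _common import RESULTS, load_or_simulate


def main(seed: int = 42) -> None:
    sim = load_or_simulate(seed)
    try:
        results = sw.read_results(RESULTS / "bias.tsv")
    except FileNotFoundError:
        ctxs = sw.design_contexts(sim.counts.meta, sw.SHW_PARENTS)
        results = sw.run_heb(sim.counts, sim.triads, ctxs)

    counts = summarize_counts(results)
    counts["within_logfc"] = [
        within_background_logfc(a, d) for a, d in zip(counts["n_AB"], counts["n_D"])
    ]
    # between-background ratios per line x tissue x state
    rows = []
    for line, (tetra, dip) in sw.SHW_PARENTS.items():
        for tissue in sim.config.tissues:
            shw = counts[(counts["line"] == line) & (counts["tissue"] == tissue)].iloc[0]
            par = counts[(counts["line"] == f"{tetra}x{dip}")
                         & (counts["tissue"] == tissue)].iloc[0]
            for state, col in (("AB", "n_AB"), ("D", "n_D")):
                rows.append({
                    "line": line, "tissue": tissue, "state": state,
                    "between_logfc": between_background_logfc(shw[col], par[col]),
                })
    sw.write_results(counts, RESULTS / "within_background_logfc.tsv")
    sw.write_results(pd.DataFrame(rows), RESULTS / "between_background_logfc.tsv")

    shoot = results[(results["background"] == "SHW") & (results["tissue"] == "shoot")]
    combo, sizes, n_ne = intersect_lines(shoot[["triad_id", "line", "state"]])
    sw.write_results(combo, RESULTS / "intersections_shoot.tsv")

    c66 = results[(results["line"] == "C66") & (results["background"] == "SHW")]
    patterns, marginals = trend_patterns(c66, sim.config.tissues)
    sw.write_results(patterns, RESULTS / "trend_patterns_C66.tsv")
    sw.write_results(marginals, RESULTS / "trend_marginals_C66.tsv")

    three = {
        line: shoot[shoot["line"] == line].set_index("triad_id")["state"].sort_index()
        for line in ("C44", "C45", "C66")
    }
    trans = transition_categories(three["C44"], three["C45"], three["C66"])
    sw.write_results(trans, RESULTS / "transitions_shoot.tsv")

    par = counts[counts["background"] == "parental_insilico"]["within_logfc"]
    shw_fc = counts[counts["background"] == "SHW"]["within_logfc"]
    print(f"within-background LogFC: parental {par.min():.2f}..{par.max():.2f} (all > 0), "
          f"SHW {shw_fc.min():.2f}..{shw_fc.max():.2f}")
    print(f"shoot intersections: top pattern {tuple(combo.iloc[0][:-1])} "
          f"x{combo.iloc[0]['n_triads']}, {n_ne} triads NE-excluded")
    print(f"top C66 trend pattern: {patterns.iloc[0]['pattern_key']} "
          f"({patterns.iloc[0]['n_triads']} triads)")
    print(trans.to_string(index=False))


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    main(**vars(ap.parse_args()))
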