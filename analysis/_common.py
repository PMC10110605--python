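"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

import shwheb as sw

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
FIXTURES = RESULTS / "fixtures"


def load_or_simulate(seed: int = 42):
    """Return (sim-style bundle) from the on-disk fixture, regenerating it
    when absent or written under a different seed."""
    marker = FIXTURES / f"seed_{seed}.txt"
    if not marker.exists():
        sim = sw.generate(sw.preset_headline(seed))
        sw.write_fixture(sim, FIXTURES)
        marker.parent.mkdir(parents=True, exist_ok=True)
        for old in FIXTURES.glob("seed_*.txt"):
            old.unlink()
        marker.write_text("headline preset\n")
        return sim
    import pandas as pd

    counts = sw.read_counts(FIXTURES / "counts.tsv", FIXTURES / "meta.tsv")
    triads = sw.read_triads(FIXTURES / "triads.tsv")
    counts = counts.with_lengths(sw.triad_gene_lengths(triads))
    truth = pd.read_csv(FIXTURES / "truth.tsv", sep="\t", na_values=["NA"])
    gene_truth = pd.read_csv(FIXTURES / "gene_truth.tsv", sep="\t", na_values=["NA"])
    return sw.SimData(counts, triads, truth, gene_truth, sw.preset_headline(seed))
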