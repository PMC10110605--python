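# shwheb — homoeologue expression bias in synthetic hexaploid wheat

`shwheb` analyses how the balance of expression between wheat subgenomes
shifts upon allopolyploidization. Bread wheat triads — genes present in a
1:1:1 copy on the A, B and D subgenomes — let one compare the D
homoeologue against the mean of its A and B partners, both in a synthetic
hexaploid (SHW, AABBDD) and in an "in-silico" parental reconstruction that
pairs the tetraploid parent's AB expression with the diploid parent's D
expression. The package takes gene-level count matrices and a triad table
and produces per-triad bias calls, cross-tissue/cross-line summaries,
tissue-specificity profiles and a whole-gene-set differential-expression
comparison, with a ground-truth simulator so the entire pipeline is
testable offline.

## The statistics at the core

Per triad and context, bias is measured as

    HEB = log2( RPKM_D / RPKM_AB ),   RPKM_AB = (RPKM_A + RPKM_B) / 2

and tested with a Poisson likelihood-ratio test in which replicate-level
counts have mean e_g·l_g·N_r (per-base rate x gene length x library size),
so length and depth differences between homoeologues are modelled rather
than ignored. The null constrains e_D = (e_A+e_B)/2; 2·ΔlogL is referred
to chi-square(1), BH-corrected within each tissue x background family, and
triads are classified AB / D / UN / NE (not expressed). Summary layers add
count-ratio LogFCs, UpSet-style intersections, trend patterns, the Tau
tissue-specificity index (cutoff 0.8) with chi-square/Cramer's-V
association, and an NB likelihood-ratio DE test (FDR < 0.05, |log2FC| ≥ 2).
See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import shwheb as sw

sim = sw.generate(sw.preset_headline(seed=42))        # 8 genotypes x 10 tissues x 3 reps
ctxs = sw.design_contexts(sim.counts.meta, sw.SHW_PARENTS)
results = sw.run_heb(sim.counts, sim.triads, ctxs)    # triad x context bias calls

counts = sw.summarize_counts(results)
shoot_par = counts[counts.context_id == "PI377655xAS2386:shoot:parental"].iloc[0]
shoot_shw = counts[counts.context_id == "C66:shoot:SHW"].iloc[0]
print(shoot_par.n_AB, shoot_par.n_D,
      round(sw.within_background_logfc(shoot_par.n_AB, shoot_par.n_D), 2))
print(shoot_shw.n_AB, shoot_shw.n_D,
      round(sw.within_background_logfc(shoot_shw.n_AB, shoot_shw.n_D), 2))
```

prints

```
192 387 1.01
618 109 -2.5
```

i.e. in the parental background twice as many triads are biased towards
the D subgenome as towards AB (LogFC +1.01), while in the matched hexaploid
the excess reverses (LogFC −2.5): the simulated D-subgenome suppression
upon polyploidization, recovered by the pipeline. The same run scores
sensitivity 0.995 at |log2 effect| = 2 against the simulator's truth, with
no false-direction calls.

The numbered drivers under `analysis/` run the complete story and write
their tables under `results/`:

```sh
cd analysis
python 01_simulate.py            # design + ground truth fixture
python 02_bias_calls.py          # RPKM + LRT bias calls, recovery vs truth
python 03_bias_summaries.py      # LogFCs, intersections, trends, transitions
python 04_tissue_specificity.py  # Tau profiles + bias association
python 05_differential_expression.py
```

Real data drop in the same way: `read_counts(counts.tsv, meta.tsv)`,
`read_triads(triads.tsv)` (plus `gene_lengths_from_gff3` if lengths come
from an annotation), then the identical calls.

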