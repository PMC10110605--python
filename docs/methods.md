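# Methods

## Problem and scope

Allopolyploid wheat carries three closely related subgenomes (A, B, D).
For ~18k "triads" — genes present exactly once on each subgenome — one can
ask whether the D homoeologue is expressed above or below the average of
its A and B partners, and how that balance changes when the D genome moves
from its diploid donor into a newly synthesised hexaploid (SHW) alongside
the A and B genomes of a tetraploid. This package implements that analysis
end-to-end on gene-level count matrices: normalisation, per-triad bias
calls with a likelihood-ratio test, comparative summaries across tissues,
lines and genomic backgrounds, a Tau tissue-specificity layer, a
negative-binomial differential-expression stage, and a ground-truth count
simulator that makes every stage testable without external data.

Read preprocessing, alignment, alternative splicing and GO enrichment are
out of scope; the pipeline starts at validated count matrices.

## Bias statistic and test

The per-triad bias value is

    HEB = log2( RPKM_D / RPKM_AB ),   RPKM_AB = (RPKM_A + RPKM_B) / 2

computed from replicate-averaged RPKM (averaging RPKM before the ratio is
stabler under zero-inflated replicates than averaging per-replicate
ratios). RPKM uses the whole-transcriptome library size from the sample
metadata, falling back to column sums. When exactly one side of the ratio
is zero the value is capped at +-10 for reporting (configurable);
significance never derives from the cap. Both sides zero is reported
missing.

Significance comes from a Poisson rate model. With per-base rates e_A,
e_B, e_D shared across replicates, counts in replicate r are
Poisson(e_g * l_g * N_r), so gene-length and depth differences enter the
rate directly. The null of no AB-vs-D difference is e_D = (e_A + e_B)/2;
2*deltaLL is referred to chi-square(1). The alternative MLEs are closed
form. The constrained null is a concave 2-parameter problem; substituting
u = S_D/(e_A + e_B) turns its stationarity conditions into a single
monotone equation solved by bracketed root-finding, with closed-form
boundary solutions when any homoeologue has zero total counts. This is an
exact maximiser of the same objective a quasi-Newton search would
approximate; the unit suite cross-checks it against an independent
brute-force log-grid search (agreement well below 1e-3 in the statistic).
The statistic is floored at 0. Calibration of raw p-values is verified by
simulation (null rejection fraction at p <= 0.05 stays within
[0.035, 0.065] on 2000 Poisson triads with 3 replicates).

Comparable homoeologue-bias tests in the literature circulate as external
implementations whose exact likelihoods are not stated; the model above is
the simplest likelihood consistent with the null of equal AB and D
expression, an explicit role for gene length, and replicate pooling, and
it is validated by calibration rather than by equivalence to any
particular implementation.

Contexts: in a hexaploid (SHW or reference) context the AB and D sides
come from the same libraries. The "in-silico parental" context pairs
tetraploid libraries (A, B counts) with diploid libraries (D counts) by
sorted replicate index — the expected hexaploid absent inter-subgenome
interaction. Unpaired extra replicates are dropped with a warning; the
pairing convention is ours, as no published rule exists (the likelihood
only uses within-context totals, so pairing affects bookkeeping, not the
statistic).

## Multiple testing and states

BH (step-up) FDR at alpha = 0.05 per context family (tissue x background),
with not-expressed triads excluded from the family; Bonferroni and "none"
are available. The correction choice and threshold are ours — the source
analysis does not state one. States: NE when all three homoeologues have
mean RPKM < 0.5 (configurable); else D (q <= alpha, HEB > 0), AB
(q <= alpha, HEB < 0), else UN. A significant q with HEB exactly 0 has no
direction and is classified UN.

## Comparative summaries

The "LogFC" of the summary layer is a log2 ratio of counts of biased
triads, not an expression fold change: within a background
log2(n_D/n_AB), between backgrounds log2(n_SHW/n_parental) per state.
Zero-count cells yield missing values (never +-infinity), with a warning.
Intersections across lines exclude triads NE in any compared line
(tallied separately) and partition the rest over the 3^k AB/D/UN
combinations. Trend patterns join states across tissues in the fixed
presentation order (boot_head, shoot, lemma_palea, glume, pistil_AI,
pistil_AM, pistil_1DAA, anther, hypocotyl, root). Transition categories
over three aligned backgrounds distinguish same-in-all, same-in-first-two,
reversal (first and third agree), same-in-last-two, and all-different.

## Tissue specificity

Tau = sum_i(1 - x_i/max_j x_j)/(n-1) over replicate-mean RPKM per tissue
within one genotype; 0 = uniform, 1 = single-tissue; cutoff 0.8 declares a
gene tissue-specific with its argmax tissue attached. No log-transform by
default (optional log2(x+1)). Triads are categorised by the number of
specific homoeologues, which subgenomes they are, and whether the specific
ones share a tissue. Association with bias state uses only AB- and
D-biased triads, a Pearson chi-square without continuity correction, and
Cramer's V = sqrt(chi2/(n*(min(r,c)-1))); a warning is logged when any
expected cell is < 5 rather than filtering.

## Differential expression

Per gene, hexaploid vs parent within two tissue pools — vegetative (shoot,
root, hypocotyl, glume, lemma_palea) and reproductive (boot_head, the
three pistil stages, anther). A/B genes are contrasted against the
tetraploid parent, D genes against the diploid. Normalisation factors are
library sizes scaled to geometric mean 1; dispersion is a gene-wise
method-of-moments estimate phi = max(0, (s^2 - m)/m^2) on normalised
counts (pooled within-group variance); the test is an NB likelihood ratio
with phi held fixed, which reduces exactly to the Poisson LRT at phi = 0.
logFC adds a prior count of 0.5 to the fitted normalised means. Calls use
FDR < 0.05 and |log2FC| >= 2. Tissue is deliberately not a covariate (the
pools mix tissues); the tissue-to-tissue variance is absorbed into phi,
costing power but not validity of direction — adequate for the directional
questions asked of this stage. Matching any specific external package's
gene lists is a non-goal.

## Simulator

The generator emulates the eight-genotype design (2 diploid DD, 2
tetraploid AABB, 4 hexaploid AABBDD; 10 tissues x 3 replicates = 240
samples) at configurable triad count. Gene lengths are log-normal (median
~1.5 kb, sdlog 0.45); per-triad base rates are log-normal with median RPKM
5 (sdlog 1.0) so typical per-gene counts are ~150 at the default 20M-read
depth. Bias is injected by scaling e_D by 2^(+-effect) for configured
fractions of triads; the hexaploid background multiplies e_D of a
configured fraction of triads by a global repression factor. A per-triad,
per-tissue log-normal factor (sdlog 0.3) moves all three homoeologues
together (ratio-preserving); tissue-specific genes instead concentrate 95%
of their mass in one tissue, which can break the ratio in individual
tissues — the truth table therefore records the realised rates per triad x
tissue x background and derives the true state from them (D / AB when
|log2 ratio| exceeds a 0.25 band, UN inside it). Counts are NB with shared
dispersion phi (Poisson at phi = 0, the default). Genotypes of the same
ploidy class share rates and differ only by sampling noise, which keeps
the truth compact; the hexaploid-to-parent cross map is fixed but partly
arbitrary (only C66 = PI377655 x AS2386 is documented).

Presets (the documented study conditions; also used by the acceptance
script):

- `preset_headline`: 30% D-biased / 8% AB-biased triads at |log2 effect|
  2 in the parental background; 85% of triads have e_D repressed 4-fold in
  the hexaploid; 10% of genes tissue-specific; 1000 triads by default.
  This produces a positive within-background LogFC in every parental
  context and a much smaller (negative) one in every matched SHW context —
  the qualitative signature of D-subgenome suppression upon
  polyploidization — plus near-complete recovery of the effect-2 truth
  rows (sensitivity >= 0.9, false direction <= 0.01).
- `preset_null`: all-UN truth for calibration (2000 triads, one tissue).
- `preset_d_repression_de`: no triad-level bias, but 20% of triads with
  e_D repressed ~6.7-fold in the hexaploid, driving D-dominated down-calls
  in the DE stage.

What the simulator does not emulate: gene-wise dispersion distributions,
correlated homoeologue noise, mapping ambiguity between subgenomes,
homoeologous exchanges, or genotype-specific regulatory divergence.
Passing tests therefore demonstrate correctness and calibration of the
statistics under the stated model, not robustness to those real-data
complications; the Poisson test is expected (and documented) to be
anti-conservative under unmodelled overdispersion (simulate with phi > 0
to observe this).

## Problem sizes and numerics

Default analysis runs use 1000 triads x 10 tissues x 8 genotypes (the
simulator's design default of 18,357 triads is available when wanted);
calibration uses 2000 triads in one tissue; the DE stage 400 triads.
Root-finds use machine-precision bracketed Brent iterations; the LRT
statistic and the NB statistic are floored at 0; 0*log(0) terms are
evaluated as 0. Degenerate inputs (all-zero triads, all-zero genes, empty
groups, zero-count LogFC cells) return sentinels or missing values rather
than infinities, as described above.

## Interfaces

The library (`shwheb`) is the programmatic interface; the numbered scripts
under `analysis/` are thin drivers over it and write all tables under
`results/`. A console CLI would add nothing over these two layers and was
not built.
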