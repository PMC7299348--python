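# Methods

## Study design and data model

The pipeline analyzes a gene × sample matrix of raw read counts for
purified cochlear spiral ganglion neurons (SGNs) at five developmental
ages — E15.5, P1, P8, P14, P30 — with replicate libraries per age, plus
hair-cell (HC) and glia reference populations. Counts are assumed to come
from a quantifier such as featureCounts; both a plain gene × sample TSV
and the featureCounts dialect (comment lines, Geneid/Chr/Start/End/
Strand/Length columns) are read, and per-gene lengths for TPM come from a
two-column TSV, the featureCounts Length column, or union-exon lengths
parsed from a GTF (gene-record span as fallback). Gene identifiers are
opaque strings throughout.

Two sample layouts are supported: single pooled reference libraries
(the minimal 17-sample layout: 5 ages × 3 replicates + HC + Glia pools)
and replicated references. The group-means linear model tolerates
single-replicate groups as long as total residual degrees of freedom
`d = n_samples − n_groups ≥ 1`; every SGN age must carry ≥ 2 replicates.
The synthetic study default uses 3 replicates for HC and Glia, because
the expression gate counts "all replicates" within the reference groups
too and replicated references make the 10 SGN-vs-reference significance
conditions identifiable at realistic noise.

## Normalization

*CPM* divides counts by the per-sample total × 1e6; *TPM* first divides
by gene length and renormalizes each column to 1e6. Expression gates use
CPM on **raw** library sizes so they are reproducible from counts alone;
modeling uses TMM-effective library sizes.

*TMM* follows the published trimmed-mean-of-M-values recipe exactly:
reference sample chosen as the one whose upper-quartile count proportion
is closest to the across-sample mean (overridable); genes zero in either
sample dropped; 30% two-sided trim on M, 5% on A (rank-based, average
ranks on ties); inverse-asymptotic-variance weights; factor
`2^(Σ wM/Σ w)`; factors rescaled to geometric mean 1; technical
replicates (max |M| < 1e-6) and empty trims fall back to factor 1 with a
warning. Agreement with edgeR's `calcNormFactors` is tested to 1e-9, and
against an independently coded step-by-step oracle to 1e-8. Depth
equivariance holds to a few percent only, because the binomial precision
weights depend on depth — identical to the reference implementation's
behavior.

## Precision weights and moderated inference

log2-CPM is `log2((count + 0.5)/(eff_lib + 1) × 1e6)`. A first unweighted
group-means fit yields per-gene residual sd; `sqrt(sd)` is smoothed on
average log2-count by lowess with span 0.5 (statsmodels, 3 robustifying
iterations), interpolated linearly with flat extrapolation, evaluated at
each observation's fitted log2-count, and raised to the power −4 to give
weights. Predicted `sqrt(sd)` is floored at 1e-4 so degenerate
zero-residual genes keep finite weights. Cross-checked against limma's
`voom`: identical log-CPM, weights within 5% (the two lowess
implementations differ slightly).

Weighted least squares on the group-indicator design decouples into
per-group weighted means (solved in closed form; tested against a
normal-equations oracle at 1e-10). The variance prior (d₀, s₀²) is
estimated by matching moments of log s² to a scaled-F distribution,
with the trigamma inverse solved by Newton iteration; all-equal
variances hit the d₀ = ∞ branch (full shrinkage, reported via a
warning). Agreement with limma's `squeezeVar` is tested to 1e-6.
Moderated t uses `t̃ = Δcoef/(se_unscaled · s̃)` on `d + d₀` degrees of
freedom (capped at 1e6), two-sided p-values, and BH q-values computed
independently within each contrast. With unit weights and d₀ = 0 the
machinery reduces exactly to the pooled-variance two-sample t-test
(tested at 1e-8). Under no-effect negative-binomial simulations the
per-contrast fraction of p < 0.05 is 0.046–0.049 (pooled over 20 seeds
× 2000 genes).

## Gates, filters, transition taxonomy

All thresholds live in one `Thresholds` dataclass whose defaults are the
study's values (CPM gates 1 and 10; FC 4 / q 0.01 specificity; SGN-pair
FC 2; TPM 5 / 30 / 75; 25× reference ratio; q 0.05 / FC 2 transitions;
q 0.1 / FC 2 / element-wise FC 4 unchanged; category reporting size 10;
30-fold QC gate). Interpretation choices on points the recipe leaves
open, each made once:

- "Differentially expressed between **all** SGNs and HC, glia" is read
  strictly: every age must pass against both references (condition 1 of
  the constant filter); likewise "mean TPM in SGNs > 30" applies to every
  age mean. The dynamic filter's condition 1 requires a *single* age to
  pass against both references simultaneously.
- Specificity conditions are signed: SGN above reference.
- The SGN-pair flatness condition (FC < 2) carries no q requirement, as
  none is stated.
- "Maximum element-wise FC" pairs replicates by index (rep *i* of age A
  vs rep *i* of age B) on TMM-normalized CPM with a pseudo-count of 1;
  the max of the two-sided ratio must stay below 4. An all-pairs variant
  is available behind `Thresholds.elementwise_mode="all_pairs"`.
- "qval" is BH FDR within each pairwise contrast.
- The noisy symbol is preserved in the raw pattern string and merged
  into '-' only for category grouping, so no information is destroyed.
- The dynamics universe (CPM > 10 in all replicates of ≥ 1 age, SGN
  samples only) is re-modeled on SGN samples alone before transition
  calling; the enrichment universe is the corresponding gated set, not
  the genome.

## Synthetic data

The generator plants eight gene classes with true means on the TPM scale
(group compositions are balanced so every group's true means sum to 1e6
within ~3%; the flat background absorbs the remainder through one global
scale factor, keeping truly flat genes the compositional majority — a
premise TMM normalization relies on):

| class | ages (TPM) | references (TPM) | n (default) |
|---|---|---|---|
| background | flat, log-uniform ≈3–3000 after scaling | same | 2000 |
| housekeeping | flat 50–400 | same | 50 |
| constant_specific | flat 120–250 | level/50–100, < 2.5 | 50 |
| dynamic_specific | monotone or peaked, trough = peak/3–10, peak 150–400 | peak/60–100 (2nd ref ×0.5–2) | 50 |
| hc / glia_specific | home/25–100 | home 50–400 in the home group | 50 each |
| patterned | geomean-anchored trajectories, level 120–250, step 5–8× | geomean of the trajectory | 50 × 6 patterns |
| noisy | flat 20–100, dispersion 2.0 | same | 50 |

Counts are negative-binomial: a gene's expected count is its
length-weighted share of the group's TPM composition times a library
target drawn uniformly in 0.8–1.2 × 10⁶ reads (deliberately desk-scale;
real libraries are ~20× deeper). Gene-wise dispersion follows the
decreasing trend φ = 3/μ + 0.04, i.e. an asymptotic biological CV of 0.2
— the standard figure for well-controlled inbred-mouse bulk experiments;
at BCV ≳ 0.3 the all-pairs flatness and TPM-margin conditions of the
constant filter become noise-limited regardless of expression level, and
no filter of this form can recover planted genes reliably at n = 3.
Planted specific and patterned classes draw lengths ≥ 1.5–4 kb and
levels such that their true CPM and TPM clear the gates they are defined
to satisfy, with margin for counting noise; class margins (references
< 2.5 TPM against the 5-TPM condition, ≥ 30× against the 25× condition)
keep each condition's failure probability at the percent level.

A noise-free oracle applies both filters to the true means (significance
replaced by the corresponding fold condition) and must recover the
planted sets exactly — this invariant caught one construction bug during
development and guards the class definitions.

What the generator does **not** emulate: GC/length biases beyond the
length-weighted allocation, batch structure, tonotopic (apex–base)
gradients, single-cell heterogeneity, and the real study's gene-count
scale (~52k genes, ~21.5M reads). Passing recovery tests therefore
demonstrates correctness of the filtering machinery under the stated
noise model, not performance on any particular real dataset.

## QC

The wet-lab 30-fold marker gate is applied in silico to expression-derived
folds (pseudo-count 0.01 TPM): enrichment markers must be ≥ 30-fold up in
their home population, contamination markers ≥ 30-fold down. The default
marker panel (Mafb/Slc17a6/Slc17a7/Lypd1 neuronal; Myo6/Myo7a/Pou4f3/Gfi1
HC; Sox10/Foxd3/Plp1 glial; Gapdh/Actg1/Actb housekeeping) is a list of
configurable strings, not hard-coded biology. Sample structure is
summarized by all-vs-all Pearson correlation of log-CPM with
average-linkage leaf ordering.

## Problem sizes and determinism

Default analyses run on 2,600 genes × 21 samples (seconds per stage);
the null calibration uses 20 × 2,000-gene simulations (~6 s total).
These sizes were chosen so the full suite and the acceptance script run
in minutes on one CPU. Every random draw flows through
`numpy.random.default_rng` seeded from a single integer; identical
inputs and seed give bit-identical counts and byte-identical output
TSVs.

## Known limitations

- The pooled-SGN variant of the specificity filters (testing the average
  of all ages against a reference as one contrast) is not implemented;
  only the strict every-age reading is.
- eBayes uses a constant prior (no trended or robust prior) and the
  linear model has no duplicate-correlation/random-effect support.
- GO-style annotations are treated as flat sets; no graph propagation.
- TPM depends on the length convention of the supplied annotation;
  featureCounts lengths and union-exon GTF lengths can differ.
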