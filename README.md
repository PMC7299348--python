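# sgnseq

Bulk RNA-seq analysis of spiral ganglion neuron (SGN) development in the
mouse cochlea. SGNs are the afferent neurons that relay sound from hair
cells (HCs) to the brainstem. The package asks two questions of a
gene × sample count matrix covering purified SGNs at five ages (E15.5, P1,
P8, P14, P30) plus HC and glia reference populations:

1. **Which genes are SGN-specific within the cochlea?** — split into genes
   with *constant* expression across development and genes with *dynamic*
   expression, using fold-change, significance and TPM-level conditions
   against both references.
2. **How does each expressed gene move between consecutive ages?** — a
   four-symbol transition code over {u, d, -, n} (up, down, unchanged,
   noisy), e.g. `u---` for a gene induced between E15.5 and P1 and stable
   afterwards.

It is aimed at researchers who have count-level bulk RNA-seq for a small
time course with reference cell types and want a reproducible, tested
implementation of this filtering/classification style of analysis.

## The statistics at the core

- **Normalization.** CPM and TPM with exact column normalization, and
  between-sample TMM scaling factors: for sample *s* against reference
  *r*, gene-wise log-ratios `M_g = log2((c_gs/N_s)/(c_gr/N_r))` are
  trimmed 30% by M and 5% by A (two-sided), then averaged with
  inverse-asymptotic-variance weights
  `w_g = (1/c_gs − 1/N_s + 1/c_gr − 1/N_r)^−1`; the factor is
  `2^(Σ w M / Σ w)`, rescaled so factors have geometric mean 1.
- **Moderated differential expression.** log2-CPM
  `log2((c+0.5)/(Ñ+1)·1e6)` with effective library sizes `Ñ = N·TMM`;
  a lowess fit (span 0.5) of `√sd` on average log-count supplies
  per-observation precision weights `w = (fitted √sd)^−4`; per-gene
  weighted least squares on a group-means design; residual variances
  shrunk by empirical Bayes, `s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d)` with
  (d₀, s₀²) moment-matched to a scaled-F distribution across genes;
  moderated t on d + d₀ degrees of freedom; Benjamini–Hochberg q-values
  within each contrast.
- **Specificity filters.** Constant: q < 0.01 and FC > 4 above *both*
  references at *every* age; all SGN age pairs FC < 2; reference mean
  TPM < 5; every age mean TPM > 30. Dynamic: some age with q < 0.01 and
  FC > 4 above both references; some age pair with q < 0.05 and FC > 2;
  max age mean TPM > 75 and ≥ 25× both reference means.
- **Transition calls.** u/d: q < 0.05 and FC > 2 (signed); unchanged:
  q > 0.1, FC < 2 and max replicate-pair fold change < 4 on
  TMM-normalized CPM (+1 pseudo-count); everything else is noisy, which
  merges into '-' for category grouping.
- **Enrichment.** Upper-tail hypergeometric p for each gene group:
  `p = P[X ≥ k]`, `X ~ Hypergeom(N, K, n)` over the universe of gated
  genes, with BH adjustment across groups.
- **QC.** The 30-fold marker enrichment/depletion gate (e.g. the neuronal
  gene Mafb up, the glial gene Sox10 and HC gene Myo6 down) and all-vs-all
  Pearson correlation of log-CPM with average-linkage ordering.

A synthetic-data module generates negative-binomial counts around planted
TPM-scale group means for eight gene classes (constant/dynamic specific,
HC/glia specific, housekeeping, patterned, noisy, background), with a
truth table, so every stage is verifiable by recovery. See
`docs/methods.md` for the model, parameter and calibration details.

## Worked example

```bash
python analysis/01_simulate.py --seed 1   # synthetic study, planted truth
python analysis/02_qc.py
python analysis/03_normalize_de.py
python analysis/04_specificity_filters.py
python analysis/05_transition_patterns.py
python analysis/06_enrichment.py
```

prints, among other things:

```
simulated 2600 genes x 21 samples in 7 groups; data under .../scratch/pipeline
mean within-age r = 0.9381; mean SGN-vs-reference r = 0.8441
gated 2498/2600 genes; 21 contrasts; prior df 16.924
constant: called 47 (planted 50), sensitivity 0.94, precision 1.0
dynamic: called 50 (planted 50), sensitivity 0.98, precision 0.98
dynamics universe 1996 genes in 16 categories (7 above the reporting size); planted-pattern recovery 0.997
planted '-d--' query recovered as top group in 3/3 annotations
```

Reading: replicates correlate more within an age (0.94) than with the
reference populations (0.84); the CPM > 1 gate keeps 2498 of 2600 genes;
the constant filter recovers 47 of the 50 planted constant SGN-specific
genes with no false positives, the dynamic filter 49 of 50 with one; and
99.7% of transition-patterned genes land in their intended category. The
planted enrichment signal is recovered by the hypergeometric scan in all
three synthetic annotation collections.

The same pipeline runs from the shell on any counts file:

```bash
sgnseq run-all --counts counts.tsv --samples samples.tsv \
    --lengths lengths.tsv --gmt sets.gmt --outdir out/
```

writing per-stage TSVs plus `manifest.json` with all stage gene counts.

## Using the deposited study data

The original study's counts are on GEO under accession **GSE132925**
(file `GSE132925-cochlear-SGN-cnts.txt.gz`). To analyze them: download
and `gunzip` the file, write a sample sheet mapping its columns to the
groups `SGN_E15.5 … SGN_P30, HC, Glia`, supply gene lengths (e.g. from a
GENCODE GTF via `--gtf`), and run `sgnseq run-all` with the default
thresholds. The package does not download data itself.
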