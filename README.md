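# reexpress

Integrative DNA-methylation / gene-expression analysis of epigenetically
silenced genes reactivated by a demethylating drug, with validation
against a tumour cohort and cohort stratification by the resulting gene
signatures.

The package is written for computational biologists working with paired
Infinium-style methylation arrays and expression arrays from
drug-treatment experiments (e.g. azacytidine in cancer cell lines),
together with cohort-level RNA-seq (RPKM) and 450K methylation data. It
implements the complete analysis as a tested, reusable library plus a
CLI, and ships a synthetic-data generator with known ground truth so
every stage can be exercised and calibrated end to end.

## What it computes

**Probe-level methylation.** From methylated (M) and unmethylated (U)
bead intensities:

- beta value: `β = M / (U + M)` ∈ [0, 1]
- M value: `m = log2(M / U)`, with `β = 2^m / (1 + 2^m)`
- detection p: one-sided normal test of total signal M + U against the
  per-sample negative-control mean/SD; cells with p > 0.05 are masked NA
- Δβ = β(treated) − β(mock), per probe

**The re-expression filter cascade.** A gene is a candidate when

1. its median expression log2(treated/mock) exceeds 0.5 at day 3 *or*
   day 10 (re-expression, ≥1.4-fold), and
2. at least one of its CpG-island probes within ±1000 bp of the TSS has
   mock β > 0.5 (high baseline methylation) and mock − treated
   demethylation ≥ 0.25.

Candidates are validated against the cohort: a methylation probe is
*informative* when its Spearman ρ against its gene's expression across
cohort samples is negative with Benjamini–Hochberg FDR < 0.01; a
candidate survives only if one of its passing probes is informative
with ρ < −0.25 and FDR < 0.05. The validated signature is annotated
with transcription-factor and reference-list overlap fractions.

**Enrichment.** Preranked gene-set enrichment with the weighted
Kolmogorov–Smirnov running sum (ES = signed extremum; hit increment
∝ |score|, miss decrement 1/(N − Nh)), gene-set-permutation NES and
nominal p, BH FDR across sets, significance at p < 0.05 and FDR < 0.25,
and the NES-matrix convention (0 where not significant; a set appears
iff significant in ≥1 list). A PScan-style promoter motif test scores
each promoter (window −450..+50 around the TSS) by its best PWM
log-odds hit on either strand and compares foreground vs background
means with a one-sided z-test.

**Cohort stratification.** Row-standardized expression matrices,
complete-linkage Euclidean clustering with reproducible leaf ordering,
sample-order propagation across linked heat-map panels (methylation
rows ordered by signed TSS distance), five-bin quantile expression
tracks, a PCA batch check on M values (sex-chromosome and SNP probes
removed), and a random-25-gene clustering-stability control scored by
adjusted Rand index.

**Closed-form metrics.** Flow-cytometry log2 MFI change,
`log2[(MFI_ab − MFI_iso)_treated / (MFI_ab − MFI_iso)_mock]`, and
RECIST-style percent change of summed target-lesion diameters.

## Worked example

Run the whole pipeline on synthetic data (2,000 genes, 50 planted
silenced-reactivated genes, a 60-sample cohort with a 30% planted
subgroup):

```python
from reexpress import RunConfig, run_all

report = run_all(RunConfig(outdir="demo_run", seed=1))
print(report["counts"])
print(report["fractions"])
```

prints

```
{'genes': 2000, 'probes': 6972, 'planted': 50, 'induced_fold': 0,
 'candidates': 49, 'validated': 49, 'informative_probes': 54,
 'recovered_planted': 49, 'false_positives': 0,
 'transcription_factors': 10}
{'tf_fraction': 0.20408163265306123, 'reference_overlap': 0.5918367346938775,
 'planted_recovery': 0.98}
```

Reading: of the 50 genes planted with promoter demethylation (Δβ
effect 0.4) and expression induction (log2 1.5), 49 pass the
re-expression filter and all 49 survive cohort validation — 98%
recovery with zero false positives among the 1,950 null genes. 20% of
the validated signature are transcription factors (matching the planted
TF fraction), and the cohort clustering on the signature recovers the
planted subgroup exactly (`report["cohort"]["ari_signature_vs_truth"]`
is 1.0) while random 25-gene sets do not (mean adjusted Rand ≈ 0.075).
`induced_fold` counts genes ≥4-fold induced; the planted log2 1.5
effect is deliberately below that bar.

The same run is available from the shell:

```sh
reexpress run-all --seed 1 --out demo_run
```

and individual stages as `reexpress simulate | meth | expr | filter |
gsea | motif | cohort | metrics`.

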