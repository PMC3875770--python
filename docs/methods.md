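# Methods

This note documents the models, conventions and design choices behind
the package, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Methylation model

Infinium-style probes report methylated (M) and unmethylated (U) bead
intensities. We compute `β = M / (U + M)` with no offset constant in
the denominator, and `m = log2(M / U)`. The two scales are linked by
the bijection `β = 2^m / (1 + 2^m)`, which holds to 1e−12 on every
jointly unmasked cell and is asserted as an acceptance property.

**Detection p-values.** The detection test is a one-sided normal test
of a probe's total signal M + U against the per-sample mean and SD of
the negative-control probes (a probe whose signal equals the control
mean gets p = 0.5). This is the common array-practice formulation;
per-colour-channel control pools are not modelled — a single pooled
control set per sample is assumed. A zero control SD is floored at
1e−6 of the control mean, with a warning. Masking applies for
p **strictly greater** than α (default 0.05): a cell at exactly the
threshold is retained. Lowering α is monotone (never unmasks), and a
masked cell propagates through every downstream computation as
missing — it never becomes a zero.

**Δβ.** Defined cellwise as treated − mock, so demethylation under
treatment is negative; the filter cascade evaluates demethylation as
mock − treated ≥ 0.25 (signed, direction fixed by the biology: the
drug removes methylation). Per-sample demethylation is summarised by a
five-number summary over unmasked Δβ values.

## Expression processing

Treatment arrays yield per-probe `log2(treated / mock)`; non-positive
linear inputs are masked. Multiple probes per gene are aggregated by
the per-sample **median** of unmasked probe values; an even probe count
takes the midpoint of the central pair. The fold-change signature
(default 4-fold) uses an **inclusive** boundary: a gene at exactly
log2(4) is included. Cohort RPKM preprocessing follows the fixed
order: zeros → NA (no reads observed, not evidence of log2 = −∞), then
log2, then removal of X/Y-chromosome genes. Within-/between-array
normalisation of raw arrays is out of scope; inputs are assumed
normalised.

## The filter cascade

Thresholds (all configurable via `FilterThresholds`): expression
median M > 0.5 (strict) at day 3 OR day 10; probe CpG-island flag
required; |signed TSS distance| ≤ 1000 bp; mock β > 0.5 (strict);
mock − treated ≥ 0.25 (inclusive); cohort ρ < −0.25 (strict) with
BH FDR < 0.05; informative-probe FDR < 0.01. Strict vs inclusive
boundaries follow the wording of the rules ("higher than" vs "at
least"). The probe-level demethylation test is evaluated at each
timepoint independently and OR-combined, with the passing timepoint
recorded in the gene's provenance.

Cohort validation correlates each probe's β with its gene's expression
across the samples present on both platforms using Spearman's ρ with
average-rank ties; p-values come from the t approximation with n − 2
degrees of freedom, and the FDR is Benjamini–Hochberg (the specific
FDR method is our choice; only "FDR" is prescribed). Probes absent
from the cohort matrix are treated as non-informative rather than as
errors. Fewer than 3 complete pairs yields a missing correlation. The
bulk probe scan computes ρ as Pearson correlation of average ranks
(vectorised); the scalar `spearman_rho` wraps scipy — tests assert the
two routes agree to 1e−12.

Tightening any threshold can only shrink the output signature; this
monotonicity is asserted across all seven threshold fields.

## Enrichment

Preranked GSEA with the weighted running sum: walking a ranked list of
N genes with Nh set members, hits add `|s|^w / Σ_hits |s|^w` (weight
w = 1 by default), misses subtract `1/(N − Nh)`; the ES is the signed
extremum (first occurrence on ties; ties in ranking scores are broken
by stable input order). A set with all hit scores zero at w > 0 falls
back to equal hit weights; a set covering the entire list is rejected
as degenerate. The null is **gene-set permutation** (random sets of
identical size — the only null available for preranked input), 1000
permutations by default; the pipeline default is 200, chosen as the
resolution actually needed for the p < 0.05 / FDR < 0.25 significance
call. NES divides the ES by the mean |null ES| of matching sign;
nominal p is the same-sign tail fraction, floored at 1/(n_perm + 1) so
it is never exactly zero; when no null value shares the sign the
result is flagged and p = 1/(n_perm + 1). FDR across sets is BH on
nominal p-values — a deliberate, simpler substitute for the original
tool's NES-based FDR. The NES display matrix keeps a set iff it is
significant in at least one ranked list and writes 0 where
significance fails.

The permutation engine exploits the piecewise shape of the running sum
(it only rises at hits), evaluating extrema at hit boundaries in
O(k log k) per permutation; tests assert this shortcut equals the full
running-sum ES exactly.

## Motif over-representation

PWMs are built from 4 × width count matrices with a 0.5 pseudocount
and log2-odds against a uniform (configurable) background. A promoter
(window −450..+50 relative to the TSS, taken from FASTA headers, never
recomputed from a genome) is scored by its best hit over all positions
on both strands; non-ACGT bases contribute 0 (background-neutral).
The over-representation statistic is
`z = (mean_fg − mean_bg) / (SD_bg / √n_fg)` with a one-sided normal
p — the best-hit-mean z-test of the cited promoter-scanning approach.
At least 5 foreground promoters are required; zero background variance
is an error.

## Cohort stratification

Rows (genes) are centred and scaled to SD 1 (ddof = 1); zero-variance
rows are dropped. Clustering uses Euclidean distance with complete
linkage. Missing values use pairwise-complete distances rescaled by
the fraction of shared coordinates; a pair with no shared coordinates
is an error naming the items. Dendrogram leaves are reordered by
subtree mean with ties broken by input order — this mirrors the
weighted-reordering default of standard heat-map tools and makes leaf
orders reproducible. Clustering operates on the row-standardized
matrix by default (`cluster_on="raw"` is available; whether the
original displays clustered scaled or raw values is ambiguous, so both
are supported). Sample order is propagated unchanged to companion
panels (a pure permutation — value multisets are preserved exactly),
and methylation panels are additionally row-ordered by ascending
signed TSS distance.

Expression tracks use five equal-frequency intervals (quintiles,
labels 1 = lowest; the only self-consistent reading of "five …
intervals"); heavy ties can collapse intervals and are flagged. The
PCA batch check removes sex-chromosome probes, SNP-flagged probes and
incomplete rows, then reports the first two principal components of
the samples and their explained-variance fractions.

The random-signature control re-clusters the samples on random k-gene
sets (default k = 25) and reports adjusted Rand indices against the
signature-based two-group partition.

## Synthetic data: what it emulates and what it does not

The generator plants a known truth: `n_planted` genes (default 50 of
2,000) whose promoter CpG-island probes have mock β drawn in
[0.6, 0.95], treated β lowered by `delta_beta_effect` (default 0.4 at
day 10, half at day 3), and expression log ratios raised by
`expr_effect` (default log2 1.5 at day 10). Intensities are
back-computed from target betas by fixing a log-normal total intensity
T and setting M = βT, U = (1 − β)T, so recomputed betas reproduce the
targets to 1e−12 by construction. Detection dropout (default 1% of
cells) replaces a cell's total intensity with a negative-control draw:
β is preserved but the detection p becomes background-like, so ≈95% of
dropout cells fail the 0.05 mask. The cohort couples a per-sample
latent silencing level to planted-gene promoter β (increasing) and
expression (strictly decreasing on the log2 scale), giving Spearman
ρ = −1 in the zero-noise limit; the planted subgroup (default 30% of
60 samples) draws high latent values. Expression zeros are injected
uniformly at a default 5% rate. Auxiliary fixtures plant three
enriched gene sets (≈80% planted members), a TF list containing the
planted TF subset (default 20% of planted genes), a reference list
covering 60% of planted genes, and a consensus PWM site embedded in
every planted gene's promoter window.

Noise is independent Gaussian on the β and log2 scales (default SD
0.05 for both, the study condition the recovery properties are stated
at). With all noise SDs at 0 every planted effect is exactly its
configured size, and identical configs produce bit-identical fixtures
(named, seeded generator streams).

Deliberately **not** modelled: bisulfite-chemistry effects, dye bias,
probe cross-reactivity, batch effects beyond an optional mean shift,
read-level RNA-seq counts, and correlated noise between probes of a
gene. Passing recovery/calibration tests therefore demonstrates that
the cascade's logic and thresholds behave as specified under clean
planted effects — not that the thresholds are optimal for any real
dataset.

## Problem sizes and seeds

Default study scale is 2,000 genes (≈7,000 methylation probes,
2 expression probes/gene), a 60-sample cohort, 200 gene-set
permutations and 20 random-control draws — sizes at which every
pipeline property of interest (recovery, FDR calibration, enrichment
significance, stratification) is already stable, keeping a full run in
seconds. The FDR-calibration checks use 5,000 null probes × 60 samples
over 20 seeds (test suite) and 2,000 probes × 5 seeds (acceptance
script). One global seed is fanned out to per-stage child seeds via
fixed spawn keys, so stage-level results are reproducible independent
of stage order.

## Known limitations

- The detection-p model is parametric (normal); arrays with heavy-
  tailed background would need an empirical null.
- The treatment experiment models a single cell line per run; multi-
  line studies are handled by running per line and combining
  signatures externally.
- The motif z-test treats promoter best-hit scores as approximately
  normal; very small backgrounds violate this.
- BH-on-nominal-p FDR for gene sets is more conservative than
  NES-based FDR when many sets share signal.
- The `induced_fold` 4-fold signature is empty at the default planted
  effect (log2 1.5 < 2); raise `expr_effect` to exercise it.
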