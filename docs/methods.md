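# Methods

This note documents the statistical models implemented in `octempo`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions that make
runs reproducible.

## Study design assumed

A donor × timepoint bulk RNA-seq count matrix: D donors (default 8), each
sampled once at each of T timepoints (default days 0, 2, 5, 9 of
osteoclast differentiation), counts summarised per gene. Optional extras:
a continuous per-donor phenotype (resorption activity), GWAS summary
statistics with a gene annotation giving TSS positions, a promoter
motif-count matrix, and a pseudo-bulk cluster × gene expression matrix
from single-cell data.

## Differential expression

**Normalization.** Median-of-ratios size factors: for genes with positive
counts in every sample, `s_j = median_g K_gj / (∏_j K_gj)^{1/n}`. If no
gene is positive everywhere the function errors rather than silently
switching to a pseudo-reference; with tens of samples this indicates a
degenerate input. All test statistics are invariant to rescaling the
size-factor vector by a constant (absorbed by the intercept), and scaling
one sample's counts scales its factor proportionally.

**Dispersion.** Per-gene NB dispersion α (Var = μ + αμ²) by method of
moments on normalized counts within design groups (default: timepoint),
with the Poisson term corrected for the size-factor spread
(`E Var(K/s) = μ·mean(1/s) + αμ²`), pooled across groups by residual df,
floored at 0, then shrunk 50/50 toward a fitted `α(μ) = a₀ + a₁/μ` trend
and floored at 10⁻⁸. The 50/50 shrinkage stabilises 8-replicate moment
estimates without the machinery of a full empirical-Bayes fit; on null
simulations at α = 0.05 the median estimate lands within a few percent of
the truth and the LRT below is calibrated (KS distance to uniform ≈ 0.01–
0.02 at 5000 genes, see the acceptance output). For the single-timepoint
phenotype model, group moments would count the phenotype signal itself as
noise; passing `dispersion=None` instead estimates α from the residuals of
a pilot fit of the phenotype model (moment equation around the fitted
means with an n/(n−p) df correction, same trend shrinkage).

**GLM fitting.** Log-link NB GLMs with fixed α, fitted by IRLS batched
across genes (shared design matrix, per-gene weights; linear solves via
`np.linalg.solve` on stacked normal equations with a 10⁻¹⁰ ridge jitter).
Initialisation from a log-linear least-squares fit of `log max(K, 0.5)`;
convergence when the relative deviance change falls below 10⁻⁸, at most
100 iterations; linear predictors clipped to ±30 to prevent overflow.
Non-converged genes are reported with status `degenerate`, p = NA, and are
excluded from the BH denominator. Genes with total count below 10 are not
tested (`low_count`). The IRLS deviances match direct likelihood
maximisation to better than 10⁻⁴ on Poisson toys (tested).

**Tests.** Timepoint: LRT of `~donor + timepoint` vs `~donor`, statistic =
deviance difference, χ² with T − 1 df; default call at BH-FDR < 10⁻⁴.
Phenotype: Wald z on the NB slope of `~1 + phenotype` at one timepoint,
one sample per donor required, constant phenotypes refused; default call
at BH-FDR < 10⁻². With 8 donors the Wald test is slightly liberal in the
tails (a small-sample property; the global-null false-positive count stays
near zero, but the realised FDR in mixed settings can exceed the nominal
1% — see Limitations). Fold changes are plain
`log2((mean_b + 1)/(mean_a + 1))` of group-mean normalized counts; no
shrinkage is applied.

**BH adjustment** is the standard step-up procedure, order-preserving,
with NA p-values excluded from the number of tests.

## Reproducibility filter and temporal clustering

Per gene and donor, the profile is `log2(normalized count + 1)` over the
T timepoints; the filter computes Pearson r between each donor's profile
and the cross-donor mean profile and keeps genes with r > 0.8 (strict) in
at least 6 donors. Zero-variance profiles give r = NA, which never counts
as a pass — a flat gene has no trajectory to reproduce. The kept set is
monotone in both the r threshold and the donor count (tested).

Clustering operates on donor-averaged profiles, z-scored per gene
(population sd): the filter has already enforced donor concordance, so
averaging denoises without hiding discordance. Euclidean k-means with
k = 8 and 50 restarts (4-dimensional profiles cluster stably; the best of
50 inits by within-cluster SS is reproducible given the seed).

**Archetype labels.** Each z-scored centroid is labelled by (i) direction:
whichever of max−start and start−min is larger; (ii) peak timing: the
*first* timepoint within 0.1 z of the extremum — the plateau tolerance
matters because "rise early then hold" profiles are flat at the top and
noise would otherwise place the peak arbitrarily; a peak at the last
timepoint is *late*, at the second *early*, otherwise *mid*; (iii)
transience: the profile is *transient* when the endpoint has retraced at
least half of the start→extremum excursion (equivalently, ends closer to
the start than to the peak). The half-excursion rule separates the eight
generator archetypes exactly and is total over all orderings of four
values (tested exhaustively).

## Gene-set and GWAS enrichment

**Hypergeometric overlap.** Exact tails `P(X ≥ k)` (over) and `P(X ≤ k)`
(under) with X ~ Hypergeom(N, K, n) in an explicit, caller-supplied
universe (recommended: all genes tested for DE); genes outside the
universe are dropped with a log message. Both directions are reported;
matrix-wide BH is optional since raw p heatmaps and adjusted tables are
both common presentations. Being an exact discrete test, the null p is
conservative (super-uniform), not exactly uniform.

**GSEA.** Classic unweighted KS running sum (hit +1/|S|, miss −1/(N−|S|)),
ES = extremum by absolute value, p by the plus-one permutation estimator
over random same-size sets. The permutation comparison counts ties
(`|ES_perm| ≥ |ES_obs|`), which is conservative on discrete rankings; the
null mean p over 10⁴ draws is ≈ 0.51 at n_perm = 199.

**SNP windows.** SNPs are significant iff p < 5×10⁻⁸ strictly. A SNP is
linked to a gene when it lies within the window of the TSS, closed
interval, 0-based positions, strand ignored; a SNP may link to several
genes, and to several clusters — each cluster's test counts it
independently. The 2×2 table per (cluster, window) contrasts linked vs
unlinked SNPs by significance; Pearson χ² without continuity correction,
df = 1, computed in closed form `N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`; any
zero margin flags the result degenerate (p = NA). The default background
is *exclusive* (SNPs not linked to the cluster), keeping the two rows
disjoint so the χ² sampling model is valid; an *inclusive* mode (all SNPs)
is available behind a flag. Default window sweep: 50, 100, 250, 500,
1000, 2500 kb. No LD pruning or clumping is performed — SNPs are counted
as given.

## Motif activity, target scores, network statistics

**Model.** `E_gs = Σ_m N_gm A_ms + ε_gs` with E row-centred log expression
and N promoter motif counts. Per-sample ridge solution
`A_·s = (NᵀN + λI)⁻¹ Nᵀ E_·s`; λ = "auto" minimises 5-fold
cross-validated prediction error on held-out genes over a log grid
10⁻⁴…10⁴ (simpler and directly testable, compared with evidence
maximisation). Standard errors come from the ridge sandwich
`C NᵀN C` (C = (NᵀN+λI)⁻¹) with per-sample residual variance at
`df = G − tr(H)`. Row-centred E implies activities summing to zero across
samples, exactly.

**Differential activity.** `Σ_s (A_ms/se_ms)²` against χ² with S − 1 df
(one df lost to centring); default call at p < 10⁻³. Zero standard errors
(e.g. motifs absent from every gene) are flagged degenerate. The
correlation between samples induced by the shared design makes this test
approximate; under pure-noise expression the realised call rate at 10⁻³
stays below 1% (tested).

**Target scores.** `score(g,m) = N_gm · sd_s(A_m·)/σ_g` with σ_g the
gene's residual sd under the fitted model, floored at 10⁻⁶; an edge
requires score > 2 strictly. The score is a declared signal-to-noise
surrogate: a pair scores above 2 when the motif's activity swing,
multiplied through its site count, exceeds twice the gene's residual
noise. It is linear in the site count and zero exactly when the motif is
absent.

**NEAT.** For a directed network with W edges, source set A with total
out-degree o_A and target set B with total in-degree i_B, the observed
A→B edge count is referred to Hypergeom(W, i_B, o_A); p is the exact
upper tail and the expectation `o_A·i_B/W`. Expectations are additive
over disjoint target partitions, and the p equals brute-force enumeration
on all networks with W ≤ 12 (tested). Self-edges are retained. For
cluster-vs-cluster matrices the sources must carry out-degree; the
pipeline assigns each TF to the cluster containing the plurality of its
targets so that cluster source sets have degree mass, and logs that
mapping.

**Coexpression.** For each TF in the network measured in the pseudo-bulk
matrix: Spearman ρ (average ranks on ties) across ≥ 3 clusters between
the TF's expression and the summed expression of its targets; constant
TFs give ρ = NA and rank last. Any designated TF subset can then be
tested for leading-edge position in this ranking with the GSEA above.

## Synthetic-data generator

The generator emulates: (a) NB counts (Var = μ + αμ², default α = 0.05,
i.e. ~22% biological CV) with eight piecewise-log-linear temporal
archetypes peaking/dipping at day 2 (early, and transient which returns
to baseline by day 9), day 5 (mid) or day 9 (late), default peak
amplitude 2 log₂ units, half the genes null, and per-donor log-normal
library-size factors (sd 0.3) so size-factor estimation is non-trivial;
donor-discordant genes (default 10%) draw an independent archetype per
donor; (b) base means log-normal(5, 1) in natural log, i.e. median ≈ 150
counts; (c) a single 250 Mb linear chromosome with uniform TSSs — window
logic is pure position arithmetic, so one chromosome loses no generality;
SNPs uniform, significant with probability `sig_rate_near` within the
planted window of target-gene TSSs and `sig_rate_bg` elsewhere, p-values
uniform within the significant/non-significant ranges; (d) disjoint
TF target blocks with motif counts (Poisson(2)+1) exactly on true target
pairs, cluster-level expression following the MARA generative model with
noise sd 0.1, TF expression coupled to its latent activity with
correlation `coupling` (target noise scaled by √(1−coupling²) so perfect
coupling yields exactly monotone target sums); (e) a donor phenotype
uniform on [0, 1] whose signature genes are scaled by
`2^(slope·phenotype)` deterministically (rounded), so the planted means
are multiplied exactly without compounding sampling noise.

Not emulated: read-level data (no FASTQ/BAM), GC/length biases, outlier
samples and count outliers, correlated genes within archetypes beyond the
shared mean profile, LD between SNPs, multi-chromosome structure,
overlapping TF target sets, cell-level single-cell noise. Passing the
recovery tests therefore certifies the statistical machinery under the
stated generative assumptions, not robustness to artefacts real data may
contain.

Problem sizes used in tests and the acceptance script (2000 genes ×
8 donors × 4 timepoints for recovery; 5000 null genes for calibration;
2000 GWAS simulations of 4000 SNPs; 10⁴ GSEA draws) were chosen as the
smallest sizes at which the measured quantities are stable to well within
the asserted margins.

## Known limitations

- No exact numerical parity with DESeq2 (different dispersion estimator,
  no outlier replacement, no independent filtering, no LFC shrinkage);
  results that depend on those internals will not match gene-for-gene.
- The Wald phenotype test with 8 donors is anticonservative in the far
  tails; treat the 10⁻² FDR calls on real 8-donor data as candidate sets.
- The ISMARA target "score" is proprietary to that service; the
  signal-to-noise surrogate here is calibrated so that 2 means "twice the
  residual noise", not to equal ISMARA output.
- The χ² SNP-window test treats SNPs as exchangeable; with real LD the
  effective number of independent SNPs is smaller and p-values are
  optimistic. The window sweep (50–2500 kb) is a sensitivity display, not
  a multiple-testing-corrected scan.
- The exact discrete tests (hypergeometric, NEAT, permutation GSEA) are
  conservative by construction; their null p-values are super-uniform
  rather than uniform.
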