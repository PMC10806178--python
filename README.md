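# octempo

Time-course transcriptomics of human osteoclast differentiation, as a
tested, reusable Python library.

Osteoclasts — the bone-resorbing cells — differentiate from CD14⁺ monocyte
progenitors over roughly nine days of M-CSF/RANKL culture. A standard
study design profiles bulk RNA-seq from several donors at day 0 and a few
later days, asks which genes change over the course, groups them into
temporal expression patterns, and then connects those patterns outward: to
gene sets from other studies, to GWAS variants for bone-density traits, and
to the transcription-factor circuitry that drives them. `octempo`
implements that whole analysis chain for anyone running a donor × timepoint
count experiment, together with a synthetic-data generator that plants
every signal the chain is supposed to find, so each stage can be validated
by recovery rather than by eye.

## What it computes

- **Differential expression** (`octempo.de`). Median-of-ratios size
  factors; per-gene NB dispersion by method of moments shrunk toward an
  `a₀ + a₁/μ` trend; log-link negative-binomial GLMs fitted by IRLS,
  batched across genes. Timepoint effects use a likelihood-ratio test of
  `~ donor + timepoint` against `~ donor` (χ², df = T − 1, BH-adjusted,
  default call at FDR < 10⁻⁴). A continuous donor phenotype (e.g. %
  eroded bone surface) is tested per timepoint by a Wald test on the NB
  slope (default FDR < 10⁻²).
- **Temporal patterns** (`octempo.patterns`). A gene is *reproducible*
  when its per-donor log₂ profile has Pearson r > 0.8 with the cross-donor
  mean profile in at least 6 of 8 donors. Donor-averaged z-scored profiles
  of the reproducible DE genes are clustered by Euclidean k-means (k = 8)
  and each centroid is labelled with a temporal archetype: early / mid /
  late peak (or trough), or transient excursion.
- **Gene-set enrichment** (`octempo.enrichment`). Exact hypergeometric
  overlap tests of clusters against GMT collections within an explicit
  universe, and classic unweighted-KS GSEA with a set-permutation null.
- **GWAS TSS-window enrichment** (`octempo.gwas`). SNPs split at
  p < 5×10⁻⁸, linked to genes within a symmetric TSS window (50 kb–2.5 Mb
  sweep), and each cluster's significant:non-significant ratio contrasted
  against the rest of the genome by Pearson's χ² (df = 1).
- **Motif activity** (`octempo.mara`). MARA-style model
  `E_gs = Σ_m N_gm A_ms + ε`: ridge regression of row-centred log
  expression on promoter motif counts, penalty chosen by cross-validation;
  χ² test for motifs whose activity varies beyond its standard error
  (call at p < 10⁻³); TF→target edges where the signal-to-noise score
  `N_gm · sd(A_m)/σ_g` exceeds 2.
- **Regulatory network statistics** (`octempo.regnet`). Degree-conditioned
  directed network enrichment between gene groups
  (NEAT: `n_{A→B} ~ Hypergeom(W, i_B, o_A)`), per-TF regulator enrichment
  with BH, gene-signature sums over pseudo-bulk clusters, and TFs ranked by
  Spearman ρ between their own expression and their targets' summed
  expression.
- **Synthetic data** (`octempo.simulate`). NB counts with eight planted
  temporal archetypes, donor-consistent vs donor-discordant genes and
  log-normal donor library sizes; SNP maps with a planted excess of
  significant SNPs near chosen TSSs; planted TF→target networks with
  coupled pseudo-bulk expression; and a donor phenotype log-linearly
  coupled to a gene signature. All generators return ground truth and are
  bit-reproducible given a seed.
- **Pipeline** (`octempo.pipeline`, CLI `octempo`). Runs the stages end to
  end from a YAML config, writes TSV artifacts, the resolved config, and a
  SHA-256 manifest; `octempo run-all --seed 3 --outdir out/` or per-stage
  subcommands.

## Worked example

`examples/02_temporal_patterns.py` simulates the reference design
(2000 genes, 8 donors, days 0/2/5/9, NB dispersion 0.05, peak effect
2 log₂ units, half the genes null) and runs DE → filter → clustering:

```
reproducible genes: 798 of 2000
clustered 794 DE+reproducible genes into 8 temporal patterns
adjusted Rand index vs planted archetypes: 0.997
  cluster 1: early_up        (106 genes)
  cluster 2: late_down       (101 genes)
  cluster 3: transient_down  (100 genes)
  cluster 4: late_up         (104 genes)
  cluster 5: transient_up    (99 genes)
  cluster 6: early_down      (99 genes)
  cluster 7: mid_up          (94 genes)
  cluster 8: mid_down        (91 genes)
```

Reading this: the reproducibility filter keeps essentially all planted
donor-consistent signal genes (the null half of the transcriptome is flat,
hence uncorrelated across donors, and is removed), k-means then separates
the kept genes almost perfectly into the eight planted trajectories (ARI
0.997), and every centroid is labelled with the archetype that generated
it. The other examples cover DE and its donor blocking (`01`), the GWAS
window sweep (`03`), motif activity → network → NEAT → coexpression
(`04`), and phenotype association (`05`); each prints the numbers it
computes and one line on what they mean.

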