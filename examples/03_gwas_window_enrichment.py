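"""Test whether genome-wide-significant GWAS SNPs pile up near the TSSs of a
gene cluster, sweeping the TSS window from 50 kb to 2.5 Mb.

Prints the 2x2 chi-square enrichment per window for a cluster with a
planted excess of significant SNPs nearby and for a background cluster.
"""

import pandas as pd

import octempo as oc
from octempo.simulate import generate_annotation

ann = generate_annotation(400, seed=0)
target = set(ann["gene"][:60])  # the cluster with planted proximity signal
snps = oc.generate_gwas(ann, target, n_snps=50_000, window_bp=100_000,
                        sig_rate_near=0.3, sig_rate_bg=0.01, seed=1)
snps = oc.classify_snps(snps, alpha=5e-8)
print(f"{len(snps)} SNPs, {int(snps['significant'].sum())} genome-wide significant (p < 5e-8)")

clusters = pd.Series(
    [1 if g in target else 2 for g in ann["gene"]], index=pd.Index(ann["gene"])
)
res = oc.cluster_snp_enrichment(snps, ann, clusters,
                                windows=[50_000, 100_000, 500_000, 2_500_000])
for _, row in res.iterrows():
    print(f"  cluster {row['cluster']} window {row['window']//1000:>5d} kb: "
          f"sig/nonsig near = {row['a_cluster_sig']}/{row['b_cluster_nonsig']}, "
          f"chi2 = {row['chi2']:.1f}, p = {row['pvalue']:.2e}")
print("-> the planted cluster's enrichment peaks at the generating window and"
      " dilutes beyond it; the background cluster shows only the spillover of"
      " significant SNPs whose windows also cover a neighbouring TSS")
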