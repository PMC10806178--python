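"""Associate gene expression at one timepoint with a continuous donor
phenotype (resorption activity) by a NB GLM Wald test on the slope.

Prints the recovery of a planted 50-gene signature at FDR < 0.01.
"""

import octempo as oc

cfg = oc.SimulationConfig(n_genes=1000, n_donors=8, frac_null=1.0,
                          effect_log2fc=0.0, frac_discordant=0.0, seed=5)
cm, _ = oc.generate_timecourse(cfg)
signature = list(cm.genes[:50])
cm2, pheno = oc.generate_phenotype(cm, signature, slope_log2_per_unit=3.0, seed=6)
print("per-donor phenotype (resorption, scaled):",
      ", ".join(f"{v:.2f}" for v in pheno))

day = cm2.design["day"].max()
sub = cm2.subset_samples(cm2.design.index[cm2.design["day"] == day])
sf = oc.size_factors(cm2)
res = oc.phenotype_association(sub, sf.loc[sub.samples], None, pheno, pheno_fdr=1e-2)

n_assoc = int(res["associated"].sum())
recall = res.loc[signature, "associated"].mean()
print(f"resorption-associated genes at day {day:g} (FDR<0.01): {n_assoc}")
print(f"planted signature recovered: {recall:.0%}")
print("-> dispersion is re-estimated from the phenotype-model residuals, so"
      " the planted slope itself is not mistaken for biological noise")
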