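"""Simulate an osteoclast differentiation time course and test for
timepoint-dependent expression with the donor-blocked NB likelihood-ratio test.

Prints the number of genes called differentiation-associated at FDR < 1e-4
and the recall of the planted signal.
"""

import octempo as oc

cfg = oc.SimulationConfig(n_genes=1000, n_donors=8, effect_log2fc=2.0,
                          nb_dispersion=0.05, frac_null=0.5, seed=0)
cm, truth = oc.generate_timecourse(cfg)
print(f"counts: {cm.n_genes} genes x {cm.n_samples} samples "
      f"(8 donors, days {list(cfg.timepoints_days)})")

sf = oc.size_factors(cm)
disp = oc.estimate_dispersion(cm, sf)
res = oc.lrt_timepoint(cm, sf, disp, de_fdr=1e-4)

n_de = int(res["de"].sum())
signal = truth["archetype"] != "null"
consistent = signal & truth["donor_consistent"]
discordant = signal & ~truth["donor_consistent"]
fp = res.loc[~signal, "de"].sum()
print(f"differentiation-associated genes (FDR<1e-4): {n_de}")
print(f"recall, donor-consistent planted genes: {res.loc[consistent, 'de'].mean():.1%}")
print(f"recall, donor-discordant planted genes: {res.loc[discordant, 'de'].mean():.1%} "
      "(profiles cancel across donors)")
print(f"false positives among null genes: {int(fp)}")
print("-> the LRT contrasts ~donor+timepoint against ~donor, so donor-level"
      " library and baseline differences never masquerade as temporal signal")
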