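"""Filter genes for cross-donor reproducibility and cluster their temporal
profiles into the eight archetypes (early/mid/late/transient, up/down).

Prints how many genes survive the (Pearson r > 0.8 in >= 6 of 8 donors)
filter, the cluster centroids' archetype labels, and the agreement with the
planted truth.
"""

from sklearn.metrics import adjusted_rand_score

import octempo as oc

cfg = oc.SimulationConfig(n_genes=2000, n_donors=8, effect_log2fc=2.0,
                          nb_dispersion=0.05, frac_null=0.5, seed=1)
cm, truth = oc.generate_timecourse(cfg)
sf = oc.size_factors(cm)
disp = oc.estimate_dispersion(cm, sf)
de = oc.lrt_timepoint(cm, sf, disp)

prof = oc.donor_profiles(cm, sf)
kept, table = oc.reproducibility_filter(prof, r_threshold=0.8, min_donors=6)
print(f"reproducible genes: {len(kept)} of {cm.n_genes}")

genes = kept.intersection(de.index[de["de"]])
assign, centroids = oc.kmeans_cluster(prof.mean.loc[genes], k=8, seed=1)
ari = adjusted_rand_score(truth.loc[assign.index, "archetype"], assign["cluster"])
print(f"clustered {len(assign)} DE+reproducible genes into 8 temporal patterns")
print(f"adjusted Rand index vs planted archetypes: {ari:.3f}")
for cid, arch in oc.label_archetypes(centroids).items():
    n = (assign["cluster"] == cid).sum()
    print(f"  cluster {cid}: {arch:<15s} ({n} genes)")
print("-> each centroid is a z-scored log2 profile over days 0/2/5/9;"
      " labels follow peak timing and whether the excursion is retraced")
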