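"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates the study design the pipeline targets: CD14+
monocyte-derived osteoclast cultures from several donors, RNA harvested at
day 0 and three later days, counts summarised per gene.  Genes are planted
with one of eight temporal archetypes (early/mid/late/transient, up/down)
or left flat ("null"); counts are negative-binomial with per-donor
library-size factors.  Companion generators plant GWAS SNP maps with an
excess of significant SNPs near chosen TSSs, TF->target regulatory truth
with motif counts and coupled pseudo-bulk cluster expression, and a
continuous donor phenotype (resorption activity) log-linearly coupled to a
gene signature.  Every generator returns ground-truth labels so downstream
recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ARCHETYPES, NULL_ARCHETYPE, CountMatrix, RegulatoryNetwork

# log-normal donor library-size spread (sd of log size factors)
DONOR_SIZE_LOG_SD = 0.3
# log-normal base-mean distribution of expressed genes (log-space mean/sd)
BASE_MEAN_LOG_MU = 5.0
BASE_MEAN_LOG_SD = 1.0
# one linear synthetic chromosome; window logic is position arithmetic only
GENOME_SIZE_BP = 250_000_000
GENOME_WIDE_ALPHA = 5e-8


@dataclass
class SimulationConfig:
    """Parameters of the synthetic time course.

    Defaults mirror the emulated study design: 8 donors, harvest on days
    0/2/5/9, NB dispersion 0.05 (biological CV ~22%), peak planted effect
    of 2 log2 units, half the genes flat.
    """

    n_genes: int = 2000
    n_donors: int = 8
    timepoints_days: tuple = (0, 2, 5, 9)
    nb_dispersion: float = 0.05
    effect_log2fc: float = 2.0
    frac_null: float = 0.5
    frac_discordant: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise ValueError("need at least 2 donors (donor blocking unidentifiable)")
        if len(self.timepoints_days) < 3:
            raise ValueError("need at least 3 timepoints (temporal models unidentifiable)")
        days = np.asarray(self.timepoints_days, dtype=float)
        if np.any(np.diff(days) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        for name in ("frac_null", "frac_discordant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")


def archetype_profile(archetype: str, days, amplitude: float) -> np.ndarray:
    """Log2 fold-change trajectory of one archetype over the sampling days.

    Piecewise linear in log2 space: early/mid/late ramp from baseline to the
    peak at the second/third/last day and hold; transient peaks at the second
    day and returns to baseline by the last.  "down" archetypes are mirrored.
    """
    days = np.asarray(days, dtype=float)
    d0, d_early, d_mid, d_last = days[0], days[1], days[2], days[-1]
    sign = 1.0
    base = archetype
    if archetype.endswith("_down"):
        sign, base = -1.0, archetype[: -len("_down")] + "_up"
    if base == "null" or amplitude == 0:
        return np.zeros_like(days)
    if base == "early_up":
        prof = np.interp(days, [d0, d_early], [0.0, amplitude])
    elif base == "mid_up":
        prof = np.interp(days, [d0, d_mid], [0.0, amplitude])
    elif base == "late_up":
        prof = np.interp(days, [d0, d_last], [0.0, amplitude])
    elif base == "transient_up":
        prof = np.interp(days, [d0, d_early, d_last], [0.0, amplitude, 0.0])
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    return sign * prof


def _assign_archetypes(n_genes: int, frac_null: float, rng: np.random.Generator) -> np.ndarray:
    n_null = int(round(frac_null * n_genes))
    n_signal = n_genes - n_null
    labels = np.array(
        [NULL_ARCHETYPE] * n_null + [ARCHETYPES[i % len(ARCHETYPES)] for i in range(n_signal)],
        dtype=object,
    )
    rng.shuffle(labels)
    return labels


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with Var = mu + alpha*mu^2; alpha = 0 degenerates to Poisson."""
    if alpha == 0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_timecourse(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the donor x timepoint count matrix and its ground truth.

    Returns the CountMatrix (samples named ``D<donor>_T<day>``) and a truth
    table with per-gene archetype, base mean and donor-consistency flag.
    Donor-consistent genes share one temporal profile across donors;
    discordant genes get an independently drawn archetype per donor.
    """
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.timepoints_days, dtype=float)
    n_g, n_d, n_t = config.n_genes, config.n_donors, len(days)

    genes = pd.Index([f"G{i:05d}" for i in range(n_g)], name="gene")
    archetypes = _assign_archetypes(n_g, config.frac_null, rng)
    base_mean = rng.lognormal(BASE_MEAN_LOG_MU, BASE_MEAN_LOG_SD, size=n_g)

    signal_idx = np.flatnonzero(archetypes != NULL_ARCHETYPE)
    n_disc = min(int(round(config.frac_discordant * n_g)), signal_idx.size)
    discordant_idx = rng.choice(signal_idx, size=n_disc, replace=False)
    consistent = np.ones(n_g, dtype=bool)
    consistent[discordant_idx] = False

    profile_lut = {
        a: archetype_profile(a, days, config.effect_log2fc) for a in (*ARCHETYPES, NULL_ARCHETYPE)
    }
    # shared profile matrix (genes x timepoints), then per-donor overrides
    shared = np.stack([profile_lut[a] for a in archetypes])  # log2fc
    size_factors_true = rng.lognormal(0.0, DONOR_SIZE_LOG_SD, size=n_d)

    sample_ids, donor_col, day_col = [], [], []
    counts = np.empty((n_g, n_d * n_t), dtype=np.int64)
    col = 0
    for d in range(n_d):
        prof = shared.copy()
        if n_disc:
            per_donor = rng.choice(len(ARCHETYPES), size=n_disc)
            prof[discordant_idx] = np.stack(
                [profile_lut[ARCHETYPES[k]] for k in per_donor]
            )
        mu = size_factors_true[d] * base_mean[:, None] * np.exp2(prof)
        for t in range(n_t):
            counts[:, col] = _nb_sample(rng, mu[:, t], config.nb_dispersion)
            sample_ids.append(f"D{d + 1}_T{days[t]:g}")
            donor_col.append(f"D{d + 1}")
            day_col.append(days[t])
            col += 1

    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=sample_ids),
        pd.DataFrame({"donor": donor_col, "day": day_col}, index=pd.Index(sample_ids, name="sample")),
    )
    truth = pd.DataFrame(
        {
            "archetype": archetypes,
            "base_mean": base_mean,
            "donor_consistent": consistent,
        },
        index=genes,
    )
    return cm, truth


def generate_annotation(n_genes: int, seed: int = 0, genome_size: int = GENOME_SIZE_BP) -> pd.DataFrame:
    """Uniformly placed TSSs on one linear synthetic chromosome."""
    rng = np.random.default_rng(seed)
    tss = np.sort(rng.integers(0, genome_size, size=n_genes))
    return pd.DataFrame(
        {
            "gene": [f"G{i:05d}" for i in range(n_genes)],
            "chrom": "chr1",
            "tss": tss,
            "strand": rng.choice(["+", "-"], size=n_genes),
        }
    )


def generate_gwas(
    annotation: pd.DataFrame,
    target_genes,
    n_snps: int,
    window_bp: int,
    sig_rate_near: float,
    sig_rate_bg: float,
    seed: int = 0,
    genome_size: int = GENOME_SIZE_BP,
) -> pd.DataFrame:
    """SNP map with a planted excess of genome-wide-significant SNPs near
    the TSSs of ``target_genes``.

    SNP positions are uniform; a SNP within ``window_bp`` of a target TSS is
    significant (p drawn below 5e-8) with probability ``sig_rate_near``,
    otherwise with probability ``sig_rate_bg``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    for name, rate in (("sig_rate_near", sig_rate_near), ("sig_rate_bg", sig_rate_bg)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if annotation.empty:
        raise ValueError("annotation must be non-empty")
    rng = np.random.default_rng(seed)
    cols = ["snp", "chrom", "pos", "pval"]
    if n_snps == 0:
        return pd.DataFrame(columns=cols)

    pos = rng.integers(0, genome_size, size=n_snps)
    target = annotation.loc[annotation["gene"].isin(set(target_genes))]
    tss = np.sort(target["tss"].to_numpy())
    lo = np.searchsorted(tss, pos - window_bp, side="left")
    hi = np.searchsorted(tss, pos + window_bp, side="right")
    near = hi > lo

    p_sig = np.where(near, sig_rate_near, sig_rate_bg)
    sig = rng.random(n_snps) < p_sig
    pval = np.where(
        sig,
        rng.uniform(0.0, GENOME_WIDE_ALPHA, size=n_snps),
        rng.uniform(GENOME_WIDE_ALPHA, 1.0, size=n_snps),
    )
    return pd.DataFrame(
        {"snp": [f"rs{i}" for i in range(n_snps)], "chrom": "chr1", "pos": pos, "pval": pval}
    )


def generate_regulatory_truth(
    n_tfs: int,
    n_genes: int,
    targets_per_tf: int,
    n_clusters: int,
    coupling: float,
    seed: int = 0,
    noise_sd: float = 0.1,
    motif_mean_sites: float = 2.0,
) -> tuple[RegulatoryNetwork, pd.DataFrame, pd.DataFrame]:
    """Planted TF->target truth with motif counts and pseudo-bulk expression.

    Each TF m has a latent motif activity a_m(c), centred across the
    ``n_clusters`` pseudo-bulk clusters.  Target-gene expression follows the
    MARA generative model E_gc = N_gm a_m(c) + noise, with motif counts
    N_gm > 0 exactly on true targets.  The TF's own expression is
    ``coupling * a_m + sqrt(1-coupling^2) * xi_m`` so the Pearson correlation
    between TF expression and the summed expression of its targets tends to
    ``coupling`` as the number of clusters grows; target noise is scaled by
    ``sqrt(1-coupling^2)`` so perfect coupling gives exactly monotone sums.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    if targets_per_tf > n_genes:
        raise ValueError("targets_per_tf cannot exceed n_genes")
    if n_tfs * targets_per_tf > n_genes:
        raise ValueError("disjoint target sets require n_tfs * targets_per_tf <= n_genes")
    rng = np.random.default_rng(seed)

    tfs = [f"TF{m:03d}" for m in range(n_tfs)]
    genes = [f"G{i:05d}" for i in range(n_genes)]
    perm = rng.permutation(n_genes)

    activity = rng.normal(0.0, 1.0, size=(n_tfs, n_clusters))
    activity -= activity.mean(axis=1, keepdims=True)

    motif = np.zeros((n_genes, n_tfs))
    expr = rng.normal(0.0, noise_sd, size=(n_genes, n_clusters))
    edges = []
    residual_scale = np.sqrt(max(0.0, 1.0 - coupling**2))
    for m in range(n_tfs):
        tgt = perm[m * targets_per_tf : (m + 1) * targets_per_tf]
        sites = rng.poisson(motif_mean_sites, size=tgt.size) + 1
        motif[tgt, m] = sites
        expr[tgt] = sites[:, None] * activity[m][None, :] + residual_scale * rng.normal(
            0.0, noise_sd, size=(tgt.size, n_clusters)
        )
        edges.extend((tfs[m], genes[g]) for g in tgt)

    tf_expr = coupling * activity + residual_scale * rng.normal(0.0, 1.0, size=(n_tfs, n_clusters))

    cluster_ids = [f"C{c}" for c in range(n_clusters)]
    cluster_expr = pd.DataFrame(
        np.hstack([expr.T, tf_expr.T]),  # clusters x (genes + tfs)
        index=cluster_ids,
        columns=genes + tfs,
    )
    motif_counts = pd.DataFrame(motif, index=genes, columns=tfs)
    net = RegulatoryNetwork(
        pd.DataFrame(edges, columns=["source", "target"]).assign(score=np.nan)
        if edges
        else pd.DataFrame(columns=["source", "target", "score"])
    )
    return net, motif_counts, cluster_expr


def generate_phenotype(
    cm: CountMatrix, signature, slope_log2_per_unit: float, seed: int = 0
) -> tuple[CountMatrix, pd.Series]:
    """Couple a donor phenotype (resorption activity, scaled to [0, 1]) to a
    gene signature.

    Per-donor phenotype ~ Uniform(0, 1); counts of signature genes are
    scaled by 2^(slope * phenotype) and rounded, so their means are
    multiplied exactly without injecting additional sampling noise; other
    genes are untouched.
    """
    signature = list(signature)
    if not signature:
        raise ValueError("signature must be non-empty")
    missing = set(signature) - set(cm.genes)
    if missing:
        raise ValueError(f"signature genes absent from counts: {sorted(missing)[:5]} ...")
    rng = np.random.default_rng(seed)
    donors = pd.unique(cm.design["donor"])
    pheno = pd.Series(rng.uniform(0.0, 1.0, size=len(donors)), index=donors, name="phenotype")

    counts = cm.counts.copy()
    if slope_log2_per_unit != 0.0:
        sig_idx = counts.index.get_indexer(signature)
        base = counts.iloc[sig_idx].to_numpy().astype(float)
        factor = np.exp2(
            slope_log2_per_unit * pheno.loc[cm.design["donor"]].to_numpy()
        )[None, :]
        counts.iloc[sig_idx] = np.rint(base * factor).astype(np.int64)
    return CountMatrix(counts, cm.design.copy()), pheno
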