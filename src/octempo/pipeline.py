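"""End-to-end orchestration of the analysis stages with fixed on-disk artifacts.

Stages (each skippable, each a pure function of its declared inputs):
simulate -> de -> filter -> cluster -> enrich -> gwas -> mara -> network ->
coexpr.  A run writes every stage's tables to the output directory, the
resolved configuration beside them, and a manifest listing each artifact
with its SHA-256 checksum.  One global seed is fanned out to per-stage
seeds by fixed offsets so skipping stages never changes the randomness of
the ones that run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de, enrichment, gwas, mara, patterns, regnet, simulate
from .containers import ARCHETYPES
from .io import read_counts, read_gwas, read_matrix, write_counts, write_gmt, write_matrix

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "simulate",
    "de",
    "filter",
    "cluster",
    "enrich",
    "gwas",
    "mara",
    "network",
    "coexpr",
)
_STAGE_SEED_OFFSET = {name: 1000 + 97 * i for i, name in enumerate(STAGE_ORDER)}


class StageError(RuntimeError):
    """Failure of a named pipeline stage; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Resolved configuration; thresholds default to the study's values."""

    outdir: str = "octempo_out"
    seed: int = 0
    # synthetic-data block
    n_genes: int = 2000
    n_donors: int = 8
    timepoints_days: tuple = (0, 2, 5, 9)
    nb_dispersion: float = 0.05
    effect_log2fc: float = 2.0
    frac_null: float = 0.5
    frac_discordant: float = 0.1
    # analysis thresholds
    de_fdr: float = 1e-4
    pheno_fdr: float = 1e-2
    r_threshold: float = 0.8
    min_donors: int = 6
    k: int = 8
    n_init: int = 50
    snp_alpha: float = 5e-8
    windows_bp: tuple = gwas.DEFAULT_WINDOWS_BP
    target_score: float = 2.0
    activity_p: float = 1e-3
    # synthetic GWAS / regulatory blocks
    n_snps: int = 20000
    gwas_window_bp: int = 100_000
    sig_rate_near: float = 0.25
    sig_rate_bg: float = 0.01
    n_tfs: int = 40
    targets_per_tf: int = 25
    n_clusters_sc: int = 30
    coupling: float = 0.8

    def __post_init__(self) -> None:
        checks = {
            "de_fdr": 0 < self.de_fdr < 1,
            "pheno_fdr": 0 < self.pheno_fdr < 1,
            "r_threshold": -1 <= self.r_threshold <= 1,
            "min_donors": 1 <= self.min_donors <= self.n_donors,
            "k": self.k >= 2,
            "snp_alpha": 0 < self.snp_alpha < 1,
            "target_score": self.target_score >= 0,
            "activity_p": 0 < self.activity_p < 1,
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"configuration values out of range: {bad}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _STAGE_SEED_OFFSET[stage]) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _out(cfg: PipelineConfig, name: str) -> Path:
    return Path(cfg.outdir) / name


# ---------------------------------------------------------------------------
# stages; each loads what it needs from disk so stages can be skipped


def _stage_simulate(cfg: PipelineConfig, ctx: dict) -> None:
    sim_cfg = simulate.SimulationConfig(
        n_genes=cfg.n_genes,
        n_donors=cfg.n_donors,
        timepoints_days=tuple(cfg.timepoints_days),
        nb_dispersion=cfg.nb_dispersion,
        effect_log2fc=cfg.effect_log2fc,
        frac_null=cfg.frac_null,
        frac_discordant=cfg.frac_discordant,
        seed=cfg.stage_seed("simulate"),
    )
    cm, truth = simulate.generate_timecourse(sim_cfg)
    ctx["counts"], ctx["truth"] = cm, truth
    write_counts(cm, _out(cfg, "counts.tsv"), _out(cfg, "design.tsv"))
    truth.to_csv(_out(cfg, "truth.tsv"), sep="\t")

    planted = {
        f"planted_{a}": set(truth.index[truth["archetype"] == a]) for a in ARCHETYPES
    }
    write_gmt(planted, _out(cfg, "planted_sets.gmt"))
    ctx["planted_sets"] = planted

    ann = simulate.generate_annotation(cfg.n_genes, seed=cfg.stage_seed("simulate") + 1)
    ann.to_csv(_out(cfg, "annotation.tsv"), sep="\t", index=False)
    ctx["annotation"] = ann

    target_genes = planted["planted_early_up"]
    snps = simulate.generate_gwas(
        ann,
        target_genes,
        n_snps=cfg.n_snps,
        window_bp=cfg.gwas_window_bp,
        sig_rate_near=cfg.sig_rate_near,
        sig_rate_bg=cfg.sig_rate_bg,
        seed=cfg.stage_seed("simulate") + 2,
    )
    snps.to_csv(_out(cfg, "gwas.tsv"), sep="\t", index=False)
    ctx["snps"] = snps

    net_truth, motif_counts, cluster_expr = simulate.generate_regulatory_truth(
        n_tfs=cfg.n_tfs,
        n_genes=cfg.n_genes,
        targets_per_tf=cfg.targets_per_tf,
        n_clusters=cfg.n_clusters_sc,
        coupling=cfg.coupling,
        seed=cfg.stage_seed("simulate") + 3,
    )
    net_truth.edges.to_csv(_out(cfg, "true_edges.tsv"), sep="\t", index=False)
    write_matrix(motif_counts, _out(cfg, "motif_counts.tsv"))
    write_matrix(cluster_expr, _out(cfg, "cluster_expr.tsv"))
    ctx["motif_counts"], ctx["cluster_expr"] = motif_counts, cluster_expr


def _need_counts(cfg: PipelineConfig, ctx: dict):
    if "counts" not in ctx:
        ctx["counts"] = read_counts(_out(cfg, "counts.tsv"), _out(cfg, "design.tsv"))
    return ctx["counts"]


def _stage_de(cfg: PipelineConfig, ctx: dict) -> None:
    cm = _need_counts(cfg, ctx)
    sf = de.size_factors(cm)
    disp = de.estimate_dispersion(cm, sf)
    res = de.lrt_timepoint(cm, sf, disp, de_fdr=cfg.de_fdr)
    ctx["size_factors"], ctx["dispersion"], ctx["de"] = sf, disp, res
    sf.to_csv(_out(cfg, "size_factors.tsv"), sep="\t")
    res.to_csv(_out(cfg, "de.tsv"), sep="\t")


def _stage_filter(cfg: PipelineConfig, ctx: dict) -> None:
    cm = _need_counts(cfg, ctx)
    sf = ctx.get("size_factors")
    if sf is None:
        sf = de.size_factors(cm)
        ctx["size_factors"] = sf
    profiles = patterns.donor_profiles(cm, sf)
    kept, table = patterns.reproducibility_filter(
        profiles, r_threshold=cfg.r_threshold, min_donors=cfg.min_donors
    )
    ctx["profiles"], ctx["kept"], ctx["repro"] = profiles, kept, table
    table.to_csv(_out(cfg, "reproducibility.tsv"), sep="\t")


def _stage_cluster(cfg: PipelineConfig, ctx: dict) -> None:
    if "de" not in ctx:
        ctx["de"] = pd.read_csv(_out(cfg, "de.tsv"), sep="\t", index_col=0)
    if "profiles" not in ctx:
        _stage_filter(cfg, ctx)
    de_genes = ctx["de"].index[ctx["de"]["fdr"] < cfg.de_fdr]
    genes = ctx["kept"].intersection(de_genes)
    assignment, centroids = patterns.kmeans_cluster(
        ctx["profiles"].mean.loc[genes],
        k=cfg.k,
        n_init=cfg.n_init,
        seed=cfg.stage_seed("cluster"),
    )
    ctx["clusters"], ctx["centroids"] = assignment, centroids
    assignment.to_csv(_out(cfg, "clusters.tsv"), sep="\t")
    centroids.to_csv(_out(cfg, "centroids.tsv"), sep="\t")


def _need_clusters(cfg: PipelineConfig, ctx: dict) -> pd.DataFrame:
    if "clusters" not in ctx:
        ctx["clusters"] = pd.read_csv(_out(cfg, "clusters.tsv"), sep="\t", index_col=0)
    return ctx["clusters"]


def _stage_enrich(cfg: PipelineConfig, ctx: dict) -> None:
    clusters = _need_clusters(cfg, ctx)
    if "planted_sets" not in ctx:
        from .io import read_gmt

        ctx["planted_sets"] = read_gmt(_out(cfg, "planted_sets.gmt"))
    if "de" not in ctx:
        ctx["de"] = pd.read_csv(_out(cfg, "de.tsv"), sep="\t", index_col=0)
    universe = set(ctx["de"].index[ctx["de"]["status"] == "tested"])
    coll = enrichment.GeneSetCollection(ctx["planted_sets"], universe)
    queries = {
        f"cluster_{cid}": set(clusters.index[clusters["cluster"] == cid])
        for cid in sorted(clusters["cluster"].unique())
    }
    res = enrichment.enrich_matrix(queries, coll, adjust=True)
    ctx["enrichment"] = res
    res.to_csv(_out(cfg, "enrichment.tsv"), sep="\t", index=False)


def _stage_gwas(cfg: PipelineConfig, ctx: dict) -> None:
    if "snps" not in ctx:
        ctx["snps"] = read_gwas(_out(cfg, "gwas.tsv"))
    if "annotation" not in ctx:
        from .io import read_annotation

        ctx["annotation"] = read_annotation(_out(cfg, "annotation.tsv"))
    clusters = _need_clusters(cfg, ctx)
    snps = gwas.classify_snps(ctx["snps"], alpha=cfg.snp_alpha)
    res = gwas.cluster_snp_enrichment(
        snps, ctx["annotation"], clusters["cluster"], windows=cfg.windows_bp
    )
    ctx["gwas_enrichment"] = res
    res.to_csv(_out(cfg, "gwas_enrichment.tsv"), sep="\t", index=False)
    # cluster x window matrix of -log10 p for quick inspection
    mat = res.pivot(index="cluster", columns="window", values="pvalue")
    write_matrix(-np.log10(mat.clip(lower=1e-300)), _out(cfg, "gwas_minus_log10p.tsv"))


def _stage_mara(cfg: PipelineConfig, ctx: dict) -> None:
    if "motif_counts" not in ctx:
        ctx["motif_counts"] = read_matrix(_out(cfg, "motif_counts.tsv"))
    if "cluster_expr" not in ctx:
        ctx["cluster_expr"] = read_matrix(_out(cfg, "cluster_expr.tsv"))
    E = ctx["cluster_expr"].T  # genes x clusters
    E = E - E.to_numpy().mean(axis=1, keepdims=True)
    act = mara.fit_motif_activity(E, ctx["motif_counts"], ridge_lambda="auto", seed=cfg.stage_seed("mara"))
    sig = mara.activity_significance(act, p_threshold=cfg.activity_p)
    scores = mara.score_targets(ctx["motif_counts"], act, threshold=cfg.target_score)
    ctx["activity"], ctx["activity_sig"], ctx["target_scores"] = act, sig, scores
    write_matrix(act.activity, _out(cfg, "activity.tsv"))
    sig.to_csv(_out(cfg, "activity_significance.tsv"), sep="\t")
    scores.to_csv(_out(cfg, "target_scores.tsv"), sep="\t", index=False)


def _stage_network(cfg: PipelineConfig, ctx: dict) -> None:
    if "target_scores" not in ctx:
        ctx["target_scores"] = pd.read_csv(_out(cfg, "target_scores.tsv"), sep="\t")
    net = regnet.build_network(ctx["target_scores"], threshold=cfg.target_score)
    ctx["network"] = net
    net.edges.to_csv(_out(cfg, "edges.tsv"), sep="\t", index=False)

    clusters = _need_clusters(cfg, ctx)
    groups: dict[str, set] = {
        f"cluster_{cid}": set(clusters.index[clusters["cluster"] == cid])
        for cid in sorted(clusters["cluster"].unique())
    }
    # assign each TF to the temporal cluster holding most of its targets so
    # cluster-vs-cluster NEAT has sources with out-degree mass
    cl = clusters["cluster"]
    for tf in net.out_degree.index:
        tgt = [t for t in net.targets_of(tf) if t in cl.index]
        if not tgt:
            continue
        modal = cl.loc[tgt].mode().iloc[0]
        groups[f"cluster_{modal}"].add(tf)
    res = regnet.neat_matrix(net, groups, sources_are_tfs=True)
    ctx["neat"] = res
    res.to_csv(_out(cfg, "neat.tsv"), sep="\t", index=False)


def _stage_coexpr(cfg: PipelineConfig, ctx: dict) -> None:
    if "network" not in ctx:
        edges = pd.read_csv(_out(cfg, "edges.tsv"), sep="\t")
        from .containers import RegulatoryNetwork

        ctx["network"] = RegulatoryNetwork(edges)
    if "cluster_expr" not in ctx:
        ctx["cluster_expr"] = read_matrix(_out(cfg, "cluster_expr.tsv"))
    ranking = regnet.tf_target_coexpression(ctx["cluster_expr"], ctx["network"])
    ctx["coexpression"] = ranking
    ranking.to_csv(_out(cfg, "coexpression.tsv"), sep="\t", index=False)
    # GSEA of the differential-activity TFs within the coexpression ranking
    if "activity_sig" in ctx and not ranking.empty:
        diff_tfs = set(ctx["activity_sig"].index[ctx["activity_sig"]["differential"]])
        ranked = ranking.dropna(subset=["rho"])
        subset = diff_tfs & set(ranked["tf"])
        if 0 < len(subset) < len(ranked):
            res = enrichment.gsea(
                list(ranked["tf"]), subset, n_perm=999, seed=cfg.stage_seed("coexpr")
            )
            with open(_out(cfg, "coexpression_gsea.json"), "w") as fh:
                json.dump(res, fh, indent=2)


_STAGES = {
    "simulate": _stage_simulate,
    "de": _stage_de,
    "filter": _stage_filter,
    "cluster": _stage_cluster,
    "enrich": _stage_enrich,
    "gwas": _stage_gwas,
    "mara": _stage_mara,
    "network": _stage_network,
    "coexpr": _stage_coexpr,
}


def run_all(cfg: PipelineConfig, stages=None) -> dict:
    """Run the requested stages in order; returns the output manifest."""
    selected = list(STAGE_ORDER) if stages is None else [s for s in STAGE_ORDER if s in set(stages)]
    unknown = set(stages or []) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)

    ctx: dict = {}
    timings = {}
    for stage in selected:
        t0 = time.perf_counter()
        logger.info("stage %s starting", stage)
        try:
            _STAGES[stage](cfg, ctx)
        except Exception as exc:  # noqa: BLE001 - halt with stage name, keep partial outputs
            raise StageError(stage, exc) from exc
        timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", stage, timings[stage])

    files = sorted(p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "stages": selected,
        "timings_s": timings,
        "seed": cfg.seed,
        "files": {p.name: _sha256(p) for p in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
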