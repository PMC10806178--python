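"""SNP-density enrichment of temporal clusters from GWAS summary statistics.

SNPs are split into genome-wide significant (p < 5e-8, strict) and
non-significant, linked to genes when they fall within a symmetric window
of the transcription start site (closed interval, strand ignored), and each
cluster's ratio of significant to non-significant linked SNPs is contrasted
against the remaining genome with a Pearson chi-square test (df = 1, no
continuity correction), swept over a grid of window sizes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GENOME_WIDE_ALPHA = 5e-8
DEFAULT_WINDOWS_BP = (50_000, 100_000, 250_000, 500_000, 1_000_000, 2_500_000)


def classify_snps(snps: pd.DataFrame, alpha: float = GENOME_WIDE_ALPHA) -> pd.DataFrame:
    """Add a strict ``significant`` flag (pval < alpha)."""
    out = snps.copy()
    if len(out):
        p = out["pval"].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
            raise ValueError("p-values must lie in [0, 1]")
        out["significant"] = p < alpha
    else:
        out["significant"] = pd.Series(dtype=bool)
    return out


def _link_mask(snps: pd.DataFrame, ann: pd.DataFrame, window: int) -> np.ndarray:
    """Boolean per SNP: within ``window`` bp of >= 1 annotated TSS (closed)."""
    linked = np.zeros(len(snps), dtype=bool)
    ann_chroms = set(ann["chrom"])
    for chrom, idx in snps.groupby("chrom").groups.items():
        if chrom not in ann_chroms:
            logger.warning("chromosome %r absent from annotation; SNPs unlinked", chrom)
            continue
        tss = np.sort(ann.loc[ann["chrom"] == chrom, "tss"].to_numpy())
        pos = snps.loc[idx, "pos"].to_numpy()
        lo = np.searchsorted(tss, pos - window, side="left")
        hi = np.searchsorted(tss, pos + window, side="right")
        linked[snps.index.get_indexer(idx)] = hi > lo
    return linked


def assign_snps_to_genes(
    snps: pd.DataFrame, ann: pd.DataFrame, window: int
) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Link SNPs to every gene whose TSS lies within ``window`` bp.

    Returns per-gene significant / non-significant SNP counts and, per SNP,
    the array of annotation row indices of its linked genes (a SNP may link
    to several genes).  ``snps`` must carry the ``significant`` flag.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    snps = snps.reset_index(drop=True)
    n_sig = np.zeros(len(ann), dtype=int)
    n_nonsig = np.zeros(len(ann), dtype=int)
    per_snp: list[np.ndarray] = [np.empty(0, dtype=int)] * len(snps)

    for chrom, sub in snps.groupby("chrom"):
        ann_rows = np.flatnonzero((ann["chrom"] == chrom).to_numpy())
        if ann_rows.size == 0:
            logger.warning("chromosome %r absent from annotation; SNPs unlinked", chrom)
            continue
        order = np.argsort(ann["tss"].to_numpy()[ann_rows])
        ann_sorted = ann_rows[order]
        tss = ann["tss"].to_numpy()[ann_sorted]
        pos = sub["pos"].to_numpy()
        sig = sub["significant"].to_numpy()
        lo = np.searchsorted(tss, pos - window, side="left")
        hi = np.searchsorted(tss, pos + window, side="right")
        for i, (a, b, s, row) in enumerate(zip(lo, hi, sig, sub.index)):
            genes = ann_sorted[a:b]
            per_snp[row] = genes
            if s:
                n_sig[genes] += 1
            else:
                n_nonsig[genes] += 1

    per_gene = pd.DataFrame(
        {"gene": ann["gene"], "n_sig": n_sig, "n_nonsig": n_nonsig}
    ).set_index("gene")
    return per_gene, per_snp


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) for a 2x2 table."""
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        return np.nan, np.nan
    num = n * (a * d - b * c) ** 2
    den = margins[0] * margins[1] * margins[2] * margins[3]
    chi2 = num / den
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cluster_snp_enrichment(
    snps: pd.DataFrame,
    ann: pd.DataFrame,
    clusters: pd.Series,
    windows=DEFAULT_WINDOWS_BP,
    background: str = "exclusive",
) -> pd.DataFrame:
    """Chi-square SNP-density enrichment per (cluster, window).

    The 2x2 table contrasts SNPs linked to >= 1 gene of the cluster against
    the remaining SNPs ("exclusive" background; "inclusive" compares
    against all SNPs), split by genome-wide significance.  A SNP near the
    genes of several clusters counts for each of those clusters.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("windows must be non-empty")
    if background not in ("exclusive", "inclusive"):
        raise ValueError("background must be 'exclusive' or 'inclusive'")
    if "significant" not in snps.columns:
        snps = classify_snps(snps)
    sig = snps["significant"].to_numpy()
    total_sig = int(sig.sum())
    total_nonsig = int((~sig).sum())

    rows = []
    for window in windows:
        if window <= 0:
            raise ValueError("window must be positive")
        for cluster_id in sorted(pd.unique(clusters)):
            genes = set(clusters.index[clusters == cluster_id])
            sub_ann = ann.loc[ann["gene"].isin(genes)]
            linked = (
                _link_mask(snps, sub_ann, window)
                if not sub_ann.empty
                else np.zeros(len(snps), dtype=bool)
            )
            a = int(np.sum(linked & sig))
            b = int(np.sum(linked & ~sig))
            if background == "exclusive":
                c, d = total_sig - a, total_nonsig - b
            else:
                c, d = total_sig, total_nonsig
            chi2, p = chi2_2x2(a, b, c, d)
            rows.append(
                {
                    "cluster": cluster_id,
                    "window": window,
                    "a_cluster_sig": a,
                    "b_cluster_nonsig": b,
                    "c_other_sig": c,
                    "d_other_nonsig": d,
                    "chi2": chi2,
                    "df": 1,
                    "pvalue": p,
                    "ratio_cluster": a / b if b else np.nan,
                    "ratio_genome": c / d if d else np.nan,
                    "degenerate": not np.isfinite(chi2) if chi2 == chi2 else True,
                }
            )
    out = pd.DataFrame(rows)
    out["degenerate"] = ~np.isfinite(out["chi2"].to_numpy())
    return out
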