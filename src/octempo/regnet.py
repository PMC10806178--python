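"""Directed regulatory-network statistics.

Assembles TF->target edges from target scores, tests whether one gene
group sends more edges into another than its degrees predict (NEAT-style
central hypergeometric model for directed networks), finds regulators whose
target sets over-represent a gene group (hypergeometric + BH), and ranks
TFs by the Spearman correlation between their own expression and the
summed expression of their targets across pseudo-bulk clusters.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RegulatoryNetwork
from .de import bh_adjust
from .enrichment import hypergeom_overlap

logger = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 2.0


def build_network(scores: pd.DataFrame, threshold: float = DEFAULT_SCORE_THRESHOLD) -> RegulatoryNetwork:
    """Keep (source, target) pairs with score strictly above ``threshold``."""
    if (scores["score"].dropna() < 0).any():
        raise ValueError("target scores must be non-negative")
    kept = scores.loc[scores["score"] > threshold, ["source", "target", "score"]]
    if kept.empty:
        warnings.warn("no edge above the score threshold; network is empty", stacklevel=2)
    return RegulatoryNetwork(kept.reset_index(drop=True))


def neat_test(net: RegulatoryNetwork, sources, targets) -> dict:
    """Directed network enrichment of A -> B edges.

    With W total edges, o_A the summed out-degree of A and i_B the summed
    in-degree of B, the observed A->B edge count is referred to
    Hypergeom(W, i_B, o_A); p is the exact upper tail (over-enrichment).
    """
    A, B = set(sources), set(targets)
    o_A = int(net.out_degree.reindex(A).fillna(0).sum())
    i_B = int(net.in_degree.reindex(B).fillna(0).sum())
    if o_A == 0 or i_B == 0:
        raise ValueError(
            f"NEAT test undefined: total out-degree of A is {o_A}, total in-degree of B is {i_B}"
        )
    W = net.W
    mask = net.edges["source"].isin(A) & net.edges["target"].isin(B)
    n_AB = int(mask.sum())
    expected = o_A * i_B / W
    p = float(stats.hypergeom.sf(n_AB - 1, W, i_B, o_A))
    return {
        "o_A": o_A,
        "i_B": i_B,
        "W": W,
        "n_AB": n_AB,
        "expected": expected,
        "pvalue": p,
    }


def neat_matrix(net: RegulatoryNetwork, groups: dict[str, set], sources_are_tfs: bool = True) -> pd.DataFrame:
    """All-pairs NEAT tests between named gene groups (e.g. clusters).

    Source sets are restricted to nodes with out-degree (TFs in the
    network) when ``sources_are_tfs`` is set; pairs with zero out- or
    in-degree are skipped with a log message.
    """
    tf_nodes = set(net.out_degree.index)
    rows = []
    for a_name, a in groups.items():
        src = set(a) & tf_nodes if sources_are_tfs else set(a)
        for b_name, b in groups.items():
            try:
                res = neat_test(net, src, b)
            except ValueError:
                logger.info("skipping NEAT %s->%s (no degree mass)", a_name, b_name)
                continue
            rows.append({"source_group": a_name, "target_group": b_name, **res})
    return pd.DataFrame(rows)


def regulator_enrichment(net: RegulatoryNetwork, group, universe) -> pd.DataFrame:
    """Per-TF hypergeometric enrichment of its targets in a gene group.

    TFs without targets are skipped; p-values are BH-adjusted across TFs.
    """
    rows = []
    for tf in net.out_degree.index:
        targets = net.targets_of(tf)
        if not targets:
            continue
        rows.append(hypergeom_overlap(targets, group, universe, name_query=tf, name_set="group"))
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.rename(columns={"query": "tf"})
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def signature_sum(expr: pd.DataFrame, gene_set) -> pd.Series:
    """Summed expression of a gene signature per cluster (or cell).

    ``expr`` is clusters x genes.  Genes absent from the matrix are logged;
    an empty intersection is an error.
    """
    members = list(dict.fromkeys(gene_set))
    present = [g for g in members if g in expr.columns]
    missing = len(members) - len(present)
    if not present:
        raise ValueError("no signature gene is present in the expression matrix")
    if missing:
        logger.info("%d signature genes absent from the expression matrix", missing)
    return expr[present].sum(axis=1)


def tf_target_coexpression(expr: pd.DataFrame, net: RegulatoryNetwork) -> pd.DataFrame:
    """Rank TFs by Spearman correlation with their targets' summed expression.

    Correlation is computed across pseudo-bulk clusters (>= 3 required)
    with average ranks on ties.  TFs with constant expression get rho = NA
    and are placed last.
    """
    if expr.shape[0] < 3:
        raise ValueError("need >= 3 clusters for rank correlation")
    rows = []
    for tf in net.out_degree.index:
        if tf not in expr.columns:
            logger.info("TF %s not measured; skipped", tf)
            continue
        targets = [t for t in net.targets_of(tf) if t in expr.columns]
        if not targets:
            continue
        x = expr[tf].to_numpy(dtype=float)
        y = signature_sum(expr, targets).to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rho = np.nan
        else:
            rho = float(stats.spearmanr(x, y).statistic)
        rows.append({"tf": tf, "rho": rho, "n_targets": len(targets)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    return out.sort_values("rho", ascending=False, na_position="last").reset_index(drop=True)
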