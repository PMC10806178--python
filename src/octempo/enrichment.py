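"""Gene-set overlap enrichment and rank-based GSEA.

Overlap enrichment is an exact hypergeometric tail test of the overlap
between a query gene set (e.g. a temporal cluster) and a collection set,
within an explicit universe.  GSEA uses the classic unweighted
Kolmogorov-Smirnov running sum (hit +1/|S|, miss -1/(N-|S|)) with a
set-permutation null and the plus-one p-value estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to an explicit universe."""

    sets: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe must be non-empty")
        self.sets = {name: set(s) & self.universe for name, s in self.sets.items()}


def hypergeom_overlap(query, target, universe, name_query: str = "query", name_set: str = "set") -> dict:
    """Exact hypergeometric enrichment of the query/target overlap.

    Over-enrichment p is P(X >= k) and under-enrichment p is P(X <= k) for
    X ~ Hypergeom(N=|universe|, K=|target|, n=|query|).  Genes outside the
    universe are dropped (logged).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query, target = set(query), set(target)
    outside = (query | target) - universe
    if outside:
        logger.info("dropping %d genes outside the universe", len(outside))
        query &= universe
        target &= universe
    N, K, n = len(universe), len(target), len(query)
    k = len(query & target)
    p_over = float(stats.hypergeom.sf(k - 1, N, K, n))
    p_under = float(stats.hypergeom.cdf(k, N, K, n))
    return {
        "query": name_query,
        "set": name_set,
        "overlap": k,
        "query_size": n,
        "set_size": K,
        "universe_size": N,
        "pvalue": p_over,
        "pvalue_under": p_under,
    }


def enrich_matrix(
    queries: dict[str, set],
    collection: GeneSetCollection,
    adjust: bool = False,
) -> pd.DataFrame:
    """One hypergeometric test per (query, collection set) pair.

    With ``adjust=True`` the over-enrichment p-values are BH-corrected
    across the whole query x set matrix.
    """
    rows = []
    for qname, q in queries.items():
        q_in = set(q) & collection.universe
        if not q_in:
            logger.warning("query %s has no genes in the universe; skipped", qname)
            continue
        for sname, s in collection.sets.items():
            rows.append(
                hypergeom_overlap(q_in, s, collection.universe, name_query=qname, name_set=sname)
            )
    out = pd.DataFrame(rows)
    if adjust and not out.empty:
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# GSEA


def _es_from_positions(pos: np.ndarray, n_total: int, n_set: int) -> np.ndarray:
    """Extreme (by |.|) of the unweighted KS running sum, batched.

    ``pos`` is (batch, n_set) of sorted 0-based hit ranks.  Between hits the
    running sum decreases linearly, so the extrema over the whole walk are
    attained immediately after a hit (local max candidates) or immediately
    before one (local min candidates), plus the endpoint value 0.
    """
    m = n_set
    miss = 1.0 / (n_total - m)
    hit = 1.0 / m
    j = np.arange(1, m + 1, dtype=float)
    after = j * hit - (pos + 1 - j) * miss  # value just after the j-th hit
    before = (j - 1) * hit - (pos - (j - 1)) * miss  # just before the j-th hit
    hi = after.max(axis=-1)
    lo = before.min(axis=-1)
    return np.where(hi >= -lo, hi, lo)


def gsea(ranked_items, item_set, n_perm: int = 999, seed: int = 0) -> dict:
    """Classic unweighted GSEA of ``item_set`` within a ranked list.

    ``ranked_items`` is the list ordered by decreasing score.  ES is the
    running-sum extremum; the p-value is the plus-one permutation estimate
    over random sets of the same size.
    """
    items = list(ranked_items)
    n = len(items)
    member = set(item_set)
    missing = member - set(items)
    if missing:
        raise ValueError(f"set members missing from the ranking: {sorted(missing)[:5]}")
    m = len(member)
    if m == 0 or m >= n:
        raise ValueError("set size must satisfy 0 < |set| < N")
    pos = np.sort([i for i, it in enumerate(items) if it in member])
    es_obs = float(_es_from_positions(pos[None, :], n, m)[0])

    rng = np.random.default_rng(seed)
    count = 0
    batch = max(1, min(n_perm, 4_000_000 // max(n, 1)))
    remaining = n_perm
    while remaining > 0:
        b = min(batch, remaining)
        keys = rng.random((b, n))
        perm_pos = np.sort(np.argpartition(keys, m - 1, axis=1)[:, :m], axis=1)
        es_perm = _es_from_positions(perm_pos, n, m)
        count += int(np.sum(np.abs(es_perm) >= abs(es_obs) - 1e-12))
        remaining -= b
    pvalue = (1 + count) / (n_perm + 1)
    return {"es": es_obs, "pvalue": pvalue, "n_perm": n_perm, "set_size": m, "n": n, "seed": seed}
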