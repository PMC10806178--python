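"""Negative-binomial GLM differential expression for the time course.

The stage mirrors the standard count-based DE workflow: median-of-ratios
size factors, per-gene method-of-moments dispersion shrunk toward a fitted
mean-dispersion trend, then log-link NB GLMs — a likelihood-ratio test of
timepoint indicators with donor blocking (design ~ donor + timepoint vs
~ donor), and a Wald test of a continuous donor phenotype slope at a single
timepoint.  All models are fitted by iteratively reweighted least squares
with the dispersion held fixed, batched across genes.

Numerical notes: no fold-change shrinkage is applied; genes with total
count below ``MIN_TOTAL_COUNT`` are not tested (status ``low_count``);
non-converged fits are reported as ``degenerate`` with NA p-values and are
excluded from the Benjamini-Hochberg denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix

MIN_TOTAL_COUNT = 10
DISPERSION_FLOOR = 1e-8
DEFAULT_DE_FDR = 1e-4
DEFAULT_PHENO_FDR = 1e-2
_IRLS_MAX_ITER = 100
_IRLS_TOL = 1e-8


# ---------------------------------------------------------------------------
# normalization


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For genes observed in every sample, each sample's factor is the median
    ratio of its count to the gene's geometric mean across samples.
    """
    K = cm.counts.to_numpy(dtype=float)
    all_positive = np.all(K > 0, axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "median-of-ratios is undefined (pseudo-reference fallback is disabled)"
        )
    logK = np.log(K[all_positive])
    log_geomean = logK.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logK - log_geomean, axis=0))
    return pd.Series(sf, index=cm.samples, name="size_factor")


def normalized_counts(cm: CountMatrix, sf: pd.Series) -> pd.DataFrame:
    return cm.counts / sf.loc[cm.samples].to_numpy()


# ---------------------------------------------------------------------------
# dispersion


def _dispersion_trend(mean: np.ndarray, alpha_hat: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu on genes with usable moment estimates."""
    use = (alpha_hat > 0) & (mean > 0) & np.isfinite(alpha_hat)
    if use.sum() < 10:
        fallback = float(np.median(alpha_hat[use])) if use.any() else DISPERSION_FLOOR
        return np.full_like(mean, max(fallback, DISPERSION_FLOOR))
    X = np.column_stack([np.ones(use.sum()), 1.0 / mean[use]])
    coef, *_ = np.linalg.lstsq(X, alpha_hat[use], rcond=None)
    coef = np.clip(coef, 0.0, None)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.maximum(mean, 1e-12)
    return np.maximum(trend, DISPERSION_FLOOR)


def estimate_dispersion(cm: CountMatrix, sf: pd.Series, grouping: str = "day") -> pd.DataFrame:
    """Per-gene NB dispersion by method of moments within design groups.

    Within each group with >= 2 replicates, alpha is estimated from the
    normalized-count mean and variance (correcting the Poisson part for the
    size-factor spread), pooled across groups by residual degrees of
    freedom, floored at zero, then shrunk 50/50 toward a fitted a0 + a1/mu
    mean-dispersion trend.  Returns a DataFrame with columns ``alpha``,
    ``base_mean`` and ``status``.
    """
    norm = normalized_counts(cm, sf).to_numpy()
    groups = cm.design[grouping]
    inv_sf = 1.0 / sf.loc[cm.samples].to_numpy()

    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    total_df = 0
    for g in pd.unique(groups):
        cols = np.flatnonzero((groups == g).to_numpy())
        if cols.size < 2:
            continue
        sub = norm[:, cols]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        xi = inv_sf[cols].mean()  # E[Var(K/s)] = xi*mu + alpha*mu^2
        w = cols.size - 1
        num += w * (var - xi * mu)
        den += w * mu**2
        total_df += w
    if total_df == 0:
        raise ValueError("need at least one design group with >= 2 replicates")

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.where(den > 0, num / den, np.nan)
    alpha_hat = np.where(np.isfinite(alpha_hat), np.maximum(alpha_hat, 0.0), np.nan)

    base_mean = norm.mean(axis=1)
    trend = _dispersion_trend(base_mean, np.nan_to_num(alpha_hat, nan=0.0))
    alpha = 0.5 * np.nan_to_num(alpha_hat, nan=0.0) + 0.5 * trend
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    total = cm.counts.to_numpy().sum(axis=1)
    status = np.where(total < MIN_TOTAL_COUNT, "low_count", "tested")
    return pd.DataFrame(
        {"alpha": alpha, "base_mean": base_mean, "status": status}, index=cm.genes
    )


# ---------------------------------------------------------------------------
# batched IRLS NB GLM


def _nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB deviance, valid down to the Poisson limit alpha -> 0."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-12)
    a = np.asarray(alpha, dtype=float)[:, None]
    a_safe = np.where(a > 0, a, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    term_nb = (y + 1.0 / a_safe) * (np.log1p(a_safe * mu) - np.log1p(a_safe * y))
    term_pois = mu - y
    term2 = np.where(a > 0, term_nb, term_pois)
    return 2.0 * (term1 + term2).sum(axis=1)


def fit_nb_glm(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = _IRLS_MAX_ITER,
    tol: float = _IRLS_TOL,
) -> dict:
    """Fit log-link NB GLMs for all genes at once by IRLS.

    Y is genes x samples, X samples x p (shared design), ``offset`` the log
    size factors, ``alpha`` the per-gene fixed dispersion.  Returns beta,
    fitted means, deviance, the per-gene Fisher information matrices
    (X' W X) and a convergence flag.
    """
    Y = np.asarray(Y, dtype=float)
    G, S = Y.shape
    p = X.shape[1]
    alpha = np.asarray(alpha, dtype=float)

    # initialise from a log-linear least-squares fit
    Z0 = np.log(np.maximum(Y, 0.5)) - offset[None, :]
    beta = np.linalg.lstsq(X, Z0.T, rcond=None)[0].T  # G x p

    eye = np.eye(p) * 1e-10
    dev = np.full(G, np.inf)
    active = np.ones(G, dtype=bool)
    converged = np.zeros(G, dtype=bool)
    mu = np.empty_like(Y)

    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        eta = beta[idx] @ X.T + offset[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu_i = np.exp(eta)
        W = mu_i / (1.0 + alpha[idx, None] * mu_i)
        z = eta - offset[None, :] + (Y[idx] - mu_i) / mu_i
        XtWX = np.einsum("sp,gs,sq->gpq", X, W, X) + eye[None, :, :]
        XtWz = np.einsum("sp,gs,gs->gp", X, W, z)
        beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        beta[idx] = beta_new
        mu[idx] = mu_i
        new_dev = _nb_deviance(Y[idx], mu_i, alpha[idx])
        delta = np.abs(new_dev - dev[idx]) / (np.abs(new_dev) + 0.1)
        done = delta < tol
        converged[idx[done]] = True
        dev[idx] = new_dev
        active[idx[done]] = False

    # final fitted means/deviance for genes that hit max_iter
    idx = np.flatnonzero(~converged)
    if idx.size:
        eta = np.clip(beta[idx] @ X.T + offset[None, :], -30.0, 30.0)
        mu[idx] = np.exp(eta)
        dev[idx] = _nb_deviance(Y[idx], mu[idx], alpha[idx])

    W = mu / (1.0 + alpha[:, None] * mu)
    fisher = np.einsum("sp,gs,sq->gpq", X, W, X)
    return {
        "beta": beta,
        "mu": mu,
        "deviance": dev,
        "fisher": fisher,
        "converged": converged,
    }


def _design_matrices(design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
    """Full (donor + timepoint) and reduced (donor-only) design matrices."""
    donors = pd.get_dummies(design["donor"]).to_numpy(dtype=float)
    days = pd.get_dummies(design["day"].astype(float), drop_first=True).to_numpy(dtype=float)
    full = np.hstack([donors, days])
    return full, donors, days.shape[1]


def lrt_timepoint(
    cm: CountMatrix,
    sf: pd.Series,
    dispersion: pd.DataFrame,
    de_fdr: float = DEFAULT_DE_FDR,
) -> pd.DataFrame:
    """Likelihood-ratio test for any timepoint effect, blocking on donor.

    Full model ~ donor + timepoint, reduced ~ donor; the statistic is the
    deviance difference, chi-square with (#timepoints - 1) df.  Returns a
    per-gene DEResult table with BH-adjusted p and the log2 fold change
    between the last and first day.
    """
    days = cm.design["day"].astype(float)
    if days.nunique() < 2 or cm.design["donor"].nunique() < 2:
        raise ValueError("need >= 2 timepoints and >= 2 donors")
    X_full, X_red, df = _design_matrices(cm.design)
    offset = np.log(sf.loc[cm.samples].to_numpy())
    alpha = dispersion.loc[cm.genes, "alpha"].to_numpy()
    status = dispersion.loc[cm.genes, "status"].astype(str).to_numpy().copy()

    testable = status == "tested"
    Y = cm.counts.to_numpy()[testable]
    fit_f = fit_nb_glm(Y, X_full, offset, alpha[testable])
    fit_r = fit_nb_glm(Y, X_red, offset, alpha[testable])

    stat = np.maximum(fit_r["deviance"] - fit_f["deviance"], 0.0)
    ok = fit_f["converged"] & fit_r["converged"] & np.isfinite(stat)
    pval = np.where(ok, stats.chi2.sf(stat, df), np.nan)

    out = pd.DataFrame(
        {
            "stat": np.nan,
            "df": df,
            "pvalue": np.nan,
            "fdr": np.nan,
            "dispersion": alpha,
            "status": status,
        },
        index=cm.genes,
    )
    tested_genes = cm.genes[testable]
    out.loc[tested_genes, "stat"] = stat
    out.loc[tested_genes, "pvalue"] = pval
    out.loc[tested_genes[~ok], "status"] = "degenerate"
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    day_vals = sorted(days.unique())
    fc = log2fc(cm, sf, day_vals[0], day_vals[-1])
    out[f"log2fc_d{day_vals[-1]:g}_vs_d{day_vals[0]:g}"] = fc
    out["de"] = out["fdr"] < de_fdr
    return out


def _dispersion_given_mu(Y: np.ndarray, mu: np.ndarray, n_params: int) -> np.ndarray:
    """Moment dispersion from model residuals: solves Var = mu + alpha mu^2
    around the fitted means, with a small-sample df correction, then shrinks
    50/50 toward the a0 + a1/mu trend (as in group-based estimation)."""
    n = Y.shape[1]
    correction = n / max(n - n_params, 1)
    num = correction * ((Y - mu) ** 2).sum(axis=1) - mu.sum(axis=1)
    den = (mu**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_hat = np.where(den > 0, np.maximum(num / den, 0.0), 0.0)
    base_mean = mu.mean(axis=1)
    trend = _dispersion_trend(base_mean, alpha_hat)
    return np.maximum(0.5 * alpha_hat + 0.5 * trend, DISPERSION_FLOOR)


def phenotype_association(
    cm: CountMatrix,
    sf: pd.Series,
    dispersion: pd.DataFrame | None,
    phenotype: pd.Series,
    pheno_fdr: float = DEFAULT_PHENO_FDR,
) -> pd.DataFrame:
    """Wald test of a continuous per-donor phenotype slope at one timepoint.

    ``cm`` must hold one sample per donor (a single timepoint); the model is
    intercept + phenotype with fixed dispersion.  Pass ``dispersion=None``
    to estimate the dispersion from the phenotype-model residuals — group
    moments would count the phenotype signal itself as noise.
    """
    donors = cm.design["donor"]
    if donors.duplicated().any():
        raise ValueError("expected one sample per donor (a single timepoint)")
    missing = set(donors) - set(phenotype.index)
    if missing:
        raise ValueError(f"phenotype missing for donors: {sorted(missing)}")
    ph = phenotype.loc[donors].to_numpy(dtype=float)
    if np.unique(ph).size < 2:
        raise ValueError("phenotype is constant; association is undefined")

    X = np.column_stack([np.ones_like(ph), ph])
    offset = np.log(sf.loc[cm.samples].to_numpy())
    total = cm.counts.to_numpy().sum(axis=1)
    if dispersion is None:
        status = np.where(total < MIN_TOTAL_COUNT, "low_count", "tested").astype(object)
        testable = status == "tested"
        Y = cm.counts.to_numpy()[testable]
        pilot = fit_nb_glm(Y, X, offset, np.full(int(testable.sum()), 0.1))
        alpha = np.full(cm.n_genes, DISPERSION_FLOOR)
        alpha[testable] = _dispersion_given_mu(Y, pilot["mu"], X.shape[1])
    else:
        alpha = dispersion.loc[cm.genes, "alpha"].to_numpy()
        status = dispersion.loc[cm.genes, "status"].astype(str).to_numpy().copy()
        testable = status == "tested"

    fit = fit_nb_glm(cm.counts.to_numpy()[testable], X, offset, alpha[testable])
    cov = np.linalg.inv(fit["fisher"])
    se = np.sqrt(np.maximum(cov[:, 1, 1], 1e-300))
    z = fit["beta"][:, 1] / se
    ok = fit["converged"] & np.isfinite(z)
    pval = np.where(ok, 2.0 * stats.norm.sf(np.abs(z)), np.nan)

    out = pd.DataFrame(
        {
            "stat": np.nan,
            "df": 1,
            "pvalue": np.nan,
            "fdr": np.nan,
            "slope_log2": np.nan,
            "dispersion": alpha,
            "status": status,
        },
        index=cm.genes,
    )
    tested_genes = cm.genes[testable]
    out.loc[tested_genes, "stat"] = z
    out.loc[tested_genes, "pvalue"] = pval
    out.loc[tested_genes, "slope_log2"] = fit["beta"][:, 1] / np.log(2.0)
    out.loc[tested_genes[~ok], "status"] = "degenerate"
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    out["associated"] = out["fdr"] < pheno_fdr
    return out


# ---------------------------------------------------------------------------
# fold changes and multiple testing


def log2fc(cm: CountMatrix, sf: pd.Series, day_a: float, day_b: float, pseudocount: float = 1.0) -> pd.Series:
    """log2((mean normalized count at day_b + c) / (mean at day_a + c))."""
    days = cm.design["day"].astype(float)
    norm = normalized_counts(cm, sf)
    res = {}
    for d in (day_a, day_b):
        cols = cm.samples[(days == float(d)).to_numpy()]
        if len(cols) == 0:
            raise ValueError(f"day {d} not present in the design")
        res[d] = norm[cols].mean(axis=1)
    return np.log2((res[day_b] + pseudocount) / (res[day_a] + pseudocount)).rename(
        f"log2fc_d{day_b:g}_vs_d{day_a:g}"
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up, order-preserving, NA-aware.

    NA entries are excluded from the number of tests m and returned as NA.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = np.isfinite(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    pv = p[valid]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[valid] = res
    return out
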