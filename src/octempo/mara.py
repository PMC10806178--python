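"""Motif activity response analysis (MARA-style) on promoter motif counts.

Row-centred log expression E (genes x samples) is modelled as
E_gs = sum_m N_gm A_ms + noise, where N holds promoter motif site counts
and A the latent per-sample motif activities.  A is the ridge solution
(closed form per sample); the penalty is either given or chosen by k-fold
cross-validation over genes.  Per-entry standard errors come from the
ridge covariance with per-sample residual variance; motifs whose activity
varies across samples beyond its error are called differential; and a
(motif, gene) pair is scored by a signal-to-noise ratio
N_gm * sd_s(A_m.) / sigma_g, with edges above a strict threshold of 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ACTIVITY_P = 1e-3
DEFAULT_SCORE_THRESHOLD = 2.0
SIGMA_FLOOR = 1e-6
_LAMBDA_GRID = np.logspace(-4, 4, 17)


@dataclass
class ActivityMatrix:
    """Fitted motif activities with uncertainties and fit residuals."""

    activity: pd.DataFrame  # motifs x samples
    stderr: pd.DataFrame  # motifs x samples
    ridge_lambda: float
    residual_sd_gene: pd.Series  # per-gene residual sd across samples
    df_residual: float


def _ridge_solve(N: np.ndarray, E: np.ndarray, lam: float) -> np.ndarray:
    """A = (N'N + lam I)^-1 N' E, motifs x samples."""
    M = N.shape[1]
    G = N.T @ N + lam * np.eye(M)
    return np.linalg.solve(G, N.T @ E)


def _cv_error(N: np.ndarray, E: np.ndarray, lam: float, folds: int, rng: np.random.Generator) -> float:
    G = N.shape[0]
    perm = rng.permutation(G)
    err = 0.0
    for f in range(folds):
        test = perm[f::folds]
        train = np.setdiff1d(perm, test)
        A = _ridge_solve(N[train], E[train], lam)
        resid = E[test] - N[test] @ A
        err += float((resid**2).sum())
    return err


def fit_motif_activity(
    E: pd.DataFrame,
    N: pd.DataFrame,
    ridge_lambda="auto",
    cv_folds: int = 5,
    seed: int = 0,
) -> ActivityMatrix:
    """Fit per-sample motif activities by ridge regression.

    ``E`` is log-scale, row-centred expression (genes x samples); ``N`` the
    motif-count matrix (genes x motifs).  Genes are intersected between the
    two.  ``ridge_lambda='auto'`` picks the penalty minimising k-fold
    cross-validated prediction error on held-out genes.
    """
    shared = E.index.intersection(N.index)
    if len(shared) < 2:
        raise ValueError("need at least 2 genes shared between expression and motif counts")
    Em = E.loc[shared].to_numpy(dtype=float)
    Nm = N.loc[shared].to_numpy(dtype=float)
    if np.any(Nm < 0):
        raise ValueError("motif counts must be non-negative")
    if E.shape[1] < 2:
        raise ValueError("need at least 2 samples")

    if ridge_lambda == "auto":
        rng = np.random.default_rng(seed)
        errors = [_cv_error(Nm, Em, lam, cv_folds, rng) for lam in _LAMBDA_GRID]
        lam = float(_LAMBDA_GRID[int(np.argmin(errors))])
    else:
        lam = float(ridge_lambda)
        if lam < 0:
            raise ValueError("ridge penalty must be >= 0")

    M = Nm.shape[1]
    Gm = Nm.T @ Nm + lam * np.eye(M)
    C = np.linalg.inv(Gm)
    A = C @ Nm.T @ Em  # motifs x samples
    fitted = Nm @ A
    resid = Em - fitted
    trace_hat = float(np.trace(Nm @ C @ Nm.T))
    df_resid = max(Em.shape[0] - trace_hat, 1.0)
    sigma2_sample = (resid**2).sum(axis=0) / df_resid
    var_scale = np.diag(C @ (Nm.T @ Nm) @ C)  # per-motif sandwich diagonal
    stderr = np.sqrt(np.maximum(var_scale[:, None] * sigma2_sample[None, :], 0.0))

    resid_sd_gene = np.sqrt((resid**2).mean(axis=1))
    return ActivityMatrix(
        activity=pd.DataFrame(A, index=N.columns, columns=E.columns),
        stderr=pd.DataFrame(stderr, index=N.columns, columns=E.columns),
        ridge_lambda=lam,
        residual_sd_gene=pd.Series(resid_sd_gene, index=shared, name="residual_sd"),
        df_residual=df_resid,
    )


def activity_significance(act: ActivityMatrix, p_threshold: float = DEFAULT_ACTIVITY_P) -> pd.DataFrame:
    """Chi-square test of non-constant activity per motif.

    Statistic sum_s (A_ms / se_ms)^2 against chi-square with
    (#samples - 1) df (activities of row-centred expression are centred).
    Motifs with zero standard error are flagged degenerate.
    """
    A = act.activity.to_numpy()
    se = act.stderr.to_numpy()
    n_samples = A.shape[1]
    degenerate = np.any(se <= 0, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.nansum((A / se) ** 2, axis=1)
    df = n_samples - 1
    p = np.where(degenerate, np.nan, stats.chi2.sf(stat, df))
    return pd.DataFrame(
        {
            "stat": np.where(degenerate, np.nan, stat),
            "df": df,
            "pvalue": p,
            "differential": (p < p_threshold) & ~degenerate,
            "status": np.where(degenerate, "degenerate", "tested"),
        },
        index=act.activity.index,
    )


def score_targets(N: pd.DataFrame, act: ActivityMatrix, threshold: float = DEFAULT_SCORE_THRESHOLD) -> pd.DataFrame:
    """Signal-to-noise target scores and edge calls.

    score(g, m) = N_gm * sd_s(A_m.) / sigma_g, where sigma_g is the gene's
    residual sd under the fitted model (floored); an edge requires the score
    strictly above ``threshold``.  Returns a long DataFrame over pairs with
    N_gm > 0 (all other scores are zero by construction).
    """
    genes = act.residual_sd_gene.index
    Nm = N.loc[genes].to_numpy(dtype=float)
    sd_act = act.activity.to_numpy().std(axis=1, ddof=1)
    sigma = np.maximum(act.residual_sd_gene.to_numpy(), SIGMA_FLOOR)
    g_idx, m_idx = np.nonzero(Nm)
    score = Nm[g_idx, m_idx] * sd_act[m_idx] / sigma[g_idx]
    return pd.DataFrame(
        {
            "source": act.activity.index.to_numpy()[m_idx],
            "target": genes.to_numpy()[g_idx],
            "score": score,
            "edge": score > threshold,
        }
    )
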