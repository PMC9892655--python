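"""Per-transcript quasi-binomial GLM on within-gene usage.

For each transcript t of gene g we model the usage U_gti = Y_gti / Y_g.i
with mean logit(pi_gti) = X_i' beta and variance
pi(1-pi)/Y_g.i * phi_gt: a binomial-style variance with the gene total as
effective trial count and a transcript-specific overdispersion phi_gt.
Only the first two moments are specified, so estimation proceeds by
iteratively reweighted least squares (IRLS) with prior weights equal to
the gene totals, and phi_gt is estimated from Pearson residuals.

Observations where the gene total is zero carry no information about
usage (the variance above is undefined); they receive zero weight and are
excluded from the effective sample size and residual degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import DesignSpec, TranscriptQuantification, transcript_gene_totals, usage

logger = logging.getLogger(__name__)

MAX_ITER = 50
DEVIANCE_RTOL = 1e-8
# |eta| beyond this means fitted usages are numerically 0/1: quasi-complete
# separation, no finite MLE (expit(15) is within 3e-7 of 1).
ETA_SEPARATION = 15.0
ETA_DIVERGED = 100.0


@dataclass
class TranscriptFit:
    """IRLS output for one transcript.

    ``cov_unscaled`` is (X'WX)^{-1} at convergence; multiplying by the
    (moderated) dispersion gives the coefficient covariance.  ``fitted_pi``
    has one entry per sample, NaN where the observation had zero weight.
    """

    transcript_id: str
    gene_id: str
    beta: np.ndarray | None
    cov_unscaled: np.ndarray | None
    dispersion: float
    df_residual: int
    n_eff: int
    converged: bool
    fitted_pi: np.ndarray | None


def quasi_binomial_deviance(u: np.ndarray, pi: np.ndarray, w: np.ndarray) -> float:
    """Binomial quasi-deviance with prior weights w (0*log0 := 0)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(u > 0, u * np.log(u / pi), 0.0)
        t2 = np.where(u < 1, (1 - u) * np.log((1 - u) / (1 - pi)), 0.0)
    return float(2.0 * np.sum(w * (t1 + t2)))


def fit_qb_glm(
    u: np.ndarray,
    w: np.ndarray,
    X: np.ndarray,
    max_iter: int = MAX_ITER,
    tol: float = DEVIANCE_RTOL,
) -> TranscriptFit:
    """Fit the quasi-binomial GLM by IRLS.

    Parameters
    ----------
    u
        Observed usages in [0, 1]; entries at zero-weight observations may
        be NaN.
    w
        Prior weights (gene totals), >= 0; zero-weight observations are
        dropped from the fit.
    X
        n x p design matrix.

    Returns a :class:`TranscriptFit` (ids left empty; :func:`fit_all`
    fills them).  Separation or non-convergence is flagged via
    ``converged=False`` with coefficients retained but downstream
    statistics expected to treat the fit as unusable.
    """
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    mask = (w > 0) & np.isfinite(u)
    n_eff = int(mask.sum())
    if n_eff == 0:
        raise ValueError("all observations have zero weight")
    uf, wf, Xf = u[mask], w[mask], X[mask]
    df_residual = max(n_eff - p, 0)

    def _failed() -> TranscriptFit:
        return TranscriptFit("", "", None, None, np.nan, df_residual, n_eff, False, None)

    if n_eff < p or np.linalg.matrix_rank(Xf) < p:
        return _failed()

    # start at empirical usages shrunk toward 1/2 (avoids logit(0) / logit(1))
    pi = (uf + 0.5 / n_eff) / (1.0 + 1.0 / n_eff)
    eta = logit(pi)
    beta = np.zeros(p)
    dev = np.inf
    converged = False
    for _ in range(max_iter):
        mu_var = pi * (1.0 - pi)
        W = wf * mu_var
        z = eta + (uf - pi) / mu_var
        XtW = Xf.T * W
        try:
            beta = np.linalg.solve(XtW @ Xf, XtW @ z)
        except np.linalg.LinAlgError:
            return _failed()
        eta = Xf @ beta
        if np.abs(eta).max() > ETA_DIVERGED:
            return _failed()
        pi = expit(eta)
        new_dev = quasi_binomial_deviance(uf, pi, wf)
        if abs(new_dev - dev) <= tol * (abs(new_dev) + 0.1):
            converged = True
            dev = new_dev
            break
        dev = new_dev

    if np.abs(eta).max() > ETA_SEPARATION:
        return _failed()
    W = wf * pi * (1.0 - pi)
    info = (Xf.T * W) @ Xf
    try:
        cov_unscaled = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return _failed()
    fitted_full = np.full(n, np.nan)
    fitted_full[mask] = pi
    return TranscriptFit("", "", beta, cov_unscaled, np.nan, df_residual, n_eff, converged, fitted_full)


def pearson_dispersion(u: np.ndarray, w: np.ndarray, fitted_pi: np.ndarray, df_residual: int) -> float:
    """Pearson estimate of the overdispersion phi.

    phi_hat = sum_i w_i (u_i - pi_i)^2 / (pi_i (1 - pi_i)) / df_residual,
    over observations with positive weight.  Undefined (NaN) at zero
    residual degrees of freedom.
    """
    if df_residual <= 0:
        return np.nan
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    pi = np.asarray(fitted_pi, dtype=float)
    mask = (w > 0) & np.isfinite(u) & np.isfinite(pi)
    resid2 = (u[mask] - pi[mask]) ** 2
    denom = pi[mask] * (1.0 - pi[mask])
    return float(np.sum(w[mask] * resid2 / denom) / df_residual)


def fit_all(q: TranscriptQuantification, design: DesignSpec) -> list[TranscriptFit]:
    """Fit every transcript; per-transcript failures are flagged, never fatal."""
    if design.n != q.n_samples:
        raise ValueError("design matrix rows do not match number of samples")
    U = usage(q).to_numpy()
    W = transcript_gene_totals(q).to_numpy()
    fits: list[TranscriptFit] = []
    genes = q.gene_of.to_numpy()
    n_failed = 0
    for i, tx in enumerate(q.values.index):
        try:
            fit = fit_qb_glm(U[i], W[i], design.X)
        except ValueError:
            fit = TranscriptFit("", "", None, None, np.nan, 0, 0, False, None)
        fit.transcript_id = str(tx)
        fit.gene_id = str(genes[i])
        if fit.converged:
            fit.dispersion = pearson_dispersion(U[i], W[i], fit.fitted_pi, fit.df_residual)
        else:
            n_failed += 1
        fits.append(fit)
    if n_failed:
        logger.info("%d / %d transcript fits flagged (separation or non-convergence)", n_failed, len(fits))
    return fits
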