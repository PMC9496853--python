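"""Parametric empirical-Bayes batch correction (ComBat model).

Removes dataset/batch effects from a stacked expression matrix before
network construction.  Per gene the model is

    y_gij = alpha_g + X beta_g + gamma_gi + delta_gi * eps_gij

with batch i, sample j, optional biological covariates X (here the disease
indicator, protected by default so correction does not erase condition
signal).  Per-(gene, batch) location gamma and scale delta^2 are shrunk
toward batch-level priors — normal for gamma, inverse-gamma (method of
moments) for delta^2 — and the data are back-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DISEASE, ValidationError


@dataclass
class BatchModel:
    """Fitted per-gene batch parameters and their empirical-Bayes priors."""

    batches: list[str]
    gamma_hat: pd.DataFrame      # gene x batch, raw location estimates
    delta2_hat: pd.DataFrame     # gene x batch, raw scale estimates
    gamma_star: pd.DataFrame     # shrunken locations
    delta2_star: pd.DataFrame    # shrunken scales (strictly positive)
    gamma_bar: pd.Series         # prior mean of gamma per batch
    tau2: pd.Series              # prior variance of gamma per batch
    a_prior: pd.Series           # inverse-gamma shape per batch
    b_prior: pd.Series           # inverse-gamma scale per batch


def _aprior(delta2: np.ndarray) -> float:
    m, s2 = delta2.mean(), delta2.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(delta2: np.ndarray) -> float:
    m, s2 = delta2.mean(), delta2.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_solve(z, gamma_hat, delta2_hat, gamma_bar, tau2, a, b, tol=1e-4):
    """Iterate the coupled posterior-mode updates for gamma*, delta2*."""
    n = z.shape[1]
    g_old = gamma_hat.copy()
    d_old = delta2_hat.copy()
    change = 1.0
    while change > tol:
        g_new = (tau2 * n * gamma_hat + d_old * gamma_bar) / (tau2 * n + d_old)
        sum2 = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max() if np.abs(g_old).max() > 0 else 0.0,
            np.abs(d_new - d_old).max() / d_old.max(),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_adjust(
    values: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.Series | None = None,
) -> tuple[pd.DataFrame, BatchModel]:
    """Adjust a stacked genes x samples matrix for batch effects.

    Parameters
    ----------
    values
        Stacked expression matrix (genes x samples).
    batch
        Per-sample batch/dataset label, indexed by sample id.
    covariates
        Optional per-sample condition label ("disease"/"control") protected
        during standardization.

    Returns the adjusted matrix (same shape and ordering) and the fitted
    :class:`BatchModel`.
    """
    batch = pd.Series(batch).loc[values.columns]
    batches = list(dict.fromkeys(batch))
    counts = batch.value_counts()
    small = [b for b in batches if counts[b] < 2]
    if small:
        raise ValidationError(f"batches with < 2 samples: {small}")
    y = values.to_numpy(dtype=float)
    n_genes, n_samples = y.shape
    if len(batches) == 1:
        model = BatchModel(
            batches=batches,
            gamma_hat=pd.DataFrame(0.0, index=values.index, columns=batches),
            delta2_hat=pd.DataFrame(1.0, index=values.index, columns=batches),
            gamma_star=pd.DataFrame(0.0, index=values.index, columns=batches),
            delta2_star=pd.DataFrame(1.0, index=values.index, columns=batches),
            gamma_bar=pd.Series(0.0, index=batches),
            tau2=pd.Series(1.0, index=batches),
            a_prior=pd.Series(np.nan, index=batches),
            b_prior=pd.Series(np.nan, index=batches),
        )
        return values.copy(), model

    # Design: one indicator column per batch, plus optional covariates.
    batch_design = np.column_stack(
        [(batch == b).to_numpy(float) for b in batches]
    )
    design = batch_design
    if covariates is not None:
        cov = pd.Series(covariates).loc[values.columns]
        ind = (cov == DISEASE).to_numpy(float)
        if 0 < ind.sum() < n_samples:
            design = np.column_stack([batch_design, ind])

    beta_hat, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    n_per = np.array([counts[b] for b in batches], dtype=float)
    grand_mean = (n_per / n_samples) @ beta_hat[: len(batches)]
    resid = y.T - design @ beta_hat
    var_pooled = (resid**2).mean(axis=0)
    zero_var = values.index[var_pooled <= 0]
    if len(zero_var):
        raise ValidationError(
            f"zero-variance genes cannot be adjusted: {list(zero_var)[:10]}"
        )

    stand_mean = np.tile(grand_mean, (n_samples, 1))
    if design.shape[1] > len(batches):
        stand_mean = stand_mean + design[:, len(batches):] @ beta_hat[len(batches):]
    z = ((y.T - stand_mean) / np.sqrt(var_pooled)).T  # genes x samples

    gamma_hat = np.empty((n_genes, len(batches)))
    delta2_hat = np.empty((n_genes, len(batches)))
    gamma_star = np.empty((n_genes, len(batches)))
    delta2_star = np.empty((n_genes, len(batches)))
    gamma_bar = np.empty(len(batches))
    tau2 = np.empty(len(batches))
    a_prior = np.empty(len(batches))
    b_prior = np.empty(len(batches))
    for bi, b in enumerate(batches):
        cols = (batch == b).to_numpy()
        zb = z[:, cols]
        gamma_hat[:, bi] = zb.mean(axis=1)
        delta2_hat[:, bi] = zb.var(axis=1, ddof=1)
        gamma_bar[bi] = gamma_hat[:, bi].mean()
        tau2[bi] = gamma_hat[:, bi].var(ddof=1)
        a_prior[bi] = _aprior(delta2_hat[:, bi])
        b_prior[bi] = _bprior(delta2_hat[:, bi])
        g, d = _it_solve(
            zb,
            gamma_hat[:, bi],
            np.maximum(delta2_hat[:, bi], 1e-12),
            gamma_bar[bi],
            tau2[bi],
            a_prior[bi],
            b_prior[bi],
        )
        gamma_star[:, bi] = g
        delta2_star[:, bi] = d
        z[:, cols] = (zb - g[:, None]) / np.sqrt(d)[:, None]

    adjusted = (z * np.sqrt(var_pooled)[:, None]).T + stand_mean
    out = pd.DataFrame(adjusted.T, index=values.index, columns=values.columns)
    gidx, bidx = values.index, batches
    model = BatchModel(
        batches=batches,
        gamma_hat=pd.DataFrame(gamma_hat, index=gidx, columns=bidx),
        delta2_hat=pd.DataFrame(delta2_hat, index=gidx, columns=bidx),
        gamma_star=pd.DataFrame(gamma_star, index=gidx, columns=bidx),
        delta2_star=pd.DataFrame(delta2_star, index=gidx, columns=bidx),
        gamma_bar=pd.Series(gamma_bar, index=bidx),
        tau2=pd.Series(tau2, index=bidx),
        a_prior=pd.Series(a_prior, index=bidx),
        b_prior=pd.Series(b_prior, index=bidx),
    )
    return out, model
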