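"""Gene-wise moderated differential expression between two conditions.

Per gene a two-group linear model gives the log2 fold change
(disease - control) and residual variance s_g^2 on d_g degrees of freedom.
An empirical-Bayes step borrows strength across genes: the log s_g^2
ensemble is fitted by method of moments to a scaled-F model, yielding prior
degrees of freedom d0 and prior variance s0^2, and each variance is replaced
by the posterior mean (d0*s0^2 + d_g*s_g^2) / (d0 + d_g).  Moderated t
statistics are referred to a t distribution on d0 + d_g degrees of freedom.
When the moment fit finds no excess variability in the s_g^2 ensemble, d0 is
taken as +inf (fully pooled variance); a single-gene input has no ensemble
to moderate and falls back to the ordinary t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import CONTROL, DISEASE, ExpressionDataset, ValidationError


@dataclass
class DEResult:
    """Per-gene moderated DE statistics.

    ``is_deg`` flags FDR-adjusted p < 0.05; ``is_possible_deg`` flags
    uncorrected p < 0.05.
    """

    table: pd.DataFrame  # columns: logFC, t, p, p_adj, is_deg, is_possible_deg
    d0: float
    s0_sq: float

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return y


def fit_f_dist(s_sq: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) to a scaled-F variance ensemble.

    Matches the mean and variance of log s_g^2 using digamma/trigamma
    identities.  Returns ``d0 = inf`` when the observed spread does not
    exceed what the residual degrees of freedom alone explain.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    ok = s_sq > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s_sq[ok])) if ok.any() else 1.0
    z = np.log(s_sq[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    excess = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = np.exp(
        e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    )
    return float(d0), float(s0_sq)


def moderated_de(ds: ExpressionDataset) -> DEResult:
    """Moderated two-group DE over all genes of a dataset."""
    dis = ds.condition == DISEASE
    con = ds.condition == CONTROL
    n1, n2 = int(dis.sum()), int(con.sum())
    if n1 < 2 or n2 < 2:
        raise ValidationError("need >= 2 samples in each condition")
    y = ds.values.to_numpy(dtype=float)
    yd, yc = y[:, dis.to_numpy()], y[:, con.to_numpy()]
    fc = yd.mean(axis=1) - yc.mean(axis=1)
    df = n1 + n2 - 2
    rss = ((yd - yd.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (yc - yc.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s_sq = rss / df
    scale = np.sqrt(1.0 / n1 + 1.0 / n2)

    if len(fc) < 2:
        # no ensemble: ordinary t-test
        d0, s0_sq = 0.0, 0.0
        s_tilde = s_sq
        df_total = float(df)
    else:
        d0, s0_sq = fit_f_dist(s_sq, df)
        if np.isinf(d0):
            s_tilde = np.full_like(s_sq, s0_sq)
            df_total = np.inf
        else:
            s_tilde = (d0 * s0_sq + df * s_sq) / (d0 + df)
            df_total = d0 + df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / (np.sqrt(s_tilde) * scale)
    t = np.where(np.isfinite(t), t, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    p_adj = bh_adjust(p)
    table = pd.DataFrame(
        {
            "logFC": fc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "is_deg": p_adj < 0.05,
            "is_possible_deg": p < 0.05,
        },
        index=ds.values.index,
    )
    return DEResult(table=table, d0=float(d0), s0_sq=float(s0_sq))
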