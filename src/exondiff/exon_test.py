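"""Built-in two-group moderated t-test on log-CPM values.

This is the testing engine applied per exon (exon-based strategy) or per
gene on summed counts (gene-based strategy).  It is an empirical-Bayes
moderated t: per-feature pooled variances are shrunk toward a scaled
inverse-chi-square prior fitted to all features by the log-scale
method-of-moments, and the t reference distribution gains the prior
degrees of freedom.  The strategy itself is test-agnostic — results from
any external per-exon test can be substituted through the plugin table
read by :func:`exondiff.count_io.read_external_exon_results`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .count_io import ExonCountTable
from .preprocess import NormalizationState, log_cpm, tmm_factors

__all__ = [
    "ShrinkagePrior",
    "fit_two_group",
    "estimate_prior",
    "moderated_p",
    "test_features",
]


@dataclass
class ShrinkagePrior:
    """Scaled inverse-chi-square variance prior (d0 may be math.inf)."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("prior degrees of freedom must be > 0")
        if not (self.s0_sq > 0):
            raise ValueError("prior variance must be > 0")


def fit_two_group(
    logcpm: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Per-feature effect and pooled residual variance for a two-group design.

    Returns a frame with columns ``x`` (mean of group2 minus mean of group1,
    groups taken in sorted label order), ``s2`` (pooled within-group
    variance), ``df_resid`` (n1 + n2 - 2) and ``avg_expr``.
    """
    groups = groups.loc[logcpm.columns]
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    g1 = logcpm.columns[groups == labels[0]]
    g2 = logcpm.columns[groups == labels[1]]
    n1, n2 = len(g1), len(g2)
    df_resid = n1 + n2 - 2
    if df_resid < 1:
        raise ValueError("insufficient replication: residual df is 0")
    a1 = logcpm[g1].to_numpy()
    a2 = logcpm[g2].to_numpy()
    m1 = a1.mean(axis=1)
    m2 = a2.mean(axis=1)
    ss = ((a1 - m1[:, None]) ** 2).sum(axis=1) + ((a2 - m2[:, None]) ** 2).sum(axis=1)
    return pd.DataFrame(
        {
            "x": m2 - m1,
            "s2": ss / df_resid,
            "df_resid": df_resid,
            "avg_expr": logcpm.mean(axis=1).to_numpy(),
            "n1": n1,
            "n2": n2,
        },
        index=logcpm.index,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def estimate_prior(s2: np.ndarray | pd.Series, df_resid: int) -> ShrinkagePrior:
    """Fit the variance prior by method of moments on log(s2).

    Under the model ``s2 ~ s0_sq * F(df_resid, d0)``, the mean and variance
    of ``log(s2)`` identify (d0, s0_sq) through digamma/trigamma relations.
    When the observed spread of log-variances does not exceed the pure
    chi-square sampling spread, d0 is infinite (complete shrinkage).  A
    fully degenerate input (all s2 equal) carries no sampling noise to
    de-bias, so the common value itself is returned as s0_sq.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two features with positive variance")
    z = np.log(s2[ok])
    if np.ptp(z) == 0.0:
        return ShrinkagePrior(d0=math.inf, s0_sq=float(s2[ok][0]))
    half = df_resid / 2.0
    e = z - float(special.digamma(half)) + math.log(half)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, half))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = math.exp(
            emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
        return ShrinkagePrior(d0=d0, s0_sq=s0)
    return ShrinkagePrior(d0=math.inf, s0_sq=math.exp(emean))


def moderated_p(
    x: np.ndarray,
    s2: np.ndarray,
    df_resid: int,
    prior: ShrinkagePrior,
    n1: int,
    n2: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t statistics and two-sided p-values.

    Posterior variance ``(d0*s0_sq + df*s2) / (d0 + df)``; the reference is
    a t with ``d0 + df`` degrees of freedom, collapsing to the normal when
    d0 is infinite.
    """
    x = np.asarray(x, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
    else:
        s2_post = (prior.d0 * prior.s0_sq + df_resid * s2) / (prior.d0 + df_resid)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, x / np.where(se > 0, se, 1.0), np.where(x == 0, 0.0, np.inf * np.sign(x)))
    if math.isinf(prior.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=prior.d0 + df_resid)
    return t, np.minimum(p, 1.0)


def test_features(
    table: ExonCountTable,
    norm: NormalizationState | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Full per-feature test: log-CPM, two-group fit, shrinkage, p-values.

    Works identically for exon tables and for gene tables (where each
    "exon" row is a gene's summed counts and gene_of is the identity map).
    Returns a frame with exon_id (index), gene_id, x, p, t, s2, df_resid,
    avg_expr.
    """
    if table.groups is None:
        raise ValueError("table has no sample groups")
    table.two_group_labels()
    if norm is None:
        norm = tmm_factors(table.counts)
    lc = log_cpm(table.counts, norm, prior=prior_count)
    fit = fit_two_group(lc, table.groups)
    prior = estimate_prior(fit["s2"].to_numpy(), int(fit["df_resid"].iloc[0]))
    t, p = moderated_p(
        fit["x"].to_numpy(),
        fit["s2"].to_numpy(),
        int(fit["df_resid"].iloc[0]),
        prior,
        int(fit["n1"].iloc[0]),
        int(fit["n2"].iloc[0]),
    )
    out = pd.DataFrame(
        {
            "gene_id": table.gene_of.to_numpy(),
            "x": fit["x"].to_numpy(),
            "p": p,
            "t": t,
            "s2": fit["s2"].to_numpy(),
            "df_resid": fit["df_resid"].to_numpy(),
            "avg_expr": fit["avg_expr"].to_numpy(),
        },
        index=lc.index,
    )
    out.index.name = "exon_id"
    return out
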