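"""Filtering, gene-level summation and between-sample normalization.

The expression filter keeps an exon when its mean count over all samples
exceeds ``min_avg`` and keeps a gene when at least ``min_exons`` of its
exons survive; genes that had only a single exon to begin with are dropped
outright, because for them testing exons and testing the gene coincide.

Normalization follows the trimmed-mean-of-M-values (TMM) scheme: scaling
factors from a doubly trimmed, precision-weighted mean of per-feature
log-ratios against a reference sample, rescaled to geometric mean one, and
log2 counts-per-million computed on the resulting effective library sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .count_io import ExonCountTable

logger = logging.getLogger("exondiff")

__all__ = [
    "NormalizationState",
    "FilterReport",
    "filter_exons",
    "sum_gene_counts",
    "tmm_factors",
    "log_cpm",
]


@dataclass
class NormalizationState:
    """Per-sample library sizes and TMM scaling factors (geometric mean 1)."""

    library_size: pd.Series
    tmm_factor: pd.Series

    @property
    def effective_library_size(self) -> pd.Series:
        return self.library_size * self.tmm_factor


@dataclass
class FilterReport:
    n_exons_in: int
    n_exons_removed_low: int
    n_single_exon_genes_removed: int
    n_genes_removed: int
    n_exons_out: int
    n_genes_out: int


def filter_exons(
    table: ExonCountTable,
    min_avg: float = 1.0,
    min_exons: int = 2,
    report: bool = True,
) -> ExonCountTable:
    """Apply the low-expression exon filter and drop under-covered genes.

    An exon is kept when its mean count across *all* samples is strictly
    greater than ``min_avg``; a gene is kept when at least ``min_exons`` of
    its exons survive.  Single-exon genes are removed regardless of their
    expression level.
    """
    exons_before = table.gene_of.groupby(table.gene_of, sort=False).size()
    single_exon_genes = set(exons_before.index[exons_before < 2])

    mean_count = table.counts.mean(axis=1)
    keep_exon = mean_count > min_avg
    keep_exon &= ~table.gene_of.isin(single_exon_genes)

    surviving = table.gene_of[keep_exon]
    per_gene = surviving.groupby(surviving, sort=False).size()
    ok_genes = set(per_gene.index[per_gene >= min_exons])
    keep_exon &= table.gene_of.isin(ok_genes)

    kept = table.counts.index[keep_exon]
    if report:
        rep = FilterReport(
            n_exons_in=table.n_exons,
            n_exons_removed_low=int((~(mean_count > min_avg)).sum()),
            n_single_exon_genes_removed=len(single_exon_genes),
            n_genes_removed=len(set(table.gene_of)) - len(ok_genes),
            n_exons_out=len(kept),
            n_genes_out=len(ok_genes),
        )
        logger.info("exon filter: %s", rep)
    if len(kept) == 0:
        logger.warning("exon filter removed every exon; result is empty")
    return table.subset_exons(list(kept))


def sum_gene_counts(table: ExonCountTable) -> pd.DataFrame:
    """Gene-level counts: per-sample sum over each gene's exons."""
    return table.counts.groupby(table.gene_of, sort=True).sum()


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    """Raw TMM factor of one sample against the reference (log2 scale -> 2**)."""
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok].astype(float), ref[ok].astype(float)
    if obs.size == 0:
        return 1.0
    m = np.log2((obs / lib_obs) / (ref / lib_ref))
    a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
    # asymptotic (delta-method) variance of M, used as precision weight
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank(method="average").to_numpy()
    rank_a = pd.Series(a).rank(method="average").to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    ref_sample: str | None = None,
) -> NormalizationState:
    """Trimmed-mean-of-M-values scaling factors for a count matrix.

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean across samples.  Features with a zero count in
    either member of a pair are excluded from that pair's trimmed mean;
    the factors are rescaled to geometric mean one, so equal-composition
    libraries (including exact depth multiples) all receive factor 1.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        zero = lib.index[lib == 0][0]
        raise ValueError(f"sample {zero!r} has zero total count")
    if ref_sample is None:
        uq = counts.apply(lambda c: np.quantile(c.to_numpy() / c.sum(), 0.75))
        ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy()
    raw = {}
    for s in counts.columns:
        if s == ref_sample:
            raw[s] = 1.0
        else:
            raw[s] = _tmm_pair(
                counts[s].to_numpy(), ref, lib[s], lib[ref_sample],
                logratio_trim, sum_trim,
            )
    f = pd.Series(raw, dtype=float).loc[counts.columns]
    f = f / np.exp(np.mean(np.log(f)))
    return NormalizationState(library_size=counts.sum(axis=0), tmm_factor=f)


def log_cpm(
    counts: pd.DataFrame,
    norm: NormalizationState | None = None,
    prior: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million on effective library sizes with a prior count.

    ``log2((count + prior) / (effective_library_size + 2 * prior) * 1e6)``.
    """
    if norm is None:
        norm = tmm_factors(counts)
    eff = norm.effective_library_size.loc[counts.columns].to_numpy(dtype=float)
    arr = counts.to_numpy(dtype=float)
    out = np.log2((arr + prior) / (eff[None, :] + 2.0 * prior) * 1e6)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)
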