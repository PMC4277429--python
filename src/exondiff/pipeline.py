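"""Strategy wiring: filter -> normalize -> test -> aggregate/rank.

Both strategies start from the same exon table and the same filter.  The
exon-based strategy tests each retained exon and aggregates the signed
log-p values per gene; the gene-based strategy sums each retained gene's
exon counts (by default over all of its exons, so the gene sees its full
signal) and tests the summed counts directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import aggregate, exon_test, preprocess
from .count_io import ExonCountTable

__all__ = ["StrategyParams", "run_exon_strategy", "run_gene_strategy", "run_both"]


@dataclass
class StrategyParams:
    min_avg: float = 1.0
    min_exons: int = 2
    sum_filtered_exons_only: bool = False
    prior_count: float = 0.5
    aggregator: str = "median"
    mc_reps: int = aggregate.DEFAULT_MC_REPS
    mc_seed: int = aggregate.DEFAULT_MC_SEED
    cache_dir: str | None = None
    fdr_max: float = 0.05
    min_abs_fc: float = 1.5
    call_min_exons: int = 5
    median_p_max: float = 0.05


def run_exon_strategy(
    table: ExonCountTable,
    params: StrategyParams | None = None,
    exon_results: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Ranked gene scores from per-exon testing and signed log-p aggregation.

    When ``exon_results`` (columns gene_id, x, p) is given — e.g. from an
    external testing tool through the plugin table — the built-in test is
    skipped and those results are aggregated directly.
    """
    p = params or StrategyParams()
    if exon_results is None:
        filtered = preprocess.filter_exons(table, p.min_avg, p.min_exons)
        results = exon_test.test_features(filtered, prior_count=p.prior_count)
        exon_results = results[["gene_id", "x", "p"]]
    scores = aggregate.score_genes(
        exon_results,
        aggregator=p.aggregator,
        mc_reps=p.mc_reps,
        mc_seed=p.mc_seed,
        cache_dir=p.cache_dir,
    )
    return aggregate.call_genes(
        scores, p.fdr_max, p.min_abs_fc, p.call_min_exons, p.median_p_max
    )


def run_gene_strategy(
    table: ExonCountTable, params: StrategyParams | None = None
) -> pd.DataFrame:
    """Conventional strategy: test per-gene summed counts.

    Returns a frame with gene_id, n_exons (exons surviving the filter),
    x (log2 fold change), p, fdr and called, ranked ascending by fdr.
    """
    p = params or StrategyParams()
    filtered = preprocess.filter_exons(table, p.min_avg, p.min_exons)
    if p.sum_filtered_exons_only:
        source = filtered
    else:
        keep = table.gene_of.isin(set(filtered.gene_of))
        source = table.subset_exons(list(table.counts.index[keep]))
        source = ExonCountTable(source.counts, source.gene_of, table.groups)
    gene_counts = preprocess.sum_gene_counts(source)
    gene_table = ExonCountTable(
        counts=gene_counts,
        gene_of=pd.Series(gene_counts.index, index=gene_counts.index),
        groups=table.groups,
    )
    results = exon_test.test_features(gene_table, prior_count=p.prior_count)
    out = results.reset_index().rename(columns={"exon_id": "gene_id_"})
    out = out.drop(columns=["gene_id_"])
    out["fdr"] = aggregate.bh_adjust(out["p"].to_numpy())
    n_exons = filtered.exons_per_gene()
    out["n_exons"] = out["gene_id"].map(n_exons).astype(int)
    out = aggregate.call_genes(
        out, p.fdr_max, p.min_abs_fc, p.call_min_exons, median_p_max=None
    )
    out = out.sort_values(["fdr", "gene_id"], kind="mergesort").reset_index(drop=True)
    return out[["gene_id", "n_exons", "x", "p", "t", "fdr", "called"]]


def run_both(
    table: ExonCountTable, params: StrategyParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    return run_exon_strategy(table, params), run_gene_strategy(table, params)
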