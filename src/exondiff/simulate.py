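"""Synthetic exon-count experiments with known truth.

Counts are negative binomial (variance = mu + phi * mu^2) around per-exon
means built as

    mean[exon, sample] = libsize[sample] * gene_mean * usage_fraction
                         * 2 ** (group effect of the exon)

where the group effect is zero in group 1 and the exon's log2 fold change
in group 2.  Gene expression is spread over exons by a symmetric Dirichlet;
differentially expressed genes receive a common log2 fold change across
their exons, except for "outlier" exons that get an independent deviant
effect (opposite sign by default) — the alternative-splicing-like failure
mode that corrupts summed gene-level counts.  Between-replicate
heterogeneity can be emulated by inflating the dispersion and the
library-size spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .count_io import ExonCountTable

__all__ = ["SimConfig", "SimTruth", "simulate_experiment", "make_outlier_gene_case"]


@dataclass
class SimConfig:
    """Generator settings; defaults give a clean bulk two-group experiment.

    baseline_mean_* parameterize a log-normal over per-gene expected total
    counts (meanlog 6.0 ~ median 400 reads per gene); exon_usage_alpha is
    the symmetric Dirichlet concentration spreading those reads over exons
    (5.0: moderately even usage); dispersion is the NB phi in
    var = mu + phi mu^2; effect sizes are sign * N(effect_mean,
    effect_sd^2) in log2 units with equiprobable sign; outlier exons of DE
    genes flip sign with magnitude N(outlier_mean, outlier_sd^2).
    """

    n_genes: int = 2000
    exons_min: int = 2
    exons_max: int = 15
    n_per_group: int = 5
    baseline_mean_meanlog: float = 6.0
    baseline_mean_sdlog: float = 1.2
    exon_usage_alpha: float = 5.0
    dispersion: float = 0.1
    de_fraction: float = 0.1
    effect_mean: float = 1.0
    effect_sd: float = 0.25
    outlier_exon_prob: float = 0.1
    outlier_mean: float = 2.0
    outlier_sd: float = 0.5
    libsize_sdlog: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.de_fraction <= 1 and 0 <= self.outlier_exon_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.exons_max > 1 and self.exon_usage_alpha <= 0:
            raise ValueError("degenerate exon usage (alpha <= 0) with multi-exon genes")


@dataclass
class SimTruth:
    """Ground truth: per-gene DE status/effect and per-exon effects."""

    genes: pd.DataFrame  # gene_id, is_de, gene_log2fc
    exons: pd.DataFrame  # exon_id, gene_id, exon_log2fc, is_outlier

    def to_tsv(self, gene_path, exon_path) -> None:
        self.genes.to_csv(gene_path, sep="\t", index=False)
        self.exons.to_csv(exon_path, sep="\t", index=False)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_experiment(config: SimConfig) -> tuple[ExonCountTable, SimTruth]:
    """Draw one two-group exon-count experiment; reproducible for a seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_exons_per_gene = rng.integers(cfg.exons_min, cfg.exons_max + 1, size=cfg.n_genes)
    gene_means = rng.lognormal(cfg.baseline_mean_meanlog, cfg.baseline_mean_sdlog, cfg.n_genes)
    is_de = rng.random(cfg.n_genes) < cfg.de_fraction
    signs = rng.choice([-1.0, 1.0], size=cfg.n_genes)
    gene_lfc = np.where(is_de, signs * rng.normal(cfg.effect_mean, cfg.effect_sd, cfg.n_genes), 0.0)

    n_samples = 2 * cfg.n_per_group
    libsize = rng.lognormal(0.0, cfg.libsize_sdlog, n_samples)
    sample_ids = [f"s{i+1:02d}_g1" for i in range(cfg.n_per_group)] + [
        f"s{i+1:02d}_g2" for i in range(cfg.n_per_group)
    ]
    group = pd.Series(
        ["g1"] * cfg.n_per_group + ["g2"] * cfg.n_per_group, index=sample_ids
    )

    exon_ids: list[str] = []
    gene_of: list[str] = []
    exon_lfc_all: list[np.ndarray] = []
    is_outlier_all: list[np.ndarray] = []
    mean_rows: list[np.ndarray] = []
    in_group2 = np.array([g == "g2" for g in group])

    for g in range(cfg.n_genes):
        gid = f"G{g:05d}"
        ne = int(n_exons_per_gene[g])
        usage = rng.dirichlet(np.full(ne, cfg.exon_usage_alpha)) if ne > 1 else np.array([1.0])
        exon_lfc = np.full(ne, gene_lfc[g])
        outlier = np.zeros(ne, dtype=bool)
        if is_de[g] and cfg.outlier_exon_prob > 0:
            outlier = rng.random(ne) < cfg.outlier_exon_prob
            n_out = int(outlier.sum())
            if n_out:
                exon_lfc[outlier] = -np.sign(gene_lfc[g]) * rng.normal(
                    cfg.outlier_mean, cfg.outlier_sd, n_out
                )
        base = gene_means[g] * usage  # per-exon group-1 expectation at libsize 1
        eff = np.where(in_group2[None, :], 2.0 ** exon_lfc[:, None], 1.0)
        mean_rows.append(base[:, None] * libsize[None, :] * eff)
        exon_ids.extend(f"{gid}:E{j:03d}" for j in range(1, ne + 1))
        gene_of.extend([gid] * ne)
        exon_lfc_all.append(exon_lfc)
        is_outlier_all.append(outlier)

    mean = np.vstack(mean_rows)
    counts = _nb_draw(rng, mean, cfg.dispersion)
    table = ExonCountTable(
        counts=pd.DataFrame(counts, index=pd.Index(exon_ids), columns=sample_ids),
        gene_of=pd.Series(gene_of, index=pd.Index(exon_ids)),
        groups=group,
    )
    truth = SimTruth(
        genes=pd.DataFrame(
            {
                "gene_id": [f"G{g:05d}" for g in range(cfg.n_genes)],
                "is_de": is_de,
                "gene_log2fc": gene_lfc,
            }
        ),
        exons=pd.DataFrame(
            {
                "exon_id": exon_ids,
                "gene_id": gene_of,
                "exon_log2fc": np.concatenate(exon_lfc_all),
                "is_outlier": np.concatenate(is_outlier_all),
            }
        ),
    )
    return table, truth


def make_outlier_gene_case(
    n_exons: int = 8,
    concordant_lfc: float = 1.0,
    outlier_lfc: float = -4.0,
    n_per_group: int = 7,
    n_null_genes: int = 200,
    gene_mean: float = 2000.0,
    outlier_usage: float = 0.5,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[ExonCountTable, SimTruth]:
    """One signal gene with a dominant deviant exon among null genes.

    The signal gene has ``n_exons - 1`` exons at ``concordant_lfc`` and one
    exon at ``outlier_lfc`` carrying ``outlier_usage`` of the gene's reads,
    so the deviant exon dominates the summed gene-level count.  The gene
    is embedded among ``n_null_genes`` null genes so FDR machinery has a
    realistic gene universe.  Setting ``outlier_lfc == concordant_lfc``
    removes the outlier (all exons concordant).
    """
    if n_exons < 2:
        raise ValueError("need at least 2 exons")
    null_cfg = SimConfig(
        n_genes=n_null_genes,
        n_per_group=n_per_group,
        de_fraction=0.0,
        dispersion=dispersion,
        seed=seed,
    )
    table, truth = simulate_experiment(null_cfg)
    rng = np.random.default_rng(seed + 1_000_003)

    gid = "GSIGNL"
    usage = np.full(n_exons, (1.0 - outlier_usage) / (n_exons - 1))
    usage[-1] = outlier_usage
    exon_lfc = np.full(n_exons, float(concordant_lfc))
    exon_lfc[-1] = float(outlier_lfc)
    libsize = np.ones(2 * n_per_group)  # null genes already carry depth spread
    in_group2 = np.array([g == "g2" for g in table.groups])
    eff = np.where(in_group2[None, :], 2.0 ** exon_lfc[:, None], 1.0)
    mean = gene_mean * usage[:, None] * libsize[None, :] * eff
    sig_counts = _nb_draw(rng, mean, dispersion)
    sig_ids = [f"{gid}:E{j:03d}" for j in range(1, n_exons + 1)]

    counts = pd.concat(
        [
            table.counts,
            pd.DataFrame(sig_counts, index=pd.Index(sig_ids), columns=table.sample_ids),
        ]
    )
    gene_of = pd.concat(
        [table.gene_of, pd.Series([gid] * n_exons, index=pd.Index(sig_ids))]
    )
    combined = ExonCountTable(counts=counts, gene_of=gene_of, groups=table.groups)

    genes = pd.concat(
        [
            truth.genes,
            pd.DataFrame(
                {"gene_id": [gid], "is_de": [concordant_lfc != 0.0],
                 "gene_log2fc": [concordant_lfc]}
            ),
        ],
        ignore_index=True,
    )
    exons = pd.concat(
        [
            truth.exons,
            pd.DataFrame(
                {
                    "exon_id": sig_ids,
                    "gene_id": gid,
                    "exon_log2fc": exon_lfc,
                    "is_outlier": [False] * (n_exons - 1)
                    + [outlier_lfc != concordant_lfc],
                }
            ),
        ],
        ignore_index=True,
    )
    return combined, SimTruth(genes=genes, exons=exons)
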