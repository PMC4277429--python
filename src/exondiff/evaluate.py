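"""Evaluation toolkit: gold standards, pAUC, empirical FDR, discrepancies.

The gold-standard construction mirrors the qRT-PCR convention used for
MAQC-style benchmarking: genes reliably detected in the validation assay
are labeled positive when their absolute validation log fold change
exceeds a stringency cutoff and negative when it is below 0.2; genes in
between stay unlabeled, and unlabeled genes are ignored by the ROC.

The headline metric is the partial area under the ROC curve at a fixed
specificity of 0.8 (false-positive rate <= 0.2), standardized so a
perfect ranking scores 1.0 and an exchangeable-random ranking 0.1 in
expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

__all__ = [
    "GoldStandard",
    "build_gold_standard",
    "pauc",
    "empirical_fdr",
    "random_baseline",
    "discrepancy_report",
]


@dataclass
class GoldStandard:
    positives: set
    negatives: set
    pos_cutoff: float
    neg_cutoff: float = 0.2

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("gold-standard positives and negatives overlap")


def build_gold_standard(
    validation: pd.DataFrame,
    pos_cutoff: float,
    neg_cutoff: float = 0.2,
    min_present: int = 3,
) -> GoldStandard:
    """Positive/negative gene sets from a validation fold-change table.

    ``validation`` needs columns gene_id, log2fc and per-group replicate
    detection counts ``n_present_group1``/``n_present_group2`` (out of
    ``n_replicates``, default column absent -> 4).  A gene enters the gold
    standard only if detected in at least ``min_present`` replicates of at
    least one group; then |log2fc| > pos_cutoff labels it positive and
    |log2fc| < neg_cutoff negative.
    """
    if pos_cutoff <= neg_cutoff:
        raise ValueError("pos_cutoff must exceed neg_cutoff")
    req = {"gene_id", "log2fc", "n_present_group1", "n_present_group2"}
    if not req.issubset(validation.columns):
        raise ValueError(f"validation table needs columns {sorted(req)}")
    present = (
        (validation["n_present_group1"] >= min_present)
        | (validation["n_present_group2"] >= min_present)
    )
    v = validation[present]
    lfc = v["log2fc"].abs()
    positives = set(v.loc[lfc > pos_cutoff, "gene_id"])
    negatives = set(v.loc[lfc < neg_cutoff, "gene_id"])
    return GoldStandard(positives, negatives, pos_cutoff, neg_cutoff)


def pauc(
    scores,
    labels,
    specificity: float = 0.8,
    standardized: bool = True,
    ascending: bool = True,
) -> float:
    """Partial area under the ROC curve at false-positive rate <= 1 - specificity.

    ``scores`` are significance scores where smaller means more significant
    when ``ascending`` (p-value-like; pass ascending=False for
    larger-is-better scores).  Tied scores step diagonally.  With
    ``standardized`` the area is divided by (1 - specificity), so a perfect
    ranking gives 1.0.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("need both classes to compute a ROC curve")
    fpr, tpr, _ = roc_curve(y, -s if ascending else s)
    fpr_max = 1.0 - specificity
    # cut the curve at fpr_max, interpolating the boundary point
    idx = np.searchsorted(fpr, fpr_max, side="right")
    fx = fpr[:idx]
    fy = tpr[:idx]
    if fx[-1] < fpr_max:
        t_at = np.interp(fpr_max, fpr, tpr)
        fx = np.append(fx, fpr_max)
        fy = np.append(fy, t_at)
    area = float(np.trapezoid(fy, fx))
    return area / fpr_max if standardized else area


def empirical_fdr(
    detections: pd.DataFrame,
    gold: GoldStandard,
    prefilter_lfc: float = 0.2,
) -> float | None:
    """Fraction of gold-standard-labeled detections that are negatives.

    ``detections`` needs columns gene_id and log2fc (the analysis fold
    change); detections with |log2fc| below ``prefilter_lfc`` are removed
    first.  Returns None when no detection carries a gold label.
    """
    d = detections[detections["log2fc"].abs() >= prefilter_lfc]
    genes = set(d["gene_id"])
    tp = len(genes & gold.positives)
    fp = len(genes & gold.negatives)
    if tp + fp == 0:
        return None
    return fp / (tp + fp)


def random_baseline(
    detection_sizes,
    gold: GoldStandard,
    universe,
    reps: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Mean empirical FDR of same-sized random gene selections.

    For each requested size, genes are drawn uniformly without replacement
    from ``universe`` (all scored genes by default convention) and the
    empirical FDR against the gold standard is averaged over ``reps``
    draws (draws with no gold-labeled gene are skipped in the average).
    No fold-change prefilter applies: random picks carry no effect size.
    """
    universe = list(universe)
    rng = np.random.default_rng(seed)
    pos, neg = gold.positives, gold.negatives
    out = {}
    for size in detection_sizes:
        if size > len(universe):
            raise ValueError(f"selection size {size} exceeds universe {len(universe)}")
        if size == 0:
            out[size] = np.nan
            continue
        vals = []
        for _ in range(reps):
            pick = rng.choice(len(universe), size=size, replace=False)
            genes = {universe[i] for i in pick}
            tp, fp = len(genes & pos), len(genes & neg)
            if tp + fp:
                vals.append(fp / (tp + fp))
        out[size] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(out, name="random_fdr")


def discrepancy_report(
    gene_scores: pd.DataFrame,
    exon_scores: pd.DataFrame,
    exon_results: pd.DataFrame,
    min_exons: int = 3,
    fc_thresh: float = 2.0,
    p_thresh: float = 0.05,
    p_gap: float = 0.1,
) -> pd.DataFrame:
    """Genes on which the two strategies disagree most.

    A gene qualifies when it has more than ``min_exons`` exons and one
    strategy finds it significant (p-value — median p-value for the
    exon-based strategy — below ``p_thresh``) with a fold change above
    ``fc_thresh`` on the linear scale, while the other strategy either
    estimates a fold change in the opposite direction or differs in
    p-value by more than ``p_gap`` (gene-based p against the exon-based
    final score, both on the probability scale).

    ``gene_scores`` needs gene_id, x (log2fc), p; ``exon_scores`` is the
    aggregation output; ``exon_results`` the per-exon test table used to
    report the spread (median and standard deviation) of exon fold changes.
    """
    g = gene_scores.set_index("gene_id")
    e = exon_scores.set_index("gene_id")
    common = g.index.intersection(e.index)
    lfc_thresh = math.log2(fc_thresh)
    rows = []
    spread = exon_results.groupby("gene_id")["x"].agg(["median", "std"])
    for gene in common:
        n = int(e.loc[gene, "n_exons"])
        if n <= min_exons:
            continue
        gene_p = float(g.loc[gene, "p"])
        gene_fc = float(g.loc[gene, "x"])
        exon_p = float(e.loc[gene, "median_p"])
        exon_fc = float(e.loc[gene, "median_log2fc"])
        exon_final = float(e.loc[gene, "final_score"])
        exon_sig = exon_p < p_thresh and abs(exon_fc) > lfc_thresh
        gene_sig = gene_p < p_thresh and abs(gene_fc) > lfc_thresh
        opposite = gene_fc * exon_fc < 0
        gap = abs(gene_p - exon_final) > p_gap
        if (exon_sig or gene_sig) and (opposite or gap):
            rows.append(
                {
                    "gene_id": gene,
                    "n_exons": n,
                    "gene_log2fc": gene_fc,
                    "gene_p": gene_p,
                    "exon_median_log2fc": exon_fc,
                    "exon_median_p": exon_p,
                    "exon_final_score": exon_final,
                    "exon_fc_median": float(spread.loc[gene, "median"]),
                    "exon_fc_sd": float(spread.loc[gene, "std"]),
                    "opposite_direction": bool(opposite),
                    "p_gap_exceeded": bool(gap),
                }
            )
    cols = [
        "gene_id", "n_exons", "gene_log2fc", "gene_p", "exon_median_log2fc",
        "exon_median_p", "exon_final_score", "exon_fc_median", "exon_fc_sd",
        "opposite_direction", "p_gap_exceeded",
    ]
    return pd.DataFrame(rows, columns=cols)
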