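"""Gene-level aggregation of per-exon test results.

Each tested exon *i* contributes a signed log-transformed p-value
``s_i = sgn(x_i) * (-ln p_i)``, where ``x_i`` is its estimated log2 fold
change.  The gene score ``m`` is the median of the ``s_i`` over the gene's
``n`` exons; the least significant p-value (p = 1) contributes exactly
zero.  Significance of ``m`` is assessed against the null in which the
exon p-values are independent Uniform(0,1) and the signs independent fair
coin flips — each ``s_i`` is then a standard Laplace variate, so the null
distribution of the median is the Laplace median order statistic:

* odd ``n``: closed form via the binomial identity with per-exon tail
  ``q(t) = exp(-t) / 2``,
  ``P(|M| >= t) = 2 * sum_{k >= (n+1)/2} C(n,k) q^k (1-q)^(n-k)``;
* even ``n`` (median = mean of the two central order statistics): a cached
  Monte Carlo table with log-linear tail interpolation.

Gene-level null p-values are Benjamini-Hochberg adjusted, and the final
score is ``max(median_p, fdr)`` where ``median_p = exp(-|m|)`` — this max
rule guarantees the back-transformed median p-value is itself below any
FDR threshold a gene passes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("exondiff")

__all__ = [
    "P_FLOOR",
    "DEFAULT_MC_REPS",
    "DEFAULT_MC_SEED",
    "NullTable",
    "signed_log_p",
    "gene_median_score",
    "null_tail",
    "gene_null_pvalue",
    "bh_adjust",
    "score_genes",
    "call_genes",
]

P_FLOOR = 1e-300
DEFAULT_MC_REPS = 2_000_000
DEFAULT_MC_SEED = 20141226  # recorded in output metadata by the CLI


def signed_log_p(p, x):
    """Signed log-transformed p-value ``sgn(x) * (-ln p)``.

    p is clamped to [1e-300, 1] before the log; a zero fold change
    contributes a zero score (sgn(0) = 0).
    """
    p_arr = np.asarray(p, dtype=float)
    x_arr = np.asarray(x, dtype=float)
    n_clamped = int(np.sum(p_arr < P_FLOOR))
    if n_clamped:
        logger.info("clamped %d p-values below %.0e before log transform", n_clamped, P_FLOOR)
    p_clamped = np.clip(p_arr, P_FLOOR, 1.0)
    s = np.sign(x_arr) * (-np.log(p_clamped))
    if np.isscalar(p) and np.isscalar(x):
        return float(s)
    return s


def gene_median_score(scores, aggregator: str = "median") -> float:
    """Aggregate a gene's signed log-p scores (median by default).

    For even n the median is the arithmetic mean of the two central order
    statistics.  Genes must have at least two tested exons; single-exon
    genes are removed upstream because their result would not differ from
    the gene-based approach.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("gene score needs at least 2 exons")
    if aggregator == "median":
        return float(np.median(s))
    if aggregator == "mean":
        return float(np.mean(s))
    raise ValueError(f"unknown aggregator {aggregator!r}")


# ---------------------------------------------------------------------------
# null distribution of the median of n signed log-p scores
# ---------------------------------------------------------------------------

def _odd_tail(n: int, t) -> np.ndarray:
    """Closed-form P(|median| >= t) for odd n (and n = 1).

    Each score is standard Laplace; |median| >= t iff at least (n+1)/2
    scores lie above t (or, symmetrically, below -t), with per-score tail
    q = exp(-t)/2.
    """
    t = np.asarray(t, dtype=float)
    q = 0.5 * np.exp(-t)
    k_min = (n + 1) // 2
    return np.minimum(1.0, 2.0 * stats.binom.sf(k_min - 1, n, q))


@dataclass
class NullTable:
    """Tail function P(|M_n| >= t) for the median of n null scores.

    Analytic for odd n; for even n a Monte Carlo grid (log-spaced t,
    log-linear interpolation of the tail, log-linear extrapolation past
    the largest simulated value).
    """

    n: int
    method: str  # "analytic" | "monte_carlo"
    mc_reps: int | None = None
    mc_seed: int | None = None
    t_grid: np.ndarray | None = None
    log_tail_grid: np.ndarray | None = None
    ext_slope: float | None = None  # d log-tail / dt beyond the grid

    def tail(self, t) -> np.ndarray:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < 0):
            raise ValueError("t must be >= 0")
        if self.method == "analytic":
            out = _odd_tail(self.n, t_arr)
        else:
            # piecewise-exponential tail: linear in log-tail between grid
            # knots; the last segment's slope extends beyond the grid
            lt = np.interp(t_arr, self.t_grid, self.log_tail_grid)
            beyond = t_arr > self.t_grid[-1]
            if np.any(beyond):
                slope = self.ext_slope
                if slope is None:
                    slope = (self.log_tail_grid[-1] - self.log_tail_grid[-2]) / (
                        self.t_grid[-1] - self.t_grid[-2]
                    )
                lt[beyond] = self.log_tail_grid[-1] + slope * (
                    t_arr[beyond] - self.t_grid[-1]
                )
            out = np.exp(np.maximum(lt, math.log(P_FLOOR)))
        return out if np.ndim(t) else float(out[0])

    # -- cache serialization -------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "n": self.n,
            "method": self.method,
            "mc_reps": self.mc_reps,
            "mc_seed": self.mc_seed,
            "t_grid": None if self.t_grid is None else self.t_grid.tolist(),
            "log_tail_grid": None
            if self.log_tail_grid is None
            else self.log_tail_grid.tolist(),
            "ext_slope": self.ext_slope,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NullTable":
        d = json.loads(Path(path).read_text())
        return cls(
            n=d["n"],
            method=d["method"],
            mc_reps=d["mc_reps"],
            mc_seed=d["mc_seed"],
            t_grid=None if d["t_grid"] is None else np.array(d["t_grid"]),
            log_tail_grid=None
            if d["log_tail_grid"] is None
            else np.array(d["log_tail_grid"]),
            ext_slope=d.get("ext_slope"),
        )


_NULL_CACHE: dict[tuple[int, int, int], NullTable] = {}


def _mc_null_table(n: int, reps: int, seed: int) -> NullTable:
    rng = np.random.default_rng(seed + n)
    abs_med = np.empty(reps)
    chunk = max(1, int(4e6) // n)
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        draws = rng.laplace(size=(m, n))
        abs_med[done : done + m] = np.abs(np.median(draws, axis=1))
        done += m
    abs_med.sort()
    t_max = abs_med[-1]
    t_grid = np.concatenate([[0.0], np.geomspace(1e-4, t_max, 800)])
    # empirical survival, floored at half a rep so log stays finite
    tail = 1.0 - np.searchsorted(abs_med, t_grid, side="left") / reps
    tail = np.maximum(tail, 0.5 / reps)
    tail = np.minimum.accumulate(tail)
    # collapse trailing flat (floored) knots to keep extrapolation sane
    last = int(np.argmax(tail <= 0.5 / reps)) if tail[-1] <= 0.5 / reps else len(tail) - 1
    t_grid, tail = t_grid[: last + 1], tail[: last + 1]
    log_tail = np.log(tail)
    # extrapolation slope from a least-squares fit over the extreme-tail
    # knots (tail below 500/reps): individual knots out there sit on only a
    # handful of draws and give wildly noisy pairwise slopes
    extreme = tail <= 500.0 / reps
    if extreme.sum() >= 3:
        ext_slope = float(np.polyfit(t_grid[extreme], log_tail[extreme], 1)[0])
    else:
        ext_slope = float(
            (log_tail[-1] - log_tail[len(log_tail) // 2])
            / (t_grid[-1] - t_grid[len(log_tail) // 2])
        )
    return NullTable(
        n=n,
        method="monte_carlo",
        mc_reps=reps,
        mc_seed=seed,
        t_grid=t_grid,
        log_tail_grid=log_tail,
        ext_slope=ext_slope,
    )


def get_null_table(
    n: int,
    mc_reps: int = DEFAULT_MC_REPS,
    mc_seed: int = DEFAULT_MC_SEED,
    cache_dir: str | Path | None = None,
) -> NullTable:
    """Null table for n exons, cached in memory and optionally on disk."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n % 2 == 1:
        return NullTable(n=n, method="analytic")
    key = (n, mc_reps, mc_seed)
    path = None
    if cache_dir is not None:
        path = Path(cache_dir) / f"null_n{n}_reps{mc_reps}_seed{mc_seed}.json"
    table = _NULL_CACHE.get(key)
    if table is None and path is not None and path.exists():
        table = NullTable.from_json(path)
    if table is None:
        table = _mc_null_table(n, mc_reps, mc_seed)
    _NULL_CACHE[key] = table
    if path is not None and not path.exists():
        path.parent.mkdir(parents=True, exist_ok=True)
        table.to_json(path)
    return table


def null_tail(
    n: int,
    t,
    mc_reps: int = DEFAULT_MC_REPS,
    mc_seed: int = DEFAULT_MC_SEED,
    cache_dir: str | Path | None = None,
):
    """P(|median of n null scores| >= t); see module docstring for the model."""
    return get_null_table(n, mc_reps, mc_seed, cache_dir).tail(t)


def gene_null_pvalue(
    m: float,
    n: int,
    mc_reps: int = DEFAULT_MC_REPS,
    mc_seed: int = DEFAULT_MC_SEED,
    cache_dir: str | Path | None = None,
) -> float:
    """Two-sided null p-value of an observed gene score m with n exons."""
    return float(null_tail(n, abs(m), mc_reps, mc_seed, cache_dir))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# gene scoring and calling
# ---------------------------------------------------------------------------

def score_genes(
    exon_results: pd.DataFrame,
    aggregator: str = "median",
    mc_reps: int = DEFAULT_MC_REPS,
    mc_seed: int = DEFAULT_MC_SEED,
    cache_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Aggregate per-exon (x, p) results into ranked gene scores.

    ``exon_results`` needs columns gene_id, x, p (one row per tested exon).
    Returns one row per gene with n_exons, median_log2fc, score_m,
    median_p = exp(-|m|), null_p, BH fdr over all genes, final_score =
    max(median_p, fdr) and the diagnostic raw_median_p (plain median of
    the exon p-values); ranked ascending by final_score, ties broken by
    gene_id.
    """
    req = {"gene_id", "x", "p"}
    if not req.issubset(exon_results.columns):
        raise ValueError(f"exon results need columns {sorted(req)}")
    s = signed_log_p(exon_results["p"].to_numpy(), exon_results["x"].to_numpy())
    df = exon_results.assign(_s=s)
    rows = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        n = len(grp)
        m = gene_median_score(grp["_s"].to_numpy(), aggregator=aggregator)
        rows.append(
            {
                "gene_id": gene_id,
                "n_exons": n,
                "median_log2fc": float(np.median(grp["x"].to_numpy())),
                "score_m": m,
                "median_p": math.exp(-abs(m)),
                "null_p": gene_null_pvalue(m, n, mc_reps, mc_seed, cache_dir),
                "raw_median_p": float(np.median(grp["p"].to_numpy())),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["null_p"].to_numpy())
    out["final_score"] = np.maximum(out["median_p"], out["fdr"])
    out = out.sort_values(["final_score", "gene_id"], kind="mergesort")
    return out.reset_index(drop=True)


def call_genes(
    scores: pd.DataFrame,
    fdr_max: float = 0.05,
    min_abs_fc: float = 1.5,
    min_exons: int = 5,
    median_p_max: float | None = 0.05,
) -> pd.DataFrame:
    """Apply the calling criteria and set the ``called`` flag.

    A gene is called when its (max-rule) score is below ``fdr_max``, its
    absolute fold change is at least ``min_abs_fc`` on the linear scale
    (|median_log2fc| >= log2(min_abs_fc)) and it has at least ``min_exons``
    tested exons.  For exon-based scores the back-transformed median
    p-value must additionally be below ``median_p_max``; pass None to skip
    that criterion (gene-based scores).
    """
    out = scores.copy()
    score_col = "final_score" if "final_score" in out.columns else "fdr"
    fc_col = "median_log2fc" if "median_log2fc" in out.columns else "x"
    called = (
        (out[score_col] < fdr_max)
        & (out[fc_col].abs() >= math.log2(min_abs_fc))
        & (out["n_exons"] >= min_exons)
    )
    if median_p_max is not None and "median_p" in out.columns:
        called &= out["median_p"] < median_p_max
    out["called"] = called.to_numpy()
    return out
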