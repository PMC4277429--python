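"""Reading and writing of exon-level count data and result tables.

The central container is :class:`ExonCountTable`: a non-negative integer
count matrix (exons x samples) together with an exon-to-gene map and an
optional sample-to-group map.  Two input dialects are supported:

* per-sample two-column files as produced by exon-bin counting scripts,
  with feature keys of the form ``geneID:exonBin`` and trailing meta rows
  (feature names starting with ``_``) holding unassigned-read tallies;
* a single TSV matrix with ``gene_id`` and ``exon_id`` columns followed by
  one column per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("exondiff")

__all__ = [
    "ExonCountTable",
    "SampleSheet",
    "read_sample_sheet",
    "read_dexseq_counts",
    "read_count_matrix",
    "read_external_exon_results",
    "read_flattened_gff",
    "write_gene_results",
    "GENE_RESULT_COLUMNS",
]


class CountInputError(ValueError):
    """Raised for malformed count input (bad counts, mismatched universes...)."""


@dataclass
class ExonCountTable:
    """Per-exon read counts with gene assignment and sample groups.

    Parameters
    ----------
    counts
        Integer DataFrame indexed by exon_id with one column per sample.
    gene_of
        Series mapping each exon_id (index) to its gene_id.
    groups
        Optional Series mapping sample_id to group label.  Exactly two
        distinct groups are required for testing, but the table itself may
        carry any number (or none, e.g. straight after simulation I/O).
    """

    counts: pd.DataFrame
    gene_of: pd.Series
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        self.counts.index.name = "exon_id"
        self.gene_of.index.name = "exon_id"
        self.gene_of.name = "gene_id"
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()][0]
            raise CountInputError(f"duplicate exon_id {dup!r}")
        if not np.issubdtype(np.asarray(c.to_numpy()).dtype, np.integer):
            # allow float storage only if exactly integral
            arr = c.to_numpy()
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise CountInputError("counts must be integers")
            self.counts = c.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise CountInputError("negative count in table")
        if not self.gene_of.index.equals(self.counts.index):
            self.gene_of = self.gene_of.reindex(self.counts.index)
            if self.gene_of.isna().any():
                missing = self.gene_of.index[self.gene_of.isna()][0]
                raise CountInputError(f"exon {missing!r} has no gene assignment")
        if self.groups is not None:
            missing = [s for s in self.counts.columns if s not in self.groups.index]
            if missing:
                raise CountInputError(f"samples without group label: {missing}")
            self.groups = self.groups.loc[list(self.counts.columns)]

    # -- convenience ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def exon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def gene_ids(self) -> list[str]:
        """Unique gene ids in order of first appearance."""
        return list(dict.fromkeys(self.gene_of))

    @property
    def n_exons(self) -> int:
        return self.counts.shape[0]

    def exons_per_gene(self) -> pd.Series:
        return self.gene_of.groupby(self.gene_of, sort=False).size()

    def subset_exons(self, exon_ids: Sequence[str]) -> "ExonCountTable":
        return ExonCountTable(
            counts=self.counts.loc[list(exon_ids)].copy(),
            gene_of=self.gene_of.loc[list(exon_ids)].copy(),
            groups=None if self.groups is None else self.groups.copy(),
        )

    def with_groups(self, groups: Mapping[str, str] | pd.Series) -> "ExonCountTable":
        g = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
        return ExonCountTable(self.counts.copy(), self.gene_of.copy(), g)

    def two_group_labels(self) -> tuple[str, str]:
        """The two group labels in sorted order (group2 - group1 contrasts)."""
        if self.groups is None:
            raise CountInputError("table has no sample groups")
        labels = sorted(self.groups.unique())
        if len(labels) != 2:
            raise CountInputError(f"exactly two groups required, got {labels}")
        return labels[0], labels[1]

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix dialect readable by :func:`read_count_matrix`."""
        out = self.counts.copy()
        out.insert(0, "exon_id", out.index)
        out.insert(0, "gene_id", self.gene_of.to_numpy())
        out.to_csv(path, sep="\t", index=False)


@dataclass
class SampleSheet:
    """Samples with group labels and (for per-sample files) count paths."""

    table: pd.DataFrame  # columns: sample_id, group, file_path (optional)

    def __post_init__(self) -> None:
        t = self.table
        for col in ("sample_id", "group"):
            if col not in t.columns:
                raise CountInputError(f"sample sheet missing column {col!r}")
        if t["sample_id"].duplicated().any():
            raise CountInputError("duplicate sample_id in sample sheet")

    @property
    def groups(self) -> pd.Series:
        return pd.Series(
            self.table["group"].to_numpy(), index=self.table["sample_id"].to_numpy()
        )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t", dtype=str))


# ---------------------------------------------------------------------------
# per-sample two-column count files ("geneID:exonBin<TAB>count")
# ---------------------------------------------------------------------------

def _read_one_count_file(path: str | Path) -> pd.Series:
    features: list[str] = []
    values: list[int] = []
    n_meta = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CountInputError(
                    f"{path}: line {lineno}: expected two tab-separated fields"
                )
            feat, raw = parts
            if feat.startswith("_"):
                n_meta += 1
                continue
            try:
                value = int(raw)
            except ValueError:
                raise CountInputError(
                    f"{path}: line {lineno}: non-integer count {raw!r}"
                ) from None
            if value < 0:
                raise CountInputError(f"{path}: line {lineno}: negative count {value}")
            features.append(feat)
            values.append(value)
    if n_meta:
        logger.info("%s: dropped %d meta-feature rows", path, n_meta)
    if not features:
        raise CountInputError(f"{path}: no exon features")
    s = pd.Series(values, index=features, dtype=np.int64)
    if s.index.has_duplicates:
        dup = s.index[s.index.duplicated()][0]
        raise CountInputError(f"{path}: duplicate feature {dup!r}")
    return s


def read_dexseq_counts(sample_sheet: SampleSheet) -> ExonCountTable:
    """Assemble an :class:`ExonCountTable` from per-sample count files.

    Every file must cover an identical exon universe; meta rows (leading
    underscore, e.g. ambiguous/no-feature tallies) are dropped.  Exon ids
    keep the ``geneID:exonBin`` form; the gene id is the part before the
    first colon.
    """
    t = sample_sheet.table
    if "file_path" not in t.columns:
        raise CountInputError("sample sheet has no file_path column")
    columns: dict[str, pd.Series] = {}
    universe: pd.Index | None = None
    first_file = None
    for _, row in t.iterrows():
        s = _read_one_count_file(row["file_path"])
        if universe is None:
            universe, first_file = s.index, row["file_path"]
        elif set(s.index) != set(universe):
            raise CountInputError(
                f"exon universe of {row['file_path']} differs from {first_file}"
            )
        columns[row["sample_id"]] = s.reindex(universe)
    counts = pd.DataFrame(columns, index=universe)
    bad = [e for e in counts.index if ":" not in e]
    if bad:
        raise CountInputError(
            f"feature {bad[0]!r} is not of the form 'geneID:exonBin'"
        )
    gene_of = pd.Series([e.split(":", 1)[0] for e in counts.index], index=counts.index)
    return ExonCountTable(counts=counts, gene_of=gene_of, groups=sample_sheet.groups)


# ---------------------------------------------------------------------------
# TSV matrix dialect
# ---------------------------------------------------------------------------

def read_count_matrix(
    path: str | Path, groups: Mapping[str, str] | pd.Series | None = None
) -> ExonCountTable:
    """Read a TSV with columns ``gene_id``, ``exon_id``, then one per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "exon_id": str})
    for col in ("gene_id", "exon_id"):
        if col not in df.columns:
            raise CountInputError(f"{path}: missing column {col!r}")
    if df.shape[0] == 0:
        raise CountInputError(f"{path}: no exons")
    if df["exon_id"].duplicated().any():
        dup = df.loc[df["exon_id"].duplicated(), "exon_id"].iloc[0]
        raise CountInputError(f"{path}: duplicate exon_id {dup!r}")
    sample_cols = [c for c in df.columns if c not in ("gene_id", "exon_id")]
    if not sample_cols:
        raise CountInputError(f"{path}: no sample columns")
    counts = df[sample_cols].copy()
    counts.index = pd.Index(df["exon_id"])
    gene_of = pd.Series(df["gene_id"].to_numpy(), index=counts.index)
    g = None
    if groups is not None:
        g = groups if isinstance(groups, pd.Series) else pd.Series(dict(groups))
    return ExonCountTable(counts=counts, gene_of=gene_of, groups=g)


# ---------------------------------------------------------------------------
# external per-exon test results (plugin contract)
# ---------------------------------------------------------------------------

def read_external_exon_results(path: str | Path) -> pd.DataFrame:
    """Read per-exon results from another testing tool.

    Expects columns ``exon_id``, ``log2fc``, ``pvalue``.  p-values must lie
    in [0, 1]; exact zeros are accepted here (they are clamped just before
    the log transform in the aggregation step) but logged.
    """
    df = pd.read_csv(path, sep="\t", dtype={"exon_id": str})
    for col in ("exon_id", "log2fc", "pvalue"):
        if col not in df.columns:
            raise CountInputError(f"{path}: missing column {col!r}")
    if df["exon_id"].duplicated().any():
        dup = df.loc[df["exon_id"].duplicated(), "exon_id"].iloc[0]
        raise CountInputError(f"{path}: duplicate exon_id {dup!r}")
    p = df["pvalue"].to_numpy(dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        bad = df.loc[(p < 0) | (p > 1) | ~np.isfinite(p), "pvalue"].iloc[0]
        raise CountInputError(f"{path}: p-value {bad} outside [0, 1]")
    n_zero = int(np.sum(p == 0))
    if n_zero:
        logger.warning("%s: %d p-values are exactly 0 (clamped downstream)", path, n_zero)
    return df[["exon_id", "log2fc", "pvalue"]].copy()


# ---------------------------------------------------------------------------
# optional flattened exon annotation (coordinates only; never alters counts)
# ---------------------------------------------------------------------------

def read_flattened_gff(path: str | Path) -> pd.DataFrame:
    """Exon-bin coordinates from a flattened exonic-part GFF.

    Returns a frame indexed by exon_id (``geneID:exonBin``) with chrom,
    start, end (1-based inclusive, as in GFF) and strand.  Only rows whose
    feature type is ``exonic_part`` are used.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exonic_part":
                continue
            attrs = {}
            for item in f[8].split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attrs[key] = val.strip().strip('"')
            gene = attrs.get("gene_id") or attrs.get("geneID")
            part = attrs.get("exonic_part_number")
            if gene is None or part is None:
                continue
            rows.append(
                {
                    "exon_id": f"{gene}:E{part}" if not part.startswith("E") else f"{gene}:{part}",
                    "chrom": f[0],
                    "start": int(f[3]),
                    "end": int(f[4]),
                    "strand": f[6],
                }
            )
    return pd.DataFrame(rows).set_index("exon_id") if rows else pd.DataFrame(
        columns=["chrom", "start", "end", "strand"]
    )


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

GENE_RESULT_COLUMNS = [
    "gene_id",
    "n_exons",
    "median_log2fc",
    "score_m",
    "median_p",
    "null_p",
    "fdr",
    "final_score",
    "called",
]


def write_gene_results(scores: pd.DataFrame, path: str | Path) -> None:
    """Write ranked gene scores as TSV.

    Rows are sorted ascending by final_score with ties broken by gene_id;
    an empty frame yields a header-only file.  A diagnostic
    ``raw_median_p`` column (plain median of exon p-values, ignoring signs)
    is appended when present.
    """
    cols = list(GENE_RESULT_COLUMNS)
    if "raw_median_p" in scores.columns:
        cols.append("raw_median_p")
    if scores.shape[0] == 0:
        pd.DataFrame(columns=cols).to_csv(path, sep="\t", index=False)
        return
    out = scores.copy()
    if "called" not in out.columns:
        out["called"] = False
    out = out.sort_values(["final_score", "gene_id"], kind="mergesort")
    out[cols].to_csv(path, sep="\t", index=False)
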