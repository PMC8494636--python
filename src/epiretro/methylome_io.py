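"""ALLC methylation tables, count-matrix containers and QC filters.

ALLC files are the per-cell site-level output of bisulfite pipelines
(methylpy convention): a 7-column TSV of chrom, 1-based position, strand,
3-mer context, methylated base calls, total base calls and a methylated
flag.  This module reads and writes them, aggregates sites into cells x
feature (100-kb bin or gene body) count matrices per methylation context,
and applies the standard cell- and feature-level coverage filters.

Coordinate conventions: ALLC positions are 1-based; feature intervals are
0-based half-open (BED).  A site at position ``pos`` falls in features whose
interval contains ``pos - 1``.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})

__all__ = [
    "AllcRecord",
    "FeatureSet",
    "MethylCountMatrix",
    "CellQcRecord",
    "read_allc",
    "write_allc",
    "classify_context",
    "aggregate_counts",
    "qc_filter_cells",
    "filter_features",
    "SEX_CHROMOSOMES",
]


class AllcParseError(ValueError):
    """Raised when an ALLC line cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class AllcRecord:
    """One cytosine site: position is 1-based, context a 3-mer starting with C."""

    chrom: str
    pos: int
    strand: str
    context: str
    mc: int
    cov: int
    methylated: int = 1

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not (0 <= self.mc <= self.cov):
            raise ValueError(f"require 0 <= mc <= cov, got mc={self.mc} cov={self.cov}")
        if len(self.context) != 3 or not self.context.startswith("C"):
            raise ValueError(f"context must be a 3-mer starting with C, got {self.context!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def _open_text(path: str | os.PathLike, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_allc(path: str | os.PathLike) -> list[AllcRecord]:
    """Read an ALLC file (optionally gzipped) into records, in file order."""
    records: list[AllcRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AllcParseError(f"{path}: line {lineno}: expected >= 6 tab-separated fields")
            try:
                rec = AllcRecord(
                    chrom=fields[0],
                    pos=int(fields[1]),
                    strand=fields[2],
                    context=fields[3],
                    mc=int(fields[4]),
                    cov=int(fields[5]),
                    methylated=int(fields[6]) if len(fields) > 6 else 1,
                )
            except ValueError as exc:
                raise AllcParseError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_allc(records: Iterable[AllcRecord], path: str | os.PathLike) -> None:
    """Write records as 7-column ALLC TSV (gzipped if the path ends in .gz)."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.strand}\t{rec.context}\t"
                f"{rec.mc}\t{rec.cov}\t{rec.methylated}\n"
            )


def classify_context(context: str) -> str:
    """Map a 3-mer cytosine context to CG / CH (second base is G or not)."""
    return "CG" if context[1] == "G" else "CH"


@dataclass
class FeatureSet:
    """Genomic features (100-kb bins and/or gene bodies) as a BED-like table.

    ``table`` columns: chrom, start, end, feature_id, kind. Intervals are
    0-based half-open; feature_ids unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "feature_id", "kind"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"FeatureSet table missing columns: {sorted(missing)}")
        if (self.table["start"] >= self.table["end"]).any():
            raise ValueError("all features require start < end")
        if self.table["feature_id"].duplicated().any():
            dups = self.table.loc[self.table["feature_id"].duplicated(), "feature_id"]
            raise ValueError(f"duplicate feature_ids: {list(dups.unique())[:5]}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def feature_ids(self) -> np.ndarray:
        return self.table["feature_id"].to_numpy()

    @classmethod
    def from_bins(cls, chrom_sizes: dict[str, int], bin_size: int = 100_000) -> "FeatureSet":
        """Tile each chromosome with fixed-size bins (last partial bin dropped)."""
        rows = []
        for chrom, size in chrom_sizes.items():
            for start in range(0, size - bin_size + 1, bin_size):
                rows.append((chrom, start, start + bin_size, f"{chrom}:{start}-{start + bin_size}", "bin100kb"))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "feature_id", "kind"]))

    @classmethod
    def read_bed(cls, path: str | os.PathLike, kind: str = "gene") -> "FeatureSet":
        tbl = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "feature_id"], usecols=[0, 1, 2, 3],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "feature_id": str},
        )
        tbl["kind"] = kind
        return cls(tbl)

    def write_bed(self, path: str | os.PathLike) -> None:
        self.table[["chrom", "start", "end", "feature_id"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def subset(self, mask: np.ndarray) -> "FeatureSet":
        return FeatureSet(self.table.loc[np.asarray(mask)].reset_index(drop=True))

    def select_kind(self, kind: str) -> "FeatureSet":
        return self.subset((self.table["kind"] == kind).to_numpy())

    def drop_sex_chromosomes(self) -> "FeatureSet":
        keep = ~self.table["chrom"].isin(SEX_CHROMOSOMES)
        return self.subset(keep.to_numpy())


@dataclass
class MethylCountMatrix:
    """Paired cells x features integer matrices of methylated (mc) and total (tc) calls."""

    cells: list[str]
    features: FeatureSet
    mc: np.ndarray
    tc: np.ndarray
    context: str = "CH"

    def __post_init__(self) -> None:
        self.mc = np.asarray(self.mc)
        self.tc = np.asarray(self.tc)
        n_cells, n_feat = len(self.cells), len(self.features)
        if self.mc.shape != (n_cells, n_feat) or self.tc.shape != (n_cells, n_feat):
            raise ValueError(
                f"matrix shapes {self.mc.shape}/{self.tc.shape} do not match "
                f"{n_cells} cells x {n_feat} features"
            )
        if (self.mc < 0).any() or (self.tc < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.mc > self.tc).any():
            raise ValueError("mc must be <= tc elementwise")
        if self.context not in ("CH", "CG", "CCC"):
            raise ValueError(f"unknown context {self.context!r}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def raw_levels(self) -> np.ndarray:
        """mc/tc with NaN where tc = 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            lv = self.mc / self.tc
        return np.where(self.tc > 0, lv, np.nan)

    def subset_cells(self, ids: Sequence[str]) -> "MethylCountMatrix":
        index = {c: i for i, c in enumerate(self.cells)}
        rows = [index[c] for c in ids]
        return MethylCountMatrix(list(ids), self.features, self.mc[rows], self.tc[rows], self.context)

    def subset_features(self, mask: np.ndarray) -> "MethylCountMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            bmask = np.zeros(self.n_features, dtype=bool)
            bmask[mask] = True
            mask = bmask
        return MethylCountMatrix(
            self.cells, self.features.subset(mask), self.mc[:, mask], self.tc[:, mask], self.context
        )

    def select_kind(self, kind: str) -> "MethylCountMatrix":
        return self.subset_features((self.features.table["kind"] == kind).to_numpy())

    def save(self, out_dir: str | os.PathLike) -> None:
        """Persist as cells.tsv + features.bed + mc.mtx/tc.mtx (MatrixMarket)."""
        os.makedirs(out_dir, exist_ok=True)
        pd.Series(self.cells, name="cell_id").to_csv(
            os.path.join(out_dir, "cells.tsv"), sep="\t", index=False
        )
        self.features.table.to_csv(os.path.join(out_dir, "features.bed"), sep="\t", index=False)
        spio.mmwrite(os.path.join(out_dir, "mc.mtx"), sparse.csr_matrix(self.mc))
        spio.mmwrite(os.path.join(out_dir, "tc.mtx"), sparse.csr_matrix(self.tc))
        with open(os.path.join(out_dir, "context.txt"), "w") as fh:
            fh.write(self.context + "\n")

    @classmethod
    def load(cls, out_dir: str | os.PathLike) -> "MethylCountMatrix":
        cells = pd.read_csv(os.path.join(out_dir, "cells.tsv"), sep="\t")["cell_id"].astype(str).tolist()
        features = FeatureSet(pd.read_csv(os.path.join(out_dir, "features.bed"), sep="\t"))
        mc = np.asarray(spio.mmread(os.path.join(out_dir, "mc.mtx")).todense()).astype(np.int64)
        tc = np.asarray(spio.mmread(os.path.join(out_dir, "tc.mtx")).todense()).astype(np.int64)
        with open(os.path.join(out_dir, "context.txt")) as fh:
            context = fh.read().strip()
        return cls(cells, features, mc, tc, context)


@dataclass(frozen=True)
class CellQcRecord:
    """Per-cell sequencing QC: read depth and global methylation fractions."""

    cell_id: str
    n_nonclonal_reads: int
    mccc_level: float
    global_mch: float = float("nan")
    global_mcg: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("mccc_level", "global_mch", "global_mcg"):
            val = getattr(self, name)
            if not np.isnan(val) and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {val}")


def _select_context(records: Iterable[AllcRecord], context: str) -> Iterator[AllcRecord]:
    if context == "CH":
        return (r for r in records if r.context[1] != "G")
    if context == "CG":
        return (r for r in records if r.context[1] == "G")
    if context == "CCC":
        return (r for r in records if r.context == "CCC")
    raise ValueError(f"unknown context selector {context!r}")


def _combine_cpg_strands(records: list[AllcRecord]) -> list[AllcRecord]:
    """Merge the two strands of each CpG: a '-' site at pos p+1 joins the '+' site at p."""
    merged: dict[tuple[str, int], list[int]] = {}
    order: list[tuple[str, int]] = []
    for rec in records:
        # map a minus-strand call onto the plus-strand C of the same CpG
        pos = rec.pos - 1 if rec.strand == "-" else rec.pos
        key = (rec.chrom, pos)
        if key not in merged:
            merged[key] = [0, 0]
            order.append(key)
        merged[key][0] += rec.mc
        merged[key][1] += rec.cov
    return [
        AllcRecord(chrom=chrom, pos=pos, strand="+", context="CGA", mc=merged[(chrom, pos)][0],
                   cov=merged[(chrom, pos)][1])
        for chrom, pos in order
    ]


class AggregationResult:
    """Row of counts plus a counter of sites that fell on unknown chromosomes."""

    def __init__(self, mc_row: np.ndarray, tc_row: np.ndarray, n_skipped: int):
        self.mc_row = mc_row
        self.tc_row = tc_row
        self.n_skipped = n_skipped


def aggregate_counts(
    records: Iterable[AllcRecord],
    features: FeatureSet,
    context: str = "CH",
    combine_cpg: bool = True,
) -> AggregationResult:
    """Aggregate one cell's site records into per-feature (mc, tc) counts.

    A site at 1-based ``pos`` contributes to every feature whose 0-based
    half-open interval contains ``pos - 1``.  For the CG context, calls on
    the two strands of a CpG are combined first when ``combine_cpg``.
    Sites on chromosomes absent from the feature set are counted in
    ``n_skipped``.  For the CCC context callers typically want the
    genome-wide scalar; use :func:`global_level` instead of binning.
    """
    recs = list(_select_context(records, context))
    if context == "CG" and combine_cpg:
        recs = _combine_cpg_strands(recs)

    mc_row = np.zeros(len(features), dtype=np.int64)
    tc_row = np.zeros(len(features), dtype=np.int64)
    n_skipped = 0

    tbl = features.table
    by_chrom: dict[str, pd.DataFrame] = {c: g for c, g in tbl.groupby("chrom", sort=False)}
    for chrom, group in by_chrom.items():
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        idx = group.index.to_numpy()
        sites = [r for r in recs if r.chrom == chrom]
        if not sites:
            continue
        pos0 = np.array([r.pos - 1 for r in sites])
        mcs = np.array([r.mc for r in sites])
        covs = np.array([r.cov for r in sites])
        # features may overlap (e.g. genes), so test containment per feature
        for j, s, e in zip(idx, starts, ends):
            inside = (pos0 >= s) & (pos0 < e)
            if inside.any():
                mc_row[j] += int(mcs[inside].sum())
                tc_row[j] += int(covs[inside].sum())
    known = set(tbl["chrom"])
    n_skipped = sum(1 for r in recs if r.chrom not in known)
    return AggregationResult(mc_row, tc_row, n_skipped)


def global_level(records: Iterable[AllcRecord], context: str = "CCC") -> float:
    """Genome-wide sum(mc)/sum(cov) for one context (mCCC estimates non-conversion)."""
    mc_total = 0
    cov_total = 0
    for rec in _select_context(records, context):
        mc_total += rec.mc
        cov_total += rec.cov
    if cov_total == 0:
        return float("nan")
    return mc_total / cov_total


def qc_filter_cells(
    qc: Sequence[CellQcRecord],
    min_reads: int = 500_000,
    max_mccc: float = 0.01,
) -> list[str]:
    """Retain cells with >= min_reads non-clonal reads and mCCC <= max_mccc.

    Boundary values are retained: removal requires strictly fewer reads than
    the threshold or a non-conversion estimate strictly above it.
    """
    return [
        rec.cell_id
        for rec in qc
        if rec.n_nonclonal_reads >= min_reads and rec.mccc_level <= max_mccc
    ]


def filter_features(
    matrix: MethylCountMatrix,
    min_calls: int = 100,
    min_cell_fraction: float = 0.95,
    autosomes_only: bool = True,
) -> np.ndarray:
    """Boolean mask of features covered by > min_calls in > min_cell_fraction of cells.

    Both comparisons are strict.  Default fractions: 0.95 for 100-kb bins,
    0.80 for gene bodies.  Sex-chromosome features are dropped unless
    ``autosomes_only`` is False.
    """
    if matrix.n_cells == 0 or matrix.n_features == 0:
        raise ValueError("cannot filter an empty matrix")
    covered_frac = (matrix.tc > min_calls).mean(axis=0)
    keep = covered_frac > min_cell_fraction
    if autosomes_only:
        keep &= ~matrix.features.table["chrom"].isin(SEX_CHROMOSOMES).to_numpy()
    return keep
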