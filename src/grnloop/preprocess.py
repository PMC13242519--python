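"""Single-cell count preprocessing and time-series summarisation.

Turns per-time-point cell-by-gene count tables into the per-gene,
per-time-point (mean, SE_eff) dataset the ODE fit consumes:

1. cells with fewer than ``min_genes_per_cell`` detected genes are
   dropped, then genes expressed in fewer than ``min_cells_per_gene`` of
   the retained cells (cells first, then genes — order matters and is
   fixed);
2. each cell is scaled to a common library size (default 30,000 counts);
3. per gene, values are log1p-transformed and divided by that gene's
   maximum log1p value across *all* time points, giving values in [0,1];
4. per (gene, time point) the mean and the effective standard error
   SE_eff = SD / sqrt(N_eff) are reported, with a deliberately small
   effective sample size (default N_eff = 15) because cells from one
   sample are not independent biological replicates.

Filtering and normalisation delegate to scanpy on an AnnData view of the
counts; the summarisation is plain pandas/numpy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc


@dataclass(frozen=True)
class CountMatrix:
    """Cells x genes non-negative count table for one time point."""

    cells: tuple
    genes: tuple
    counts: np.ndarray = field(repr=False)  # shape (n_cells, n_genes)
    time_label: float = 0.0

    def __post_init__(self):
        cells = tuple(str(c) for c in self.cells)
        genes = tuple(str(g) for g in self.genes)
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (len(cells), len(genes)):
            raise ValueError(
                f"counts shape {counts.shape} != ({len(cells)}, {len(genes)})")
        if counts.size and counts.min() < 0:
            raise ValueError("negative counts")
        if len(set(genes)) != len(genes):
            raise ValueError("gene identifiers must be unique")
        if len(set(cells)) != len(cells):
            raise ValueError("cell identifiers must be unique")
        object.__setattr__(self, "cells", cells)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "counts", counts)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=list(self.cells)),
            var=pd.DataFrame(index=list(self.genes)),
        )
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData, time_label: float = 0.0) -> "CountMatrix":
        x = adata.X
        x = np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)
        return cls(tuple(adata.obs_names), tuple(adata.var_names), x, time_label)

    @classmethod
    def from_csv(cls, path, time_label: float = 0.0,
                 orientation: str = "genes_by_cells") -> "CountMatrix":
        """Read a delimited count table.

        ``genes_by_cells`` (the default): first column gene symbols,
        remaining columns cells.  ``cells_by_genes``: transposed layout.
        """
        df = pd.read_csv(path, index_col=0)
        if orientation == "genes_by_cells":
            df = df.T
        elif orientation != "cells_by_genes":
            raise ValueError(f"unknown orientation {orientation!r}")
        return cls(tuple(df.index.astype(str)), tuple(df.columns.astype(str)),
                   df.to_numpy(dtype=float), time_label)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts.T, index=self.genes, columns=self.cells).to_csv(path)


@dataclass(frozen=True)
class QCMetrics:
    """Per-cell quality-control metrics (reported, never used to filter)."""

    cells: tuple
    total_counts: np.ndarray
    n_genes_detected: np.ndarray
    mito_fraction: np.ndarray
    ribo_fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell": list(self.cells),
            "total_counts": self.total_counts,
            "n_genes_detected": self.n_genes_detected,
            "mito_fraction": self.mito_fraction,
            "ribo_fraction": self.ribo_fraction,
        })


@dataclass(frozen=True)
class TimeSeriesDataset:
    """Normalized per-gene time course with effective standard errors.

    ``table`` has one row per (gene, time_days) with columns mean,
    se_eff, n_cells.  Means are in [0,1]; for every gene with any
    positive value the maximum pre-averaging normalized value is 1 at
    some time point.  ``missing`` records (gene, time) groups that were
    requested but absent from the data: the fit skips those residuals
    rather than imputing zeros.
    """

    table: pd.DataFrame
    n_eff: float
    missing: tuple = ()

    @property
    def genes(self) -> list:
        return sorted(self.table["gene"].unique())

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.table["time_days"].unique())

    @property
    def n_records(self) -> int:
        return len(self.table)

    def gene_series(self, gene: str) -> pd.DataFrame:
        return (self.table[self.table["gene"] == gene]
                .sort_values("time_days").reset_index(drop=True))

    def initial_state(self, genes=None) -> np.ndarray:
        """Observed means at the earliest time point (fit initial condition)."""
        genes = list(genes) if genes is not None else self.genes
        t0 = self.table["time_days"].min()
        first = self.table[self.table["time_days"] == t0].set_index("gene")["mean"]
        return np.array([float(first.get(g, 0.0)) for g in genes])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_eff: float = 15.0) -> "TimeSeriesDataset":
        table = pd.read_csv(path)
        required = {"gene", "time_days", "mean", "se_eff"}
        if not required.issubset(table.columns):
            raise ValueError(f"dataset CSV must have columns {sorted(required)}")
        if "n_cells" not in table.columns:
            table["n_cells"] = np.nan
        return cls(table=table, n_eff=n_eff)


def filter_cells_genes(counts: CountMatrix, min_genes_per_cell: int = 200,
                       min_cells_per_gene: int = 3) -> CountMatrix:
    """Drop low-coverage cells, then rarely expressed genes.

    Cells are filtered before genes (gene prevalence is evaluated on the
    retained cells only); reversing the order gives different results.
    """
    adata = counts.to_anndata()
    if adata.n_obs:
        sc.pp.filter_cells(adata, min_genes=min_genes_per_cell)
    if adata.n_obs and adata.n_vars:
        sc.pp.filter_genes(adata, min_cells=min_cells_per_gene)
    else:
        adata = adata[:, []] if adata.n_obs == 0 else adata
    if adata.n_obs == 0 or adata.n_vars == 0:
        warnings.warn("filtering removed all cells or all genes")
    adata.obs = pd.DataFrame(index=adata.obs_names)
    adata.var = pd.DataFrame(index=adata.var_names)
    return CountMatrix.from_anndata(adata, counts.time_label)


def compute_qc(counts: CountMatrix, mt_prefix: str = "MT-",
               ribo_prefixes=("RPS", "RPL")) -> QCMetrics:
    """Per-cell totals, detected-gene counts and MT / RPS+RPL fractions."""
    x = counts.counts
    totals = x.sum(axis=1)
    detected = (x > 0).sum(axis=1)
    genes = np.array(counts.genes)
    is_mt = np.char.startswith(genes.astype(str), mt_prefix)
    is_ribo = np.zeros(len(genes), dtype=bool)
    for p in ribo_prefixes:
        is_ribo |= np.char.startswith(genes.astype(str), p)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito = np.where(totals > 0, x[:, is_mt].sum(axis=1) / np.maximum(totals, 1e-300), 0.0)
        ribo = np.where(totals > 0, x[:, is_ribo].sum(axis=1) / np.maximum(totals, 1e-300), 0.0)
    return QCMetrics(counts.cells, totals, detected.astype(int), mito, ribo)


def library_normalize(counts: CountMatrix, target_sum: float = 30000.0) -> CountMatrix:
    """Scale each cell to a fixed library size; all-zero cells stay zero."""
    totals = counts.counts.sum(axis=1)
    if np.any(totals == 0):
        warnings.warn(f"{int((totals == 0).sum())} all-zero cells left unscaled")
    adata = counts.to_anndata()
    if adata.n_obs and adata.n_vars:
        sc.pp.normalize_total(adata, target_sum=target_sum)
    return CountMatrix.from_anndata(adata, counts.time_label)


def drop_zero_rows(counts: CountMatrix) -> CountMatrix:
    """Remove genes whose row is entirely zero across all cells."""
    keep = np.any(counts.counts > 0, axis=0)
    return CountMatrix(counts.cells,
                       tuple(g for g, k in zip(counts.genes, keep) if k),
                       counts.counts[:, keep], counts.time_label)


def summarize_timeseries(per_timepoint_values: dict, gene_list,
                         n_eff: float = 15.0, n_eff_per_group: bool = False,
                         se_floor: float = 1e-6) -> TimeSeriesDataset:
    """Build the normalized (mean, SE_eff) time-series table.

    ``per_timepoint_values`` maps time (days) to {gene: array of per-cell
    normalized expression values}.  Per gene: non-finite entries and
    negative values are dropped (zeros retained), values are log1p
    transformed and divided by the gene's maximum log1p value over all
    time points, then averaged per time point.  SE_eff = SD / sqrt(n_eff)
    with SD the sample standard deviation (ddof=1); a single-value group
    gets SD = 0 with a warning.  Zero SEs are floored at ``se_floor`` so
    chi-square weights stay finite.  With ``n_eff_per_group`` the divisor
    is min(n_cells, n_eff) instead of the flat n_eff.
    """
    gene_list = list(dict.fromkeys(gene_list))
    times = sorted(per_timepoint_values)
    cleaned = {}  # (gene, t) -> log1p values
    missing = []
    for g in gene_list:
        for t in times:
            vals = per_timepoint_values[t].get(g)
            if vals is None:
                missing.append((g, t))
                continue
            v = np.asarray(vals, dtype=float)
            v = v[np.isfinite(v)]
            v = v[v >= 0]
            if v.size == 0:
                missing.append((g, t))
                continue
            cleaned[(g, t)] = np.log1p(v)

    rows = []
    single_groups = 0
    for g in gene_list:
        groups = {t: cleaned[(g, t)] for t in times if (g, t) in cleaned}
        if not groups:
            continue
        gmax = max(v.max() for v in groups.values())
        for t, v in groups.items():
            norm = v / gmax if gmax > 0 else np.zeros_like(v)
            if v.size == 1:
                sd = 0.0
                single_groups += 1
            else:
                sd = float(np.std(norm, ddof=1))
            divisor = min(v.size, n_eff) if n_eff_per_group else n_eff
            se = max(sd / np.sqrt(divisor), se_floor)
            rows.append((g, float(t), float(np.mean(norm)), se, int(v.size)))
    if single_groups:
        warnings.warn(f"{single_groups} (gene, time) groups had a single value; "
                      "their SD was set to 0 (then floored)")
    table = pd.DataFrame(rows, columns=["gene", "time_days", "mean", "se_eff",
                                        "n_cells"])
    return TimeSeriesDataset(table=table, n_eff=n_eff, missing=tuple(missing))


def preprocess_counts(count_matrices, gene_list, min_genes_per_cell: int = 200,
                      min_cells_per_gene: int = 3, target_sum: float = 30000.0,
                      n_eff: float = 15.0) -> TimeSeriesDataset:
    """Full chain: filter -> library-normalize -> drop zero rows -> summarize."""
    per_tp = {}
    for cm in count_matrices:
        cm = filter_cells_genes(cm, min_genes_per_cell, min_cells_per_gene)
        cm = library_normalize(cm, target_sum)
        cm = drop_zero_rows(cm)
        gidx = {g: i for i, g in enumerate(cm.genes)}
        per_tp[cm.time_label] = {
            g: cm.counts[:, gidx[g]] for g in gene_list if g in gidx}
    return summarize_timeseries(per_tp, gene_list, n_eff=n_eff)
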