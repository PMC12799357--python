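"""Cell quality control and library-size normalization.

QC follows robust outlier filtering as practiced in droplet scRNA-seq: an
absolute floor on total UMIs, MAD-based outlier cuts on log1p totals and
log1p detected-gene counts (two-sided), and a mitochondrial-content rule
combining an absolute ceiling with a one-sided MAD cut (low mitochondrial
content is not a quality defect).  MADs are unscaled (no 1.4826 factor) and
computed on the full input population.

Normalization scales every kept cell to a common target sum and applies
natural log1p, stored as a layer so raw counts stay untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc

__all__ = ["QCThresholds", "compute_qc_metrics", "filter_cells", "normalize_log"]


@dataclass(frozen=True)
class QCThresholds:
    min_total_umi: float = 500.0
    total_nmads: float = 5.0
    genes_nmads: float = 5.0
    mito_max_pct: float = 15.0
    mito_nmads: float = 4.0

    def validate(self) -> None:
        for name in ("min_total_umi", "total_nmads", "genes_nmads", "mito_max_pct", "mito_nmads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"QC threshold {name} must be positive")


def compute_qc_metrics(
    adata: ad.AnnData,
    mito_genes: Iterable[str] | None = None,
    mito_prefix: str = "MT-",
) -> pd.DataFrame:
    """Per-cell total UMIs, detected genes and mitochondrial percentage.

    Mitochondrial genes come from an explicit id list or, by default, a name
    prefix. Metrics are computed from raw counts only.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty matrix: no cells or no genes")
    if mito_genes is not None:
        mito_genes = list(mito_genes)
        missing = set(mito_genes) - set(adata.var_names)
        if missing:
            warnings.warn(f"{len(missing)} mitochondrial gene ids not in matrix: {sorted(missing)[:5]}")
        mask = adata.var_names.isin(mito_genes)
    else:
        mask = adata.var_names.str.startswith(mito_prefix)
    tmp = adata.copy()
    tmp.var["mt"] = np.asarray(mask)
    sc.pp.calculate_qc_metrics(tmp, qc_vars=["mt"], percent_top=None, log1p=False, inplace=True)
    qc = pd.DataFrame(
        {
            "total_counts": tmp.obs["total_counts"].to_numpy(),
            "n_genes": tmp.obs["n_genes_by_counts"].to_numpy(),
            "pct_mito": np.nan_to_num(tmp.obs["pct_counts_mt"].to_numpy()),  # zero-total cells
        },
        index=adata.obs_names,
    )
    return qc


def _mad_bounds(values: np.ndarray, nmads: float, two_sided: bool) -> np.ndarray:
    """Boolean pass-mask for a MAD rule; all-True (with warning) when MAD is 0."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        warnings.warn("MAD is zero for a QC metric; falling back to absolute criteria only")
        return np.ones(len(values), dtype=bool)
    dev = values - med
    if two_sided:
        return np.abs(dev) <= nmads * mad
    return dev <= nmads * mad


def filter_cells(qc: pd.DataFrame, thr: QCThresholds = QCThresholds()) -> pd.Series:
    """Boolean keep-mask over cells.

    A cell is kept iff it passes the absolute total-UMI floor, two-sided MAD
    rules on log1p(total) and log1p(detected genes), the absolute mitochondrial
    ceiling, and a one-sided (high) MAD rule on mitochondrial percentage.
    MADs are computed on the full input population.
    """
    thr.validate()
    if len(qc) == 0:
        raise ValueError("QC metrics table is empty")
    total = qc["total_counts"].to_numpy(dtype=float)
    ngenes = qc["n_genes"].to_numpy(dtype=float)
    mito = qc["pct_mito"].to_numpy(dtype=float)

    keep = total >= thr.min_total_umi
    keep &= _mad_bounds(np.log1p(total), thr.total_nmads, two_sided=True)
    keep &= _mad_bounds(np.log1p(ngenes), thr.genes_nmads, two_sided=True)
    keep &= mito <= thr.mito_max_pct
    keep &= _mad_bounds(mito, thr.mito_nmads, two_sided=False)
    return pd.Series(keep, index=qc.index, name="keep")


def normalize_log(
    adata: ad.AnnData, target_sum: float = 10_000.0, layer: str = "lognorm"
) -> ad.AnnData:
    """Scale each cell to ``target_sum`` counts and log1p, into ``adata.layers[layer]``.

    Raw counts in ``X`` are retained unchanged. Cells with zero total counts are
    rejected (they cannot be scaled); filter first.
    """
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = adata.obs_names[np.where(totals == 0)[0][0]]
        raise ValueError(f"cell {bad!r} has zero total counts; remove it before normalizing")
    adata.layers[layer] = adata.X.astype(np.float64).copy()
    sc.pp.normalize_total(adata, target_sum=target_sum, layer=layer)
    sc.pp.log1p(adata, layer=layer)
    return adata
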