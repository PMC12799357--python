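"""Donor-level T-cell composition, immunological indices and correlation scans.

Proportions of the Th / Tc / Treg subsets are computed under two denominator
conventions: relative to the total T-lymphocyte pool (balance within the
T compartment) and relative to all cells of the donor (representation within
the whole tissue landscape).  The classical immunological indices Th/Tc,
Treg/Tc and Treg/Th summarize subset balance; they are flagged undefined
(NaN) when their denominator count is zero rather than coerced to a number.

Donor-level association analyses use Spearman rank correlation with a
Bonferroni family-wise correction per scan, after excluding, per cell type,
donors whose cell count falls more than two population standard deviations
below the cohort mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

T_SUBSETS = ("Th", "Tc", "Treg")

__all__ = [
    "T_SUBSETS",
    "CorrelationResult",
    "exclude_low_count_samples",
    "subset_proportions",
    "spearman",
    "bonferroni",
    "correlation_scan",
    "scan_fractions_vs_age",
    "scan_tprops_vs_age",
    "scan_tprops_vs_burden",
]


@dataclass
class CorrelationResult:
    family: str
    x: str
    y: str
    n: int
    rho: float
    p: float
    p_adj: float
    m: int
    excluded: tuple[str, ...] = ()
    note: str = ""


def exclude_low_count_samples(counts: pd.Series, n_sd: float = 2.0) -> tuple[pd.Index, pd.Index]:
    """Split donors into (included, excluded) by the low-count rule.

    A donor is excluded iff its cell count is below mean - n_sd * SD, with the
    population (ddof=0) standard deviation taken across all donors.  When the
    SD is zero no donor is excluded.
    """
    if len(counts) < 3:
        raise ValueError(f"need at least 3 donors for the exclusion rule, got {len(counts)}")
    values = counts.to_numpy(dtype=float)
    sd = values.std(ddof=0)
    if sd == 0:
        return counts.index, counts.index[:0]
    cutoff = values.mean() - n_sd * sd
    excl = counts.index[values < cutoff]
    return counts.index.difference(excl, sort=False), excl


def subset_proportions(
    metadata: pd.DataFrame,
    calls: pd.DataFrame | None = None,
    t_subset_labels: tuple[str, ...] = T_SUBSETS,
    extra_t_labels: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-donor composition table.

    ``metadata`` is per-cell (indexed by barcode) with donor_id, age_years and
    cell_type columns; ``calls`` (optional) is a calls table as produced by
    :func:`senskin.senescence.calls_frame` and adds pooled and per-cell-type
    senescent fractions.  T cells are the union of ``t_subset_labels`` and
    ``extra_t_labels``.  Indices with a zero denominator are NaN.
    """
    t_labels = tuple(t_subset_labels) + tuple(extra_t_labels)
    donors = metadata.groupby("donor_id", observed=True)
    out = pd.DataFrame(
        {
            "age_years": donors["age_years"].first(),
            "n_cells": donors.size(),
        }
    )
    type_counts = (
        metadata.groupby(["donor_id", "cell_type"], observed=True)
        .size()
        .unstack("cell_type", fill_value=0)
    )
    for s in t_subset_labels:
        out[f"n_{s}"] = type_counts.get(s, pd.Series(0, index=out.index))
    out["n_T"] = sum(type_counts.get(lbl, pd.Series(0, index=out.index)) for lbl in t_labels)
    zero_t = out["n_T"] == 0
    if zero_t.any():
        warnings.warn(
            f"{int(zero_t.sum())} donor(s) have zero T cells; their total-T proportions "
            "and indices are undefined"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        for s in t_subset_labels:
            out[f"prop_{s}_of_T"] = np.where(out["n_T"] > 0, out[f"n_{s}"] / out["n_T"], np.nan)
            out[f"prop_{s}_of_all"] = out[f"n_{s}"] / out["n_cells"]
        out["prop_T_of_all"] = out["n_T"] / out["n_cells"]
        out["idx_Th_Tc"] = np.where(out["n_Tc"] > 0, out["n_Th"] / out["n_Tc"], np.nan)
        out["idx_Treg_Tc"] = np.where(out["n_Tc"] > 0, out["n_Treg"] / out["n_Tc"], np.nan)
        out["idx_Treg_Th"] = np.where(out["n_Th"] > 0, out["n_Treg"] / out["n_Th"], np.nan)

    if calls is not None:
        from .senescence import senescent_fractions

        per_group, pooled = senescent_fractions(calls, metadata)
        out["sen_frac_pooled"] = pooled
        for ct in per_group.columns:
            out[f"sen_frac_{ct}"] = per_group[ct]
    return out


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value (n-2 df).

    Ties get average ranks.  Zero variance in either vector gives (nan, nan)
    with a warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 4:
        raise ValueError(f"need n >= 4 for a correlation, got n={len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in a correlation input; rho undefined")
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Family-wise adjustment: p -> min(1, m * p), m defaulting to the family size."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


def correlation_scan(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    family: str,
    exclusions: dict[tuple[str, str], pd.Index] | None = None,
    min_n: int = 4,
) -> pd.DataFrame:
    """Spearman correlations for each (x, y) column pair with per-scan Bonferroni.

    ``exclusions`` maps a pair to the donor index to *keep* for that pair
    (e.g. after the low-count rule).  Pairs left with fewer than ``min_n``
    donors, or with zero variance, are reported flagged, not dropped; the
    Bonferroni family size m is the number of pairs in the scan.
    """
    m = len(pairs)
    results: list[CorrelationResult] = []
    for x, y in pairs:
        sub = table
        excluded: tuple[str, ...] = ()
        if exclusions is not None and (x, y) in exclusions:
            keep = exclusions[(x, y)]
            excluded = tuple(str(d) for d in table.index.difference(keep, sort=False))
            sub = table.loc[table.index.intersection(keep, sort=False)]
        sub = sub[[x, y]].dropna()
        if len(sub) < min_n:
            results.append(
                CorrelationResult(family, x, y, len(sub), float("nan"), float("nan"),
                                  float("nan"), m, excluded, "insufficient_n")
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = spearman(sub[x], sub[y])
        if np.isnan(rho):
            results.append(
                CorrelationResult(family, x, y, len(sub), rho, p, float("nan"), m,
                                  excluded, "undefined")
            )
            continue
        p_adj = float(bonferroni([p], m=m)[0])
        results.append(CorrelationResult(family, x, y, len(sub), rho, p, p_adj, m, excluded))
    return pd.DataFrame([r.__dict__ for r in results])


def _per_type_exclusions(
    metadata: pd.DataFrame, cell_types: list[str]
) -> dict[str, pd.Index]:
    counts = (
        metadata.groupby(["donor_id", "cell_type"], observed=True)
        .size()
        .unstack("cell_type", fill_value=0)
    )
    keep: dict[str, pd.Index] = {}
    for ct in cell_types:
        if ct in counts.columns:
            keep[ct], _ = exclude_low_count_samples(counts[ct])
    return keep


def scan_fractions_vs_age(comp: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Senescent fraction vs age, per cell type (with low-count exclusion) and pooled."""
    sen_cols = [c for c in comp.columns if c.startswith("sen_frac_") and c != "sen_frac_pooled"]
    cell_types = [c.removeprefix("sen_frac_") for c in sen_cols]
    keep = _per_type_exclusions(metadata, cell_types)
    pairs = [("age_years", c) for c in sen_cols] + [("age_years", "sen_frac_pooled")]
    exclusions = {
        ("age_years", f"sen_frac_{ct}"): keep[ct] for ct in cell_types if ct in keep
    }
    return correlation_scan(comp, pairs, family="fractions_vs_age", exclusions=exclusions)


def scan_tprops_vs_age(comp: pd.DataFrame) -> pd.DataFrame:
    """T subset shares of the T pool and immunological indices vs donor age."""
    pairs = [("age_years", f"prop_{s}_of_T") for s in T_SUBSETS]
    pairs += [("age_years", c) for c in ("idx_Th_Tc", "idx_Treg_Tc", "idx_Treg_Th")]
    return correlation_scan(comp, pairs, family="tprops_vs_age")


def scan_tprops_vs_burden(comp: pd.DataFrame) -> pd.DataFrame:
    """T subset shares of all cells (and indices) vs the pooled senescent fraction."""
    pairs = [("sen_frac_pooled", f"prop_{s}_of_all") for s in T_SUBSETS]
    pairs += [("sen_frac_pooled", "prop_T_of_all")]
    pairs += [("sen_frac_pooled", c) for c in ("idx_Th_Tc", "idx_Treg_Tc", "idx_Treg_Th")]
    return correlation_scan(comp, pairs, family="tprops_vs_burden")
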