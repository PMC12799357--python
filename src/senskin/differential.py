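"""Old-vs-young differential expression per T subset and gene-set over-representation.

Per gene, a two-sided Mann-Whitney U test compares log-normalized expression
between cells of old and young donors.  A gene passes for a target group when
its BH false-discovery rate is below ``fdr_max``, it is detected (raw count
> 0) in more than ``min_frac_target`` of the target group's cells, and in
fewer than ``max_frac_other`` of the comparison group's cells; the test is
run with each group in turn as target, so up- and down-regulated genes are
reported symmetrically.

Over-representation of a query gene list in user-supplied gene sets (GMT
format) is assessed with a one-sided upper-tail hypergeometric test against
a stated gene universe, BH-adjusted across the tested sets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEGCriteria",
    "mannwhitney_u",
    "bh_fdr",
    "find_degs",
    "degs_passing",
    "read_gmt",
    "ora_hypergeometric",
]


@dataclass(frozen=True)
class DEGCriteria:
    fdr_max: float = 0.01
    min_frac_target: float = 0.10
    max_frac_other: float = 0.50
    young_max_age: float = 30.0
    old_min_age: float = 55.0

    def validate(self) -> None:
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must be in (0, 1)")
        for name in ("min_frac_target", "max_frac_other"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.young_max_age >= self.old_min_age:
            raise ValueError("young_max_age must be < old_min_age")


def mannwhitney_u(
    values_a, values_b, method: str = "auto", exact_max_n: int = 12
) -> tuple[float, float]:
    """Mann-Whitney U (for group a) with a two-sided p-value.

    Midranks handle ties.  ``method='exact'`` (or 'auto' with
    n_a + n_b <= ``exact_max_n``) enumerates every assignment of the pooled
    sample into the two groups and reports P(|U - n_a n_b / 2| >= observed);
    otherwise the normal approximation with tie and continuity corrections
    is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    use_exact = method == "exact" or (method == "auto" and a.size + b.size <= exact_max_n)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n_b = a.size, b.size
    u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
    if use_exact:
        mu = n_a * n_b / 2
        dev_obs = abs(u_obs - mu)
        total = 0
        hits = 0
        idx = range(n_a + n_b)
        for combo in itertools.combinations(idx, n_a):
            u = float(ranks[list(combo)].sum() - n_a * (n_a + 1) / 2)
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def find_degs(
    adata: ad.AnnData,
    subset: str,
    criteria: DEGCriteria = DEGCriteria(),
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Per-gene old-vs-young Mann-Whitney table for one cell subset.

    Returns one row per gene with the U statistic (old as group a), raw and
    BH-adjusted p, expressing fractions (raw counts > 0) in the old and young
    groups, the direction of higher mean log-normalized expression, and pass
    flags for old and young as target group.
    """
    criteria.validate()
    mask = (adata.obs["cell_type"] == subset).to_numpy()
    age = adata.obs["age_years"].to_numpy(dtype=float)
    old = mask & (age >= criteria.old_min_age)
    young = mask & (age <= criteria.young_max_age)
    if old.sum() == 0:
        raise ValueError(f"no {subset!r} cells in the old group (age >= {criteria.old_min_age})")
    if young.sum() == 0:
        raise ValueError(f"no {subset!r} cells in the young group (age <= {criteria.young_max_age})")

    def dense(layer_mat):
        return layer_mat.toarray() if hasattr(layer_mat, "toarray") else np.asarray(layer_mat)

    x_old = dense(adata.layers[layer][old]).astype(float)
    x_young = dense(adata.layers[layer][young]).astype(float)
    frac_old = np.asarray((adata.X[old] > 0).mean(axis=0)).ravel()
    frac_young = np.asarray((adata.X[young] > 0).mean(axis=0)).ravel()

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes give a harmless tie warning
        res = stats.mannwhitneyu(x_old, x_young, alternative="two-sided",
                                 method="asymptotic", use_continuity=True, axis=0)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    q = bh_fdr(p)
    up_in_old = x_old.mean(axis=0) > x_young.mean(axis=0)
    sig = q < criteria.fdr_max
    pass_old = sig & up_in_old & (frac_old > criteria.min_frac_target) & (
        frac_young < criteria.max_frac_other
    )
    pass_young = sig & ~up_in_old & (frac_young > criteria.min_frac_target) & (
        frac_old < criteria.max_frac_other
    )
    return pd.DataFrame(
        {
            "gene": adata.var_names,
            "subset": subset,
            "U": res.statistic,
            "p": p,
            "fdr": q,
            "frac_old": frac_old,
            "frac_young": frac_young,
            "direction": np.where(up_in_old, "up_in_old", "up_in_young"),
            "pass_old_target": pass_old,
            "pass_young_target": pass_young,
        }
    ).reset_index(drop=True)


def degs_passing(table: pd.DataFrame, target: str = "old") -> list[str]:
    """Gene ids passing all criteria with the given group as target."""
    col = {"old": "pass_old_target", "young": "pass_young_target"}[target]
    return table.loc[table[col], "gene"].tolist()


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, tab-separated name, description, genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
    return path


def ora_hypergeometric(
    query_genes,
    universe,
    gene_sets: dict[str, list[str]],
    min_size: int = 10,
    max_size: int = 500,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query_genes`` in each set.

    Sets are intersected with the universe first; sets outside
    [min_size, max_size] after intersection are dropped.  p = P(X >= k) for
    overlap k, set size K, query size n, universe size N; BH across tested sets.
    """
    universe = set(universe)
    query = set(query_genes)
    if not query or not universe:
        raise ValueError("query and universe must be nonempty")
    stray = query - universe
    if stray:
        raise ValueError(f"{len(stray)} query genes are not in the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, genes in gene_sets.items():
        members = set(genes) & universe
        K = len(members)
        if not min_size <= K <= max_size:
            continue
        overlap = sorted(query & members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, p, ";".join(overlap)))
    table = pd.DataFrame(
        rows, columns=["gene_set", "k", "K", "n", "N", "p", "overlap_genes"]
    )
    if len(table):
        table["p_adj"] = bh_fdr(table["p"].to_numpy())
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return table.sort_values("p", kind="stable").reset_index(drop=True)
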