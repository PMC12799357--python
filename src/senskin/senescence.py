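"""Cell-type-specific senescence signatures, per-cell scoring and mixture-based calling.

The signature for a cell type is the set of genes that are nearly silent in
cells from young donors yet detected in a small-to-moderate fraction of cells
from old donors — the expression pattern expected of a program confined to
senescent cells that accumulate with age.  A gene is included when, over cells
of the cell type pooled within the young and old donor groups:

    p_young < young_max_frac
    old_min_frac < p_old < old_max_frac
    p_old >= min_fold * p_young   or   p_old - p_young > min_abs_diff

where p_* is the expressing fraction (raw count > 0).  Defaults: 5 % young
ceiling, 1-20 % old band, 2.5-fold ratio or > 5-point absolute rise.

Each cell is then scored as the mean, over signature genes, of the per-gene
z-scored log-normalized expression within the scored population.  A 1-D
Gaussian mixture (2 or 3 components, chosen by BIC) is fitted to the score
distribution of each cell type, and the senescent/normal decision boundary is
the point between the two rightmost component means where their weighted
densities are equal; cells scoring strictly above it are called senescent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "SignatureCriteria",
    "SenescenceSignature",
    "GMMFit",
    "SenescenceCallSet",
    "derive_signature",
    "score_cells",
    "fit_score_mixture",
    "senescence_threshold",
    "call_senescent",
    "calls_frame",
    "senescent_fractions",
    "run_senescence",
]


@dataclass(frozen=True)
class SignatureCriteria:
    young_max_frac: float = 0.05
    old_min_frac: float = 0.01
    old_max_frac: float = 0.20
    min_fold: float = 2.5
    min_abs_diff: float = 0.05
    young_max_age: float = 30.0
    old_min_age: float = 55.0

    def validate(self) -> None:
        if not 0 <= self.young_max_frac < 1:
            raise ValueError("young_max_frac must be in [0, 1)")
        if not self.old_min_frac < self.old_max_frac:
            raise ValueError("old_min_frac must be < old_max_frac")
        if self.min_fold <= 1:
            raise ValueError("min_fold must be > 1")
        if self.min_abs_diff <= 0:
            raise ValueError("min_abs_diff must be > 0")
        if self.young_max_age >= self.old_min_age:
            raise ValueError("young_max_age must be < old_min_age")


@dataclass
class SenescenceSignature:
    cell_type: str
    table: pd.DataFrame  # gene, p_young, p_old, fold, abs_diff, included

    @property
    def genes(self) -> list[str]:
        return self.table.loc[self.table["included"], "gene"].tolist()

    def __len__(self) -> int:
        return int(self.table["included"].sum())


@dataclass
class GMMFit:
    k: int
    weights: np.ndarray  # sorted by component mean, ascending
    means: np.ndarray
    variances: np.ndarray
    bic: dict[int, float]
    converged: bool
    seed: int


@dataclass
class SenescenceCallSet:
    cell_type: str
    scores: pd.Series
    threshold: float
    senescent: pd.Series  # bool, same index as scores
    fit: GMMFit | None = None

    @property
    def fraction(self) -> float:
        return float(self.senescent.mean())


def signature_included(
    p_young: np.ndarray, p_old: np.ndarray, criteria: SignatureCriteria
) -> np.ndarray:
    """Vectorized inclusion rule; the fold criterion holds trivially when p_young is 0."""
    p_young = np.asarray(p_young, dtype=float)
    p_old = np.asarray(p_old, dtype=float)
    young_ok = p_young < criteria.young_max_frac
    band_ok = (p_old > criteria.old_min_frac) & (p_old < criteria.old_max_frac)
    effect_ok = (p_old >= criteria.min_fold * p_young) | (
        p_old - p_young > criteria.min_abs_diff
    )
    return young_ok & band_ok & effect_ok


def expressing_fraction(adata: ad.AnnData, mask: np.ndarray) -> np.ndarray:
    """Fraction of cells in ``mask`` with raw count > 0, per gene."""
    sub = adata.X[mask]
    return np.asarray((sub > 0).sum(axis=0)).ravel() / sub.shape[0]


def derive_signature(
    adata: ad.AnnData,
    cell_type: str,
    criteria: SignatureCriteria = SignatureCriteria(),
) -> SenescenceSignature:
    """Derive the senescence signature of ``cell_type`` from young/old expressing fractions.

    Fractions are pooled over cells of the cell type within each donor age
    group (young: age <= young_max_age; old: age >= old_min_age).
    """
    criteria.validate()
    ct_mask = (adata.obs["cell_type"] == cell_type).to_numpy()
    age = adata.obs["age_years"].to_numpy(dtype=float)
    young = ct_mask & (age <= criteria.young_max_age)
    old = ct_mask & (age >= criteria.old_min_age)
    if young.sum() == 0:
        raise ValueError(f"no {cell_type!r} cells from young donors (age <= {criteria.young_max_age})")
    if old.sum() == 0:
        raise ValueError(f"no {cell_type!r} cells from old donors (age >= {criteria.old_min_age})")
    p_y = expressing_fraction(adata, young)
    p_o = expressing_fraction(adata, old)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(p_y > 0, p_o / p_y, np.inf)
    included = signature_included(p_y, p_o, criteria)
    table = pd.DataFrame(
        {
            "gene": adata.var_names,
            "cell_type": cell_type,
            "p_young": p_y,
            "p_old": p_o,
            "fold": fold,
            "abs_diff": p_o - p_y,
            "included": included,
        }
    ).reset_index(drop=True)
    if not included.any():
        warnings.warn(f"empty senescence signature for cell type {cell_type!r}")
    return SenescenceSignature(cell_type=cell_type, table=table)


def score_cells(
    adata: ad.AnnData, signature: SenescenceSignature, layer: str = "lognorm"
) -> pd.Series:
    """Mean per-gene z-scored log-normalized expression over signature genes.

    z-scores are computed within the scored population (cells of the
    signature's cell type); genes absent from the matrix or with zero variance
    in the population are dropped with a warning.
    """
    genes = signature.genes
    if not genes:
        raise ValueError(f"signature for {signature.cell_type!r} is empty")
    present = [g for g in genes if g in adata.var_names]
    if not present:
        raise ValueError(f"no signature gene of {signature.cell_type!r} found in the matrix")
    if len(present) < len(genes):
        warnings.warn(f"{len(genes) - len(present)} signature genes absent from matrix; dropped")
    mask = (adata.obs["cell_type"] == signature.cell_type).to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"no cells of type {signature.cell_type!r}")
    sub = adata[mask, present]
    L = sub.layers[layer]
    expr = L.toarray().astype(float) if hasattr(L, "toarray") else np.asarray(L, dtype=float)
    mu = expr.mean(axis=0)
    sd = expr.std(axis=0)
    usable = sd > 0
    if not usable.any():
        raise ValueError("all signature genes have zero variance in the scored population")
    if not usable.all():
        warnings.warn(f"{int((~usable).sum())} signature genes with zero variance; dropped")
    z = (expr[:, usable] - mu[usable]) / sd[usable]
    return pd.Series(z.mean(axis=1), index=adata.obs_names[mask], name="score")


def fit_score_mixture(
    scores: np.ndarray | pd.Series,
    k_candidates: tuple[int, ...] = (2, 3),
    seed: int = 0,
    n_init: int = 10,
    min_scores: int = 50,
) -> GMMFit:
    """Fit 1-D Gaussian mixtures for each candidate K; keep the lowest BIC.

    EM is restarted ``n_init`` times from seeded k-means++ initializations.
    """
    x = np.asarray(scores, dtype=float).reshape(-1, 1)
    if len(x) < min_scores:
        raise ValueError(f"need at least {min_scores} scores to fit a mixture, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate score distribution: all scores identical")
    fits: dict[int, GaussianMixture] = {}
    bics: dict[int, float] = {}
    for k in k_candidates:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            init_params="k-means++",
            random_state=seed,
            max_iter=500,
        ).fit(x)
        fits[k] = gm
        bics[k] = float(gm.bic(x))
    converged = {k: gm.converged_ for k, gm in fits.items()}
    if not any(converged.values()):
        raise RuntimeError(f"EM failed to converge for all K in {k_candidates}; BICs: {bics}")
    best_k = min((k for k in fits if converged[k]), key=lambda k: bics[k])
    gm = fits[best_k]
    means = gm.means_.ravel()
    order = np.argsort(means)
    return GMMFit(
        k=best_k,
        weights=gm.weights_[order],
        means=means[order],
        variances=gm.covariances_.reshape(-1)[order],
        bic=bics,
        converged=True,
        seed=seed,
    )


def senescence_threshold(fit: GMMFit) -> float:
    """Decision boundary between the two rightmost mixture components.

    The threshold is the point in the open interval between the two rightmost
    component means where the weighted component densities are equal; if the
    densities do not cross inside the interval, the midpoint is used.
    """
    if fit.k < 2:
        raise ValueError("threshold requires a mixture with at least 2 components")
    w1, w2 = fit.weights[-2:]
    m1, m2 = fit.means[-2:]
    v1, v2 = fit.variances[-2:]

    def g(x: float) -> float:
        return np.log(w1) + stats.norm.logpdf(x, m1, np.sqrt(v1)) - (
            np.log(w2) + stats.norm.logpdf(x, m2, np.sqrt(v2))
        )

    eps = 1e-9 * max(1.0, abs(m2 - m1))
    lo, hi = m1 + eps, m2 - eps
    if lo >= hi or g(lo) * g(hi) > 0:
        warnings.warn("weighted densities do not cross between the two rightmost means; using midpoint")
        return float(0.5 * (m1 + m2))
    return float(optimize.brentq(g, lo, hi, xtol=1e-12))


def call_senescent(
    scores: pd.Series, threshold: float, cell_type: str = "", fit: GMMFit | None = None
) -> SenescenceCallSet:
    """Binary call: a cell is senescent iff its score is strictly above the threshold."""
    calls = scores > threshold
    return SenescenceCallSet(
        cell_type=cell_type,
        scores=scores,
        threshold=float(threshold),
        senescent=calls.rename("senescent"),
        fit=fit,
    )


def calls_frame(callsets: list[SenescenceCallSet]) -> pd.DataFrame:
    """Stack call sets into one table: barcode, cell_type, score, threshold, senescent."""
    rows = []
    for cs in callsets:
        rows.append(
            pd.DataFrame(
                {
                    "barcode": cs.scores.index,
                    "cell_type": cs.cell_type,
                    "score": cs.scores.to_numpy(),
                    "threshold": cs.threshold,
                    "senescent": cs.senescent.to_numpy(),
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["barcode", "cell_type", "score", "threshold", "senescent"])
    return pd.concat(rows, ignore_index=True)


def senescent_fractions(
    calls: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per donor x cell type senescent fractions, plus the pooled per-donor fraction.

    The pooled fraction is senescent cells over all scored cells of the donor
    (equivalently the cell-count-weighted mean over cell types).
    """
    joined = calls.merge(
        metadata[["donor_id"]], left_on="barcode", right_index=True, how="left"
    )
    if joined["donor_id"].isna().any():
        raise ValueError("some called barcodes are missing from the metadata")
    per_group = (
        joined.groupby(["donor_id", "cell_type"], observed=True)["senescent"]
        .mean()
        .unstack("cell_type")
    )
    pooled = joined.groupby("donor_id", observed=True)["senescent"].mean().rename("pooled")
    return per_group, pooled


def run_senescence(
    adata: ad.AnnData,
    cell_types: list[str] | None = None,
    criteria: SignatureCriteria = SignatureCriteria(),
    seed: int = 0,
    layer: str = "lognorm",
    min_scores: int = 50,
) -> tuple[list[SenescenceSignature], list[SenescenceCallSet]]:
    """Signature -> score -> mixture -> call, per cell type; skips (with a warning)
    cell types whose signature comes out empty or whose population is too small."""
    if cell_types is None:
        cell_types = sorted(adata.obs["cell_type"].unique())
    signatures: list[SenescenceSignature] = []
    callsets: list[SenescenceCallSet] = []
    for i, ct in enumerate(cell_types):
        sig = derive_signature(adata, ct, criteria)
        signatures.append(sig)
        if len(sig) == 0:
            continue
        scores = score_cells(adata, sig, layer=layer)
        try:
            fit = fit_score_mixture(scores, seed=seed + i, min_scores=min_scores)
        except ValueError as err:
            warnings.warn(f"skipping {ct!r}: {err}")
            continue
        thr = senescence_threshold(fit)
        callsets.append(call_senescent(scores, thr, cell_type=ct, fit=fit))
    return signatures, callsets
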