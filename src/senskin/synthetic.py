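"""Synthetic multi-donor skin scRNA-seq cohorts with known senescence ground truth.

The generator emulates the statistical structure a senescence-calling pipeline
has to cope with in real skin biopsies: a cohort of donors spanning adulthood,
several cell types (including the three classical T-lymphocyte subsets), sparse
over-dispersed UMI counts, and a per-cell-type "senescence program" — a set of
genes that is rarely detected in cells from young donors but switches on in the
senescent cells that accumulate with age.  Optionally, a donor's senescent
burden shifts the Th and Treg share of the T-cell pool on the logit scale, so
composition–burden associations can be planted (or left absent for null
simulations).

Counts follow a negative-binomial model per gene with a per-donor log-normal
size factor standing in for batch/depth effects.  A cell's senescent state is
Bernoulli with probability interpolating linearly in donor age between
``f_young`` and ``f_old``; in senescent cells the program genes of that cell
type are drawn with a boosted mean instead of their background mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

T_SUBSETS = ("Th", "Tc", "Treg")

__all__ = [
    "T_SUBSETS",
    "CellTypeSpec",
    "SenescenceProgram",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "write_tenx_bundle",
    "read_tenx_bundle",
    "default_config",
]


@dataclass(frozen=True)
class CellTypeSpec:
    """A non-T cell population: mean cells per donor and NB dispersion of that count."""

    name: str
    mean_cells: float
    dispersion: float = 0.05


@dataclass(frozen=True)
class SenescenceProgram:
    """Senescence program for one cell type.

    ``f_young``/``f_old`` are the senescent-cell probabilities at the young and
    old ends of the age range.  In senescent cells each program gene's NB mean
    is ``boost_mean``; in all other cells of any type it is ``background_mean``.
    """

    cell_type: str
    n_genes: int = 40
    f_young: float = 0.02
    f_old: float = 0.30
    boost_mean: float = 1.2
    background_mean: float = 0.01


@dataclass
class SimulationConfig:
    n_donors: int = 32
    age_range: tuple[float, float] = (18.0, 76.0)
    cell_types: tuple[CellTypeSpec, ...] = (
        CellTypeSpec("Fibroblast", 120.0),
        CellTypeSpec("KC", 100.0),
        CellTypeSpec("VE", 40.0),
    )
    t_cells_mean: float = 60.0
    t_cells_dispersion: float = 0.05
    t_subset_baselines: dict[str, float] = field(
        default_factory=lambda: {"Th": 0.45, "Tc": 0.40, "Treg": 0.15}
    )
    n_genes: int = 1500
    n_mito_genes: int = 10
    mito_mean: float = 6.0
    baseline_log_mean: float = -0.7
    baseline_log_sd: float = 1.0
    gene_dispersion: float = 0.5
    programs: tuple[SenescenceProgram, ...] = ()
    burden_composition_effect: float = 0.0
    batch_effect_sd: float = 0.15
    age_sampling: str = "even"  # "even" | "uniform"
    ages: Sequence[float] | None = None  # explicit override, wins over age_sampling
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors < 2:
            raise ValueError(f"n_donors must be >= 2, got {self.n_donors}")
        amin, amax = self.age_range
        if not amin < amax:
            raise ValueError(f"age_range min must be < max, got {self.age_range}")
        if self.ages is not None:
            if len(self.ages) != self.n_donors:
                raise ValueError("ages override must have one age per donor")
            for a in self.ages:
                if not amin <= a <= amax:
                    raise ValueError(f"ages entry {a} outside age_range {self.age_range}")
        if self.age_sampling not in ("even", "uniform"):
            raise ValueError(f"age_sampling must be 'even' or 'uniform', got {self.age_sampling!r}")
        if set(self.t_subset_baselines) != set(T_SUBSETS):
            raise ValueError(f"t_subset_baselines must have exactly the keys {T_SUBSETS}")
        props = np.array([self.t_subset_baselines[s] for s in T_SUBSETS], dtype=float)
        if np.any(props < 0) or np.any(props > 1):
            raise ValueError("t_subset_baselines entries must lie in [0, 1]")
        if not np.isclose(props.sum(), 1.0):
            raise ValueError(f"t_subset_baselines must sum to 1, got {props.sum():.4f}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        known = {ct.name for ct in self.cell_types} | set(T_SUBSETS)
        total_program_genes = 0
        for prog in self.programs:
            if prog.cell_type not in known:
                raise ValueError(f"program cell_type {prog.cell_type!r} not among simulated types")
            if not (0.0 <= prog.f_young < prog.f_old <= 1.0):
                raise ValueError(
                    f"program for {prog.cell_type}: need 0 <= f_young < f_old <= 1, "
                    f"got f_young={prog.f_young}, f_old={prog.f_old}"
                )
            total_program_genes += prog.n_genes
        if total_program_genes + self.n_mito_genes > self.n_genes:
            raise ValueError("program genes plus mitochondrial genes exceed n_genes")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be >= 0")

    @property
    def all_cell_type_names(self) -> tuple[str, ...]:
        return tuple(ct.name for ct in self.cell_types) + T_SUBSETS


@dataclass
class GroundTruth:
    """Per-cell and per-donor truth emitted alongside the simulated counts."""

    senescent: pd.Series  # bool, indexed by barcode
    donor_fractions: pd.DataFrame  # donors x cell types, true senescent fraction
    donor_subset_proportions: pd.DataFrame  # donors x T subsets (share of T pool)
    donor_burden: pd.Series  # realized senescent fraction used for composition shifts
    program_genes: dict[str, list[str]]  # cell type -> planted gene ids


def default_config(**overrides) -> SimulationConfig:
    """Cohort mirroring the study conditions: 32 donors aged 18-76, skin cell
    types plus the three T subsets, and an age-accumulating senescence program
    in every cell type."""
    cfg = SimulationConfig(
        programs=tuple(
            SenescenceProgram(cell_type=name)
            for name in ("Fibroblast", "KC", "VE", "Th", "Tc", "Treg")
        ),
        burden_composition_effect=4.0,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws parametrized by mean m and dispersion a (var = m + a m^2)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    return int(max(1, _nb_counts(rng, np.array(mean), dispersion)))


def simulate_cohort(config: SimulationConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate a cohort; returns counts+metadata as AnnData and the GroundTruth.

    The AnnData carries raw integer UMI counts in ``X`` (CSR) and per-cell
    metadata in ``obs`` (donor_id, age_years, cell_type, batch).  Identical
    config and seed give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    amin, amax = config.age_range
    if config.ages is not None:
        ages = np.asarray(config.ages, dtype=float)
    elif config.age_sampling == "even":
        ages = np.round(np.linspace(amin, amax, config.n_donors), 1)
    else:
        ages = np.round(np.sort(rng.uniform(amin, amax, config.n_donors)), 1)
    donor_ids = [f"D{i + 1:03d}" for i in range(config.n_donors)]

    # gene panel: mito genes first, then program blocks, then background genes
    n_mt = config.n_mito_genes
    gene_names = [f"MT-{i + 1}" for i in range(n_mt)]
    gene_names += [f"GENE{i + 1:05d}" for i in range(config.n_genes - n_mt)]
    base_means = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    base_means[:n_mt] = config.mito_mean

    program_cols: dict[str, np.ndarray] = {}
    program_genes: dict[str, list[str]] = {}
    cursor = n_mt
    for prog in config.programs:
        cols = np.arange(cursor, cursor + prog.n_genes)
        cursor += prog.n_genes
        program_cols[prog.cell_type] = cols
        program_genes[prog.cell_type] = [gene_names[c] for c in cols]
        base_means[cols] = prog.background_mean
    prog_by_type = {p.cell_type: p for p in config.programs}

    def sen_prob(cell_type: str, age: float) -> float:
        prog = prog_by_type.get(cell_type)
        if prog is None:
            return 0.0
        frac = (age - amin) / (amax - amin)
        return float(np.clip(prog.f_young + (prog.f_old - prog.f_young) * frac, 0.0, 1.0))

    # pass 1: cell counts, types and senescent flags; burden from non-T cells
    cells_type: list[np.ndarray] = []
    cells_donor: list[int] = []
    cells_flags: list[np.ndarray] = []
    donor_nont_sen = np.zeros(config.n_donors)
    donor_nont_tot = np.zeros(config.n_donors)
    donor_blocks: list[list[tuple[str, np.ndarray]]] = []
    for d in range(config.n_donors):
        blocks: list[tuple[str, np.ndarray]] = []
        for ct in config.cell_types:
            n = _draw_count(rng, ct.mean_cells, ct.dispersion)
            flags = rng.random(n) < sen_prob(ct.name, ages[d])
            blocks.append((ct.name, flags))
            donor_nont_sen[d] += flags.sum()
            donor_nont_tot[d] += n
        donor_blocks.append(blocks)
    burden = np.divide(
        donor_nont_sen, donor_nont_tot, out=np.zeros_like(donor_nont_sen), where=donor_nont_tot > 0
    )
    burden_centered = burden - burden.mean()

    base_logits = np.log(
        np.clip([config.t_subset_baselines[s] for s in T_SUBSETS], 1e-12, None)
    )
    subset_counts = np.zeros((config.n_donors, len(T_SUBSETS)), dtype=int)
    for d in range(config.n_donors):
        n_t = _draw_count(rng, config.t_cells_mean, config.t_cells_dispersion)
        logits = base_logits.copy()
        shift = config.burden_composition_effect * burden_centered[d]
        logits[T_SUBSETS.index("Th")] += shift
        logits[T_SUBSETS.index("Treg")] += shift
        probs = np.exp(logits - logits.max())
        probs /= probs.sum()
        counts = rng.multinomial(n_t, probs)
        subset_counts[d] = counts
        for s, n_s in zip(T_SUBSETS, counts):
            flags = rng.random(n_s) < sen_prob(s, ages[d])
            donor_blocks[d].append((s, flags))

    # pass 2: counts, donor by donor
    size_factors = np.exp(rng.normal(0.0, config.batch_effect_sd, config.n_donors))
    obs_rows: list[tuple[str, str, float, str, str]] = []
    mats: list[sparse.csr_matrix] = []
    flags_all: list[np.ndarray] = []
    cell_idx = 0
    for d in range(config.n_donors):
        for ct_name, flags in donor_blocks[d]:
            n = len(flags)
            if n == 0:
                continue
            mu = np.broadcast_to(base_means * size_factors[d], (n, config.n_genes)).copy()
            cols = program_cols.get(ct_name)
            if cols is not None and flags.any():
                prog = prog_by_type[ct_name]
                mu[np.ix_(flags, cols)] = prog.boost_mean * size_factors[d]
            counts = _nb_counts(rng, mu, config.gene_dispersion)
            mats.append(sparse.csr_matrix(counts.astype(np.int32)))
            flags_all.append(flags)
            for k in range(n):
                obs_rows.append(
                    (
                        f"CELL{cell_idx + k + 1:07d}",
                        donor_ids[d],
                        ages[d],
                        ct_name,
                        f"batch{d + 1:03d}",
                    )
                )
            cell_idx += n

    obs = pd.DataFrame(
        obs_rows, columns=["barcode", "donor_id", "age_years", "cell_type", "batch"]
    ).set_index("barcode")
    X = sparse.vstack(mats, format="csr")
    var = pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    adata = ad.AnnData(X=X, obs=obs, var=var)

    flags_vec = np.concatenate(flags_all)
    senescent = pd.Series(flags_vec, index=obs.index, name="senescent")
    grp = pd.DataFrame({"donor_id": obs["donor_id"], "cell_type": obs["cell_type"], "sen": flags_vec})
    donor_fractions = (
        grp.groupby(["donor_id", "cell_type"], observed=True)["sen"].mean().unstack("cell_type")
    )
    subset_prop = subset_counts / np.maximum(subset_counts.sum(axis=1, keepdims=True), 1)
    donor_subset_proportions = pd.DataFrame(subset_prop, index=donor_ids, columns=list(T_SUBSETS))
    truth = GroundTruth(
        senescent=senescent,
        donor_fractions=donor_fractions,
        donor_subset_proportions=donor_subset_proportions,
        donor_burden=pd.Series(burden, index=donor_ids, name="burden"),
        program_genes=program_genes,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# 10x-style bundle I/O (MatrixMarket + barcodes + features, genes as rows)

def write_tenx_bundle(
    adata: ad.AnnData, out_dir: str | Path, truth: GroundTruth | None = None
) -> Path:
    """Write counts + metadata as an uncompressed 10x-convention bundle.

    On disk the matrix is genes x cells MatrixMarket; in memory cells x genes.
    """
    if adata.n_obs == 0:
        raise ValueError("no cells to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = sparse.csc_matrix(adata.X.T)
    spio.mmwrite(str(out / "matrix.mtx"), X, field="integer")
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    feats = pd.DataFrame(
        {"id": adata.var_names, "name": adata.var_names, "type": "Gene Expression"}
    )
    feats.to_csv(out / "features.tsv", sep="\t", index=False, header=False)
    adata.obs.reset_index().to_csv(out / "metadata.tsv", sep="\t", index=False)
    if truth is not None:
        truth.senescent.reset_index().to_csv(out / "truth.tsv", sep="\t", index=False)
        prog = pd.DataFrame(
            [(ct, g) for ct, genes in truth.program_genes.items() for g in genes],
            columns=["cell_type", "gene"],
        )
        prog.to_csv(out / "program_genes.tsv", sep="\t", index=False)
    return out


def read_tenx_bundle(in_dir: str | Path) -> ad.AnnData:
    """Read a bundle written by :func:`write_tenx_bundle` (or the same shape)."""
    d = Path(in_dir)
    X = sparse.csr_matrix(spio.mmread(str(d / "matrix.mtx")).T.astype(np.int32))
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    feats = pd.read_csv(d / "features.tsv", sep="\t", header=None)
    meta_path = d / "metadata.tsv"
    if meta_path.exists():
        obs = pd.read_csv(meta_path, sep="\t").set_index("barcode")
        obs = obs.loc[barcodes]
    else:
        obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    if len(barcodes) != X.shape[0]:
        raise ValueError(
            f"barcode mismatch: {len(barcodes)} barcodes for {X.shape[0]} matrix columns"
        )
    var = pd.DataFrame(index=pd.Index(feats[0].astype(str), name="gene"))
    obs.index = obs.index.astype(str)
    return ad.AnnData(X=X, obs=obs, var=var)


def read_truth(in_dir: str | Path) -> pd.Series:
    """Per-cell senescent flags written next to a bundle, if present."""
    df = pd.read_csv(Path(in_dir) / "truth.tsv", sep="\t").set_index("barcode")
    return df["senescent"].astype(bool)
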