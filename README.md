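# senskin

Senescence scoring and T-cell composition analysis for skin scRNA-seq cohorts.

Aging tissues accumulate senescent cells — cells in stable cell-cycle arrest
with a pro-inflammatory secretory phenotype (SASP) — and their clearance
depends on immune surveillance. `senskin` is a library and command-line
pipeline for asking, in a multi-donor skin single-cell RNA-seq cohort, whether
senescent-cell burden rises with donor age and whether it is associated with
an imbalance of the tissue-resident T-lymphocyte compartment (Th, Tc, Treg).
It is aimed at computational biologists who have a UMI count matrix with
per-cell donor age and cell-type annotations and want a reproducible,
testable implementation of the whole chain: QC → signature derivation →
per-cell scoring → mixture-based senescent-cell calling → donor-level
composition statistics → differential expression and gene-set
over-representation. A synthetic cohort generator with known ground truth
makes every stage testable without any data download.

## Method

For each cell type, a **senescence signature** is the set of genes whose
expressing fraction (raw count > 0) satisfies, pooling cells within the young
and old donor groups:

```
p_young < 0.05,    0.01 < p_old < 0.20,
and ( p_old ≥ 2.5 · p_young   or   p_old − p_young > 0.05 )
```

Each cell is scored as the mean over signature genes of the per-gene z-scored
log-normalized expression, *s_i = (1/|G|) Σ_g z_ig*. A 1-D Gaussian mixture
(K ∈ {2, 3}, chosen by BIC, 10 seeded k-means++ EM restarts) is fitted to each
cell type's score distribution, and the decision threshold is the point
between the two rightmost component means where the weighted component
densities are equal, *w₁ 𝒩(t; μ₁, σ₁²) = w₂ 𝒩(t; μ₂, σ₂²)*; cells scoring
strictly above *t* are called senescent.

Donor-level analysis computes Th/Tc/Treg proportions under two denominators
(total T cells; all cells), the immunological indices Th/Tc, Treg/Tc and
Treg/Th, and per-donor senescent fractions, then runs Spearman correlation
scans (age and senescent-burden targets) with per-scan Bonferroni correction
and a per-cell-type low-count donor exclusion (count < mean − 2 SD).
Differential expression between old- and young-donor cells uses a two-sided
Mann–Whitney U test per gene with BH-FDR < 0.01 and detection-fraction
filters (> 10 % in the target group, < 50 % in the comparison group);
over-representation of the passing genes in user-supplied GMT gene sets is
assessed with an upper-tail hypergeometric test.

## Worked example

```python
from senskin import composition, preprocessing, senescence
from senskin.synthetic import default_config, simulate_cohort

adata, truth = simulate_cohort(default_config(seed=7))   # 10,116 cells × 1,500 genes
qc = preprocessing.compute_qc_metrics(adata)
keep = preprocessing.filter_cells(qc)                    # kept 10,005 / 10,116 cells
adata = adata[keep.to_numpy()].copy()
preprocessing.normalize_log(adata)

signatures, callsets = senescence.run_senescence(adata, seed=7)
for sig, cs in zip(signatures, callsets):
    print(f"{sig.cell_type:<10s} signature: {len(sig):3d} genes   "
          f"senescent fraction: {cs.fraction:.3f}")

calls = senescence.calls_frame(callsets)
comp = composition.subset_proportions(adata.obs, calls)
scan = composition.scan_fractions_vs_age(comp, adata.obs)
row = scan.set_index("y").loc["sen_frac_pooled"]
print(f"pooled senescent fraction vs age: rho={row['rho']:.3f}, "
      f"adjusted p={row['p_adj']:.2e}")
```

prints

```
Fibroblast signature:  45 genes   senescent fraction: 0.156
KC         signature:  51 genes   senescent fraction: 0.163
Tc         signature:  59 genes   senescent fraction: 0.193
Th         signature:  52 genes   senescent fraction: 0.152
Treg       signature:  73 genes   senescent fraction: 0.226
VE         signature:  73 genes   senescent fraction: 0.165
pooled senescent fraction vs age: rho=0.978, adjusted p=5.00e-21
```

The per-cell-type signatures recover the senescence programs planted by the
generator, the called senescent fractions sit near the cohort-average planted
rate (~16 % given the 2 %→30 % age ramp), and the pooled fraction rises
steeply with donor age — the qualitative finding the pipeline is built to
detect. The same stages are available from the shell:

```
senskin simulate --seed 7 --out bundle/
senskin run --in bundle/ --seed 7 --out results/
```

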