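# Methods

## Scope and assumptions

`senskin` operates on a cells × genes UMI count matrix with per-cell metadata
(donor id, donor age in years, cell-type label, optional batch). Cell-type
annotation, doublet detection, batch integration and embedding are treated as
upstream concerns: labels are a required input (an external exclusion barcode
list can be supplied for doublets), and no batch correction is applied —
donor-level statistics are rank-based and the per-cell score is z-scored
within each cell type, which absorbs global depth and batch scale shifts but
not gene-specific batch effects.

## Quality control

Per-cell metrics are total UMIs, detected genes and mitochondrial percentage
(computed from raw counts via scanpy). A cell is kept iff

- total UMIs ≥ 500 (absolute floor), and
- |log1p(total) − median| ≤ 5 MAD, and
- |log1p(detected genes) − median| ≤ 5 MAD, and
- mito % ≤ 15, and mito % − median ≤ 4 MAD (one-sided: low mitochondrial
  content is not a quality defect).

MADs are unscaled (no 1.4826 normal-consistency factor) and computed on the
full input population; a zero MAD disables the MAD rule for that metric (the
absolute criteria remain) with a warning. Whether the MAD rules are one- or
two-sided and on what transform was an open choice; log1p two-sided for
totals/genes is standard robust practice in droplet QC and is the default,
switchable in code. Normalization scales each kept cell to 10,000 counts and
applies natural log1p into a separate layer; raw counts are never modified.

## Senescence signatures

For each cell type, expressing fractions (raw count > 0) are pooled over
cells from young donors (age ≤ 30) and old donors (age ≥ 55); the cutoffs are
configurable (`SignatureCriteria.young_max_age` / `old_min_age`) since no
canonical boundary exists — 30/55 leaves a buffer zone so the two groups
represent clearly distinct ages. Fractions are pooled across donors within a
group rather than averaged per donor (a flag-level alternative would weight
small donors up; pooling matches how the fractions are consumed downstream).
A gene enters the signature iff

    p_young < 0.05  and  0.01 < p_old < 0.20
    and (p_old ≥ 2.5 · p_young  or  p_old − p_young > 0.05)

with strict inequalities exactly as written; when p_young = 0 the fold
criterion is vacuously satisfied (any p_old ≥ 0), so inclusion is decided by
the old-band criterion alone. The band's upper bound (20 %) encodes the prior
that senescent cells are a minority: genes expressed in most old cells are
age-regulated rather than senescence-restricted.

## Per-cell score

The published senescence-scoring algorithm this stage follows assigns each
cell a continuous score measuring alignment with the cell type's signature;
its exact gene weighting is not restated here, so the score is this package's
own documented choice: the unweighted mean over signature genes of the
per-gene z-scored log-normalized expression, with z computed within the
scored population (all cells of the cell type). It is monotone in signature
expression, affine-stable, and parameter-free. Genes missing from the matrix
or with zero variance in the population are dropped with a warning; an empty
signature skips scoring for that cell type.

## Mixture model and decision boundary

A 1-D Gaussian mixture is fitted to each cell type's score distribution with
EM (scikit-learn), K ∈ {2, 3} selected by BIC, 10 restarts from seeded
k-means++ initializations, 500 iterations max. Components are reported sorted
by mean. At least 50 scores are required (configurable floor); an all-equal
score vector is rejected as degenerate.

The senescent/normal threshold makes "the value between the two rightmost
components" precise as the weighted-density equality point
w₁𝒩(t; μ₁, σ₁²) = w₂𝒩(t; μ₂, σ₂²) inside the open interval (μ₁, μ₂), found
by Brent's method on the log-density difference (tolerance 1e-12). If the
densities do not cross inside the interval (heavily overlapping or nested
components), the midpoint (μ₁+μ₂)/2 is used with a warning. A cell is
senescent iff its score is strictly greater than the threshold, so a cell
exactly at the boundary is not called.

Caveat: when the score distribution is genuinely unimodal, the two mirror EM
solutions (spurious tail component on the left or on the right) are nearly
equivalent in likelihood, and whichever wins is sample-dependent. With a
right-tail minor component only an extreme minority is called; with a
left-tail minor component the boundary between the two rightmost components
flags the majority. A called senescent fraction above ~50 % should therefore
be read as "no separable senescent mode", not as a biological estimate. The
test suite documents both orientations.

## Donor-level composition and correlation scans

Per donor, the composition table carries Th/Tc/Treg counts, total T cells
and total cells; proportions under both denominators (total T pool and all
cells — the former reflects balance within the T compartment, the latter
representation within the whole tissue); the indices Th/Tc, Treg/Tc, Treg/Th
(NaN-flagged, never coerced to 0, when the denominator count is zero); and
pooled plus per-cell-type senescent fractions.

Associations use Spearman rank correlation (average ranks for ties, p from
the t-approximation with n−2 df — adequate at cohort sizes of ~30; n ≥ 4
required, zero-variance inputs flagged undefined). Three scans mirror the
standard questions: per-cell-type and pooled senescent fractions vs age;
T-pool-denominator proportions and indices vs age; all-cells-denominator
proportions and indices vs pooled senescent burden. Each scan is one
Bonferroni family (p_adj = min(1, m·p), m = pairs in the scan, recorded per
result). Before a per-cell-type fraction-vs-age test, donors whose cell count
for that type falls below mean − 2·SD (population SD, ddof 0, one-sided per
the rule's wording) are excluded; with at least 3 donors required and zero SD
meaning no exclusions.

Note on compositional coupling: proportions of all cells share a denominator
with the pooled senescent fraction, so donors with relatively larger T pools
have mechanically lower pooled burden and higher T-subset all-cells
proportions. When between-donor variation in the T-to-total ratio is large
this induces a negative correlation under the null. At realistic tissue
compositions (T cells a modest minority, cell-count CV ~20 %) the artifact
is negligible — the null simulations in the acceptance suite verify a <5 %
false-flag rate — but the all-cells-denominator scan should not be applied
to cohorts where the T fraction itself varies several-fold.

## Differential expression and over-representation

Old vs young cells of one T subset (same age cutoffs as the signature stage,
configurable) are compared per gene with a two-sided Mann–Whitney U test on
log-normalized values (midranks for ties; normal approximation with tie and
continuity corrections; exact enumeration of all C(n, n_a) group assignments
when n ≤ 12, where the two-sided p is P(|U − n_a·n_b/2| ≥ observed)). Cells
are the test units, as is usual for this style of single-cell DEG; a
donor-level pseudobulk alternative would avoid pseudoreplication at the cost
of power and is deliberately out of scope here — planted-truth recovery and
null control are validated at the cell level. Genes pass for a target group
iff BH-FDR < 0.01, detection (raw count > 0) in > 10 % of target-group cells
and < 50 % of comparison-group cells; the rule is evaluated per direction
with each group in turn as target, so up- and down-regulation are symmetric.

Over-representation of a query gene list against GMT gene sets uses the
upper-tail hypergeometric p = P(X ≥ k) with overlap k, set size K (after
intersection with the stated universe), query size n, universe size N; sets
outside [10, 500] genes after intersection are dropped (bounds configurable)
and BH correction is applied across tested sets. The query must be a subset
of the universe; the universe is the caller's responsibility (typically all
detected genes).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline must detect,
not skin biology: multi-donor cohorts (default 32 donors, ages evenly spaced
over 18–76, optionally uniform draws), several cell types (fibroblasts,
keratinocytes, vascular endothelium, plus Th/Tc/Treg at 45/40/15 % of a
T pool), negative-binomial UMI counts (per-gene log-normal means, gene
dispersion 0.5, per-donor log-normal size factor with sd 0.15 standing in for
batch/depth effects, 10 mitochondrial genes at elevated mean so the QC rules
have purchase), and per-cell-type senescence programs: each cell is senescent
with probability interpolating linearly in donor age between f_young = 0.02
and f_old = 0.30 (the simplest monotone accumulation model), and program
genes (40 per type by default) switch from a background mean of 0.01 to a
boosted mean of 1.2 in senescent cells — chosen so that the expressing
fraction among old-donor cells lands inside the 1–20 % signature band while
young-donor cells stay under 5 %. Cell counts per donor are negative binomial
with dispersion 0.05 (~20–25 % CV, typical of biopsy cohorts; the gene-level
dispersion would imply >50 % CV in cells per donor, which is unrealistic and
drowns all-cells-denominator proportions in pool-size noise).

An optional burden→composition effect shifts the Th and Treg logits of the
T-subset multinomial by `slope · (burden − cohort mean burden)`, where burden
is the donor's realized senescent fraction among non-T cells (so the planted
compositional effect is driven by, but not identical to, the measured pooled
fraction). Proportions stay valid by construction. No published effect size
exists for this link; the default config uses slope 4 (a moderate effect) and
the strong-effect validation cohorts use slope 12.

What the generator does *not* emulate — and hence what passing tests cannot
show about real data: transcriptome-wide co-expression structure, cell-type-
specific library sizes, ambient RNA, doublets, gene-specific batch effects,
annotation errors, and senescence programs that overlap between cell types or
drift with age in the non-senescent population. Recovery numbers on synthetic
cohorts are upper bounds on real-data performance.

Determinism: one `numpy` Generator seeded from the config drives every draw,
so identical config + seed gives bit-identical counts and truth; the pipeline
fans a single global seed out to per-stage seeds via `SeedSequence([seed,
stage_index])`, and reruns produce byte-identical TSVs (checksummed in the
run manifest).

## Validation problem sizes

The acceptance suite uses: ≥ 1,000 randomized instances per rule oracle;
~200–300 instances per statistical oracle (exact enumeration at n ≤ 12 for
Mann–Whitney, N ≤ 12 for the hypergeometric); 20 seeds × 2,000 points for
mixture recovery (planted 0.5·𝒩(0,1) + 0.5·𝒩(6,1); means within ±0.2,
weights ±0.05, threshold 3.0 ± 0.2); one 30-donor ~6,000-cell cohort for
end-to-end call recovery (balanced accuracy ≥ 0.90, donor-fraction rank
correlation ≥ 0.8, pooled-fraction-vs-age adjusted p < 0.05); 20 planted
plus 200 null 30-donor cohorts for the composition scan (power ≥ 18/20,
false-flag rate ≤ 5 %); and 20 cohorts for DEG recovery (mean recall ≥ 0.8,
null pass rate ≤ 2 %). The full suite runs in about a minute on one CPU.

## Known limitations

- The per-cell score is a documented stand-in for the original published
  score; absolute score values and signature gene weights are not comparable
  to that implementation, though the downstream thresholding is scale-free.
- Mixture-based calling assumes a separable high-score mode; see the
  unimodal caveat above.
- Cell-level DEG p-values ignore donor as a grouping factor
  (pseudoreplication); treat them as screening statistics.
- Bonferroni families are per scan; correlations reported across several
  scans are not jointly corrected.
- The signature criteria compare two pooled age groups and ignore donors in
  the buffer zone (ages 31–54 by default).
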