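"""Donor composition, the low-count exclusion rule and correlation scans."""

import numpy as np
import pandas as pd
import pytest

from senskin.composition import (
    bonferroni,
    correlation_scan,
    exclude_low_count_samples,
    scan_fractions_vs_age,
    scan_tprops_vs_age,
    scan_tprops_vs_burden,
    spearman,
    subset_proportions,
)
from senskin.synthetic import SenescenceProgram, CellTypeSpec, simulate_cohort
from tests.conftest import small_config


# --- 2SD low-count exclusion -------------------------------------------------

@pytest.mark.parametrize(
    "counts, expected_excluded",
    [
        ([100, 100, 100, 10], []),          # cutoff ~ -0.44: nothing below
        ([100, 100, 100, 100, 100, 0], [5]),  # cutoff ~ 8.8: the empty donor goes
        ([50, 50, 50, 50], []),             # zero SD: no exclusions
    ],
)
def test_low_count_exclusion_examples(counts, expected_excluded):
    s = pd.Series(counts, index=[f"D{i}" for i in range(len(counts))])
    included, excluded = exclude_low_count_samples(s)
    assert list(excluded) == [f"D{i}" for i in expected_excluded]
    assert set(included) | set(excluded) == set(s.index)


def test_low_count_exclusion_matches_inequality_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(3, 30))
        counts = pd.Series(rng.integers(0, 500, n), index=[f"D{i}" for i in range(n)])
        included, excluded = exclude_low_count_samples(counts)
        cutoff = counts.mean() - 2 * counts.std(ddof=0)
        oracle = counts.index[counts < cutoff] if counts.std(ddof=0) > 0 else counts.index[:0]
        assert list(excluded) == list(oracle)
        assert len(included) + len(excluded) == n


def test_low_count_exclusion_needs_three_donors():
    with pytest.raises(ValueError, match="3 donors"):
        exclude_low_count_samples(pd.Series([1, 2]))


# --- composition table -------------------------------------------------------

def _toy_metadata():
    rows = (
        [("D1", 40.0, "Th")] * 20
        + [("D1", 40.0, "Tc")] * 10
        + [("D1", 40.0, "Treg")] * 5
        + [("D1", 40.0, "Tother")] * 5
        + [("D1", 40.0, "KC")] * 360
    )
    return pd.DataFrame(
        rows, columns=["donor_id", "age_years", "cell_type"],
        index=[f"c{i}" for i in range(len(rows))],
    )


def test_subset_proportions_under_both_denominators():
    comp = subset_proportions(_toy_metadata(), extra_t_labels=("Tother",))
    row = comp.loc["D1"]
    assert row["n_T"] == 40 and row["n_cells"] == 400
    assert row["prop_Th_of_T"] == pytest.approx(0.5)
    assert row["prop_Tc_of_T"] == pytest.approx(0.25)
    assert row["prop_Treg_of_T"] == pytest.approx(0.125)
    assert row["prop_Th_of_all"] == pytest.approx(0.05)
    assert row["prop_Tc_of_all"] == pytest.approx(0.025)
    assert row["prop_Treg_of_all"] == pytest.approx(0.0125)
    assert row["idx_Th_Tc"] == pytest.approx(2.0)


def test_zero_denominators_flag_indices_undefined():
    meta = pd.DataFrame(
        {"donor_id": ["D1"] * 4, "age_years": 30.0, "cell_type": ["Th", "Th", "KC", "KC"]},
        index=list("abcd"),
    )
    comp = subset_proportions(meta)
    assert np.isnan(comp.loc["D1", "idx_Th_Tc"])
    assert np.isnan(comp.loc["D1", "idx_Treg_Tc"])
    # donor with no T cells at all keeps all-cells proportions
    meta2 = meta.assign(cell_type=["KC"] * 4)
    with pytest.warns(UserWarning, match="zero T cells"):
        comp2 = subset_proportions(meta2)
    assert np.isnan(comp2.loc["D1", "prop_Th_of_T"])
    assert comp2.loc["D1", "prop_Th_of_all"] == 0.0


def test_denominator_conventions_are_consistent(cohort7):
    adata, _ = cohort7
    comp = subset_proportions(adata.obs)
    for s in ("Th", "Tc", "Treg"):
        np.testing.assert_allclose(
            comp[f"prop_{s}_of_T"] * comp["n_T"] / comp["n_cells"],
            comp[f"prop_{s}_of_all"],
        )
    # all-cells proportions over every cell type sum to 1 per donor
    per_type = adata.obs.groupby(["donor_id", "cell_type"], observed=True).size().unstack()
    np.testing.assert_allclose(
        (per_type.div(per_type.sum(axis=1), axis=0)).sum(axis=1), 1.0
    )


# --- spearman / bonferroni ---------------------------------------------------

def _rank_oracle(x, y):
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    n = len(rx)
    from scipy import stats as ss

    t = rho * np.sqrt((n - 2) / max(1e-300, 1 - rho**2))
    p = 2 * ss.t.sf(abs(t), n - 2)
    return rho, min(1.0, p)


def test_spearman_monotone_identities():
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
    assert spearman([1, 2, 3, 4], [40, 30, 20, 10])[0] == pytest.approx(-1.0)


def test_spearman_hand_ranked_example():
    # ranks differ by d = (-1, 1, -1, 1, 0): rho = 1 - 6*4 / (5*24) = 0.8
    rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert rho == pytest.approx(0.8)


def test_spearman_matches_rank_oracle_with_ties(rng):
    for _ in range(100):
        n = int(rng.integers(4, 21))
        x = rng.integers(0, 8, n).astype(float)  # heavy ties
        y = rng.integers(0, 8, n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rho, p = spearman(x, y)
        rho_o, p_o = _rank_oracle(x, y)
        assert rho == pytest.approx(rho_o, abs=1e-12)
        assert p == pytest.approx(p_o, rel=1e-9, abs=1e-12)


def test_spearman_guards():
    with pytest.raises(ValueError, match="n >= 4"):
        spearman([1, 2, 3], [1, 2, 3])
    with pytest.warns(UserWarning, match="zero variance"):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
    assert np.isnan(rho) and np.isnan(p)


def test_bonferroni_scaling_and_cap():
    np.testing.assert_allclose(bonferroni([0.01], m=8), [0.08])
    np.testing.assert_allclose(bonferroni([0.5], m=8), [1.0])
    np.testing.assert_allclose(bonferroni([0.03]), [0.03])  # single test family
    with pytest.raises(ValueError):
        bonferroni([1.5])


# --- correlation scans -------------------------------------------------------

def _truth_calls(adata, truth):
    return pd.DataFrame(
        {
            "barcode": adata.obs_names,
            "cell_type": adata.obs["cell_type"].to_numpy(),
            "score": 0.0,
            "threshold": 0.0,
            "senescent": truth.senescent.to_numpy(),
        }
    )


def _composition_cfg(slope, seed):
    return small_config(
        n_donors=30,
        cell_types=(CellTypeSpec("Fibroblast", 300.0),),
        t_cells_mean=100.0,
        t_subset_baselines={"Th": 0.45, "Tc": 0.35, "Treg": 0.20},
        n_genes=60,
        programs=(SenescenceProgram("Fibroblast", n_genes=10),),
        burden_composition_effect=slope,
        seed=seed,
    )


def test_planted_burden_effect_is_flagged_significant():
    adata, truth = simulate_cohort(_composition_cfg(slope=12.0, seed=0))
    comp = subset_proportions(adata.obs, _truth_calls(adata, truth))
    scan = scan_tprops_vs_burden(comp)
    row = scan.set_index("y").loc["prop_Treg_of_all"]
    assert row["rho"] > 0
    assert row["p_adj"] < 0.05
    assert row["m"] == len(scan)


def test_fraction_vs_age_scan_applies_low_count_exclusion():
    adata, truth = simulate_cohort(_composition_cfg(slope=0.0, seed=1))
    comp = subset_proportions(adata.obs, _truth_calls(adata, truth))
    scan = scan_fractions_vs_age(comp, adata.obs)
    pooled = scan.set_index("y").loc["sen_frac_pooled"]
    assert pooled["rho"] > 0 and pooled["p_adj"] < 0.05
    assert set(scan["family"]) == {"fractions_vs_age"}


def test_constant_metric_reports_undefined_without_crashing():
    table = pd.DataFrame(
        {"age_years": [30, 40, 50, 60, 70], "flat": [0.2] * 5},
        index=[f"D{i}" for i in range(5)],
    )
    scan = correlation_scan(table, [("age_years", "flat")], family="demo")
    assert scan.loc[0, "note"] == "undefined"
    assert np.isnan(scan.loc[0, "rho"])


def test_insufficient_donors_are_flagged_not_dropped():
    table = pd.DataFrame(
        {"age_years": [30, 40, 50], "v": [0.1, 0.2, 0.3]}, index=["D1", "D2", "D3"]
    )
    scan = correlation_scan(table, [("age_years", "v")], family="demo")
    assert scan.loc[0, "note"] == "insufficient_n"


def test_tprops_vs_age_scan_schema(cohort7):
    adata, _ = cohort7
    comp = subset_proportions(adata.obs)
    scan = scan_tprops_vs_age(comp)
    assert len(scan) == 6
    assert (scan["m"] == 6).all()
    ok = scan["p_adj"].dropna()
    assert ((ok >= scan.loc[ok.index, "p"] - 1e-15) & (ok <= 1)).all()
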