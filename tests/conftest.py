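import numpy as np
import pytest

from senskin import preprocessing
from senskin.synthetic import (
    CellTypeSpec,
    SenescenceProgram,
    SimulationConfig,
    simulate_cohort,
)


def small_config(**overrides) -> SimulationConfig:
    """Compact cohort used across unit tests: 10 donors aged 20-75, two stromal
    types plus the T subsets, 400 genes with 25-gene programs."""
    base = dict(
        n_donors=10,
        age_range=(20.0, 75.0),
        cell_types=(CellTypeSpec("Fibroblast", 80.0), CellTypeSpec("KC", 60.0)),
        t_cells_mean=60.0,
        n_genes=400,
        baseline_log_mean=0.3,  # keeps per-cell totals well above the QC floor
        programs=(
            SenescenceProgram("Fibroblast", n_genes=25),
            SenescenceProgram("KC", n_genes=25),
            SenescenceProgram("Th", n_genes=25),
            SenescenceProgram("Tc", n_genes=25),
        ),
        burden_composition_effect=0.0,
        seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def cohort7():
    """Simulated cohort (seed 7) shared by read-only tests."""
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def normalized7(cohort7):
    adata, truth = cohort7
    adata = adata.copy()
    preprocessing.normalize_log(adata)
    return adata, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
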