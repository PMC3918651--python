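import numpy as np
import pandas as pd
import pytest

from admixpheno.ancestry import AIMPanel, GenotypeMatrix
from admixpheno.phenotypes import derive
from admixpheno.simulate import (
    SimulationConfig,
    simulate_genotypes,
    simulate_panel,
    simulate_phenotypes,
    simulate_true_pea,
)


@pytest.fixture
def tiny_panel():
    """Five informative markers with known frequencies."""
    return AIMPanel(
        marker_id=np.array(["m1", "m2", "m3", "m4", "m5"], dtype=object),
        counted_allele=np.array(list("ACGTA"), dtype=object),
        p_afr=np.array([0.1, 0.2, 0.3, 0.15, 0.25]),
        p_eur=np.array([0.9, 0.7, 0.8, 0.85, 0.6]),
    )


@pytest.fixture(scope="session")
def sim_panel():
    return simulate_panel(300, 0.4, seed=101)


@pytest.fixture(scope="session")
def sim_cohort(sim_panel):
    """Small simulated cohort: truth, genotypes, phenotypes (n=400)."""
    s = simulate_true_pea(400, seed=102)
    gm = simulate_genotypes(sim_panel, s, missing_rate=0.01, seed=103)
    return s, gm


@pytest.fixture(scope="session")
def derived_cohort():
    """Full-size derived table with true ancestry attached (one replicate)."""
    cfg = SimulationConfig()
    s = simulate_true_pea(cfg.n_individuals, seed=104)
    tab, truth = simulate_phenotypes(s, cfg, seed=105)
    tab["pea"] = s
    return derive(tab, glucose_units="mg/dL"), truth
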