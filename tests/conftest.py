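import numpy as np
import pandas as pd
import pytest

import cofrac_pmi as cp


@pytest.fixture(scope="session")
def small_sim():
    """A small noisy fractionation simulation shared across tests."""
    config = cp.SimConfig(
        n_proteins=40,
        n_metabolites=10,
        planted_pmis=[("M0001", "P0021"), ("M0002", "P0030"), ("M0003", "P0035")],
        complexes=[(["P0001", "P0002"], 2.0e5), (["P0003", "P0004", "P0005"], 1.0e6)],
        noise_cv=0.10,
        seed=11,
    )
    dataset, truth, calibration = cp.simulate_fractionation(config)
    return config, dataset, truth, calibration


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noise-free simulation: planted structure is exact."""
    config = cp.SimConfig(
        n_proteins=20,
        n_metabolites=6,
        planted_pmis=[("M0001", "P0011"), ("M0004", "P0017")],
        complexes=[(["P0001", "P0002"], 2.0e5)],
        noise_cv=0.0,
        n_replicates=1,
        seed=3,
    )
    dataset, truth, calibration = cp.simulate_fractionation(config)
    return config, dataset, truth, calibration


@pytest.fixture(scope="session")
def demo_report():
    return cp.run_demo(seed=11)
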