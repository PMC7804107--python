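"""Shared fixtures: moderately sized simulations reused across modules."""

import numpy as np
import pytest

import costim
from costim import core_programs as cp


@pytest.fixture(scope="session")
def sim_params():
    """Planted four-condition experiment with moderate cross-inhibition."""
    return costim.CountSimParams(
        n_cells_per_condition=500,
        n_genes=500,
        n_program_genes_a=100,
        n_program_genes_b=100,
        n_shared_genes=30,
        baseline_mean=0.5,
        induction_fold_a=4.0,
        induction_fold_b=4.0,
        dispersion=0.5,
        costim_fractions=(0.45, 0.45, 0.10),
        cross_inhibition=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def sim_data(sim_params):
    return costim.generate_counts(sim_params)


@pytest.fixture(scope="session")
def norm_adata(sim_data):
    adata, _ = sim_data
    return costim.normalize(adata)


@pytest.fixture(scope="session")
def programs(norm_adata):
    progs, _ = cp.run_core_program_analysis(norm_adata)
    return progs


@pytest.fixture(scope="session")
def no_inhibition_data():
    """Clean costim mixture with no cross-inhibition (fractions 45/45/10)."""
    params = costim.CountSimParams(
        n_cells_per_condition=500,
        n_genes=500,
        n_program_genes_a=100,
        n_program_genes_b=100,
        n_shared_genes=30,
        cross_inhibition=0.0,
        costim_fractions=(0.45, 0.45, 0.10),
        seed=7,
    )
    adata, truth = costim.generate_counts(params)
    return costim.normalize(adata), truth


@pytest.fixture(scope="session")
def chip_data():
    params = costim.ChipSimParams(n_wells=2000, grid_shape=(40, 50), seed=3)
    return costim.generate_chip(params)
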