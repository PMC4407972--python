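import numpy as np
import pytest

from rvpower import panel as panel_mod
from rvpower.fixtures import null_toy_cohort, toy_cohort


@pytest.fixture(scope="session")
def midi_panel():
    """A 2,000-individual SFS-calibrated panel shared by tests that need a
    realistic locus but not the full augmented size."""
    return panel_mod.exome_calibrated_panel(
        seed=20260927, params=panel_mod.ExpansionParams(target_n=2000))


@pytest.fixture(scope="session")
def base_panel():
    return panel_mod.simulate_base_panel(n_individuals=120,
                                         region_length_bp=3000, seed=5)


@pytest.fixture()
def toy():
    return toy_cohort()


@pytest.fixture()
def null_toy():
    return null_toy_cohort()
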