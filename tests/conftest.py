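import numpy as np
import pytest

from bmpscreen.design import LigandPanel
from bmpscreen.preprocess import preprocess
from bmpscreen.simulate import (
    NoiseModel,
    example_panel,
    generate_dataset,
    planted_truth,
)


@pytest.fixture(scope="session")
def panel():
    return example_panel()


@pytest.fixture(scope="session")
def truth_and_contexts(panel):
    return planted_truth(panel)


@pytest.fixture(scope="session")
def noiseless_screen(panel, truth_and_contexts):
    """Zero-noise 10-ligand screen in the wild-type context only."""
    truth, contexts = truth_and_contexts
    wells, ledger = generate_dataset(
        panel, contexts[:1], truth, NoiseModel.noiseless(), n_replicates=3, seed=7
    )
    return wells, ledger


@pytest.fixture(scope="session")
def processed_noiseless(noiseless_screen):
    wells, _ = noiseless_screen
    return preprocess(wells)


@pytest.fixture
def small_panel():
    names = ["L1", "L2", "L3", "L4"]
    return LigandPanel(names, {n: 100.0 for n in names}, {n: 2.0 for n in names})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
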