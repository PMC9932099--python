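import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import hostguest as hg

# lmfit emits harmless RuntimeWarnings (sqrt of negative covariance
# diagonals) on ill-conditioned fits that we deliberately exercise
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def sbx_noiseless():
    """One clean SBX titration (simple 1:1, K = 30.1 mM^-1)."""
    spec = replace(hg.get_scenario("SBX"), noise_sd=0.0, replicates=1)
    return spec, hg.generate_titration(spec)[0]


@pytest.fixture(scope="session")
def sbx_noisy():
    """One noisy SBX titration at the default 0.002 ppm shift noise."""
    spec = replace(hg.get_scenario("SBX"), replicates=1)
    return spec, hg.generate_titration(spec, seed=11)[0]


@pytest.fixture()
def pure_noise_dataset():
    """A titration with no binding signal at all."""
    G = np.concatenate([[0.0], np.geomspace(1e-5, 1e-3, 11)])
    rng = np.random.default_rng(0)
    shifts = rng.normal(0.0, 0.002, (12, 4))
    shifts[0] = 0.0
    return hg.TitrationDataset(np.full(12, 5e-5), G,
                               pd.DataFrame(shifts, columns=list(hg.synthetic_data.PROTONS)))
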