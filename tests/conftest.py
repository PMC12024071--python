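import numpy as np
import pytest

import misim as mi
from misim.bayes_engine import SamplerSettings


@pytest.fixture(scope="session")
def invariant_dataset():
    """One large invariant replication (n=600/group, lvar=1, no mean gap)."""
    spec = mi.make_population(600, 1.0, 0.0)
    return mi.generate_dataset(spec, 20240601)


@pytest.fixture(scope="session")
def invariant_moments(invariant_dataset):
    return mi.sample_moments(invariant_dataset)


@pytest.fixture(scope="session")
def ml_fits(invariant_moments):
    """ML fits of all four model levels on the shared invariant dataset."""
    return {lv: mi.fit_ml(mi.ModelSpec(lv), invariant_moments)
            for lv in ("configural", "metric", "scalar", "baseline")}


@pytest.fixture(scope="session")
def toy_dataset():
    """Small 3-item two-group dataset for brute-force likelihood oracles."""
    spec3 = mi.make_population(40, 1.0, 0.0)
    full = mi.generate_dataset(spec3, 99)
    return mi.TwoGroupDataset(group1=full.group1[:, :3].copy(),
                              group2=full.group2[:, :3].copy())


@pytest.fixture(scope="session")
def small_posterior(invariant_moments):
    """Configural-model posterior on the shared dataset, desk-scale chains."""
    return mi.sample_posterior(mi.ModelSpec("configural"), invariant_moments,
                               settings=SamplerSettings(3, 500, 500, seed=5))
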