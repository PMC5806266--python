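import numpy as np
import pytest

from enzkin import (
    ElementaryRates,
    MichaelisMentenParams,
    PHProfileModel,
    SimulationSpec,
)


@pytest.fixture
def acetate_mm():
    """Published-style Michaelis-Menten truth for 4-nitrophenyl acetate."""
    return MichaelisMentenParams("4-nitrophenyl acetate",
                                 kcat=1.736e-3, km_mM=0.473)


@pytest.fixture
def acetate_ph_kcatkm():
    """Two-pKa truth for the acetate kcat/Km profile."""
    return PHProfileModel(k_lim=2.33, pka1=7.42, pka2=8.29,
                          parameter_kind="kcatKm")


@pytest.fixture
def reference_rates():
    """Elementary-rate reference with an interior kcat/Km optimum and
    E3 >> E2 (kcat profile shifted to higher temperatures)."""
    from enzkin.pipeline import REFERENCE_RATES

    return ElementaryRates(**REFERENCE_RATES)


@pytest.fixture
def substrate_grid():
    return tuple(np.logspace(np.log10(0.05), np.log10(5.0), 8))


def make_spec(seed, grid, noise=0.0, reps=1):
    return SimulationSpec(seed=seed, grid=grid, noise_rel_sd=noise,
                          n_replicates=reps)
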