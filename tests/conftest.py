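import numpy as np
import pytest

from bioage.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def singleton_panel(n_biomarkers: int, slope: float = 0.08, sd: float = 1.0):
    """Config fragments for a panel of independent, equally informative biomarkers."""
    names = tuple(f"bm{j}" for j in range(n_biomarkers))
    return dict(
        biomarkers=names,
        blocks=(None,) * n_biomarkers,
        slopes=(slope,) * n_biomarkers,
        slopes_female=None,
        intercepts=(0.0,) * n_biomarkers,
        residual_sds=(sd,) * n_biomarkers,
        block_correlation=0.0,
    )


@pytest.fixture
def singleton_config():
    """12 independent biomarkers, each a strong linear age trend."""
    return SimulationConfig(
        n_participants=10_000, sigma_delta=5.0, seed=11, **singleton_panel(12)
    )
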