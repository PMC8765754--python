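import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from splicewave.genome import GeneModel, Intron
from splicewave.kinetics import RateSet
from splicewave.simulate import SimConfig, sample_models_and_rates

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_intron_gene() -> GeneModel:
    L = 6000
    return GeneModel(
        gene_id="toy",
        strand="+",
        length=L,
        exons=[(0, 1000), (2500, 3500), (5000, 6000)],
        introns=[
            Intron(index=0, start=1000, end=2500, dist_to_tes=L - 2500),
            Intron(index=1, start=3500, end=5000, dist_to_tes=L - 5000),
        ],
    )


@pytest.fixture(scope="session")
def toy_rates() -> RateSet:
    return RateSet(sigma=1.5, v=1200.0, s=np.array([0.3, 0.08]), c=0.6)


@pytest.fixture(scope="session")
def small_study():
    """Three-condition synthetic study with ground truth (session-cached)."""
    config = SimConfig(n_genes=40, seed=11)
    models, truth = sample_models_and_rates(config)
    return config, models, truth
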