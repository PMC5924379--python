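import numpy as np
import pytest

from fedsimhash.cohort import CohortConfig, SitePartitionPlan, generate_cohort, partition_sites
from fedsimhash.features import (
    FeatureDomainSpec,
    SiteDataset,
    assemble_site,
    build_domain_vocabulary,
)
from fedsimhash.hashcore import HashConfig, HashModel, SiteAux

TARGET = "d_TARGET"
GAMMA = 0.01


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_patients=60, seed=3, signal_strength=2.0, positive_fraction=0.5)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_spec(small_cohort):
    return build_domain_vocabulary(small_cohort)


@pytest.fixture(scope="session")
def two_sites(small_cohort, cohort_spec):
    plan = SitePartitionPlan(M=2, per_site_sizes=(30, 30))
    parts = partition_sites(small_cohort, plan, seed=1)
    return [
        assemble_site(p, cohort_spec, GAMMA, TARGET, site_index=i) for i, p in enumerate(parts)
    ]


def make_toy_instance(seed: int, d: int = 3, b: int = 2, n: int = 4, xi: float = 0.5):
    """Random single-domain toy problem for derivative and solver checks."""
    r = np.random.default_rng(seed)
    vocab = tuple(f"l_{i}" for i in range(d))
    spec = FeatureDomainSpec((("l", vocab),))
    P = r.normal(size=(d, n))
    labels = r.integers(0, 2, size=n)
    if len(np.unique(labels)) < 2:
        labels[0] = 1 - labels[1]
    site = SiteDataset(0, spec, {"l": P}, labels)
    cfg = HashConfig(bits_per_domain=(b,), seed=seed, xi=xi)
    model = HashModel(spec, {"l": r.normal(size=(d, b))})
    aux = SiteAux(0, {"l": r.normal(size=(b, n))})
    return model, aux, site, cfg
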