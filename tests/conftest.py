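import numpy as np
import pytest

from ctmrd.ddpcr import WellCounts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_well(k_target, n_droplets, well_id="w1", role="patient",
              species="T", k_double=0, partner="W", k_partner=0):
    """Single- or two-species well with explicit cluster counts."""
    counts = {}
    if k_target:
        counts[frozenset({species})] = k_target
    if k_partner:
        counts[frozenset({partner})] = k_partner
    if k_double:
        counts[frozenset({species, partner})] = k_double
    counts[frozenset()] = n_droplets - sum(counts.values())
    return WellCounts(well_id=well_id, role=role, n_droplets=n_droplets,
                      cluster_counts=counts)


@pytest.fixture
def make_well_factory():
    return make_well
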