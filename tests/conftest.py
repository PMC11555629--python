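import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ioscore as io

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> io.SimConfig:
    """A quick 3-species universe for unit tests."""
    return io.SimConfig(
        n_species=3,
        n_orthologs=200,
        presence_prob=0.9,
        pairs_per_species=(3, 2, 4),
        frac_up=0.05,
        frac_down=0.05,
        n_paralogs=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config) -> io.SimBundle:
    return io.simulate_bundle(small_config)


@pytest.fixture(scope="session")
def default_bundle() -> io.SimBundle:
    """The study-shaped default: 7 species, 31 pairs, 5000 orthologs."""
    return io.simulate_bundle(io.SimConfig(seed=11))


def make_manifest(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["species", "pair_id", "intersexual_sample", "ovary_sample"]
    )
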