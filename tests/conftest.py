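import pytest

from acidstab.fg_registry import default_registry, match_groups
from acidstab.stability import profile_stability
from acidstab.synthdata import SynthSpec, gen_atmosphere, gen_molecule_set, gen_rate_grids


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def synth_spec():
    return SynthSpec(seed=7)


@pytest.fixture(scope="session")
def rate_library(synth_spec):
    return gen_rate_grids(synth_spec)


@pytest.fixture(scope="session")
def venus_profile(synth_spec):
    return gen_atmosphere(synth_spec)


@pytest.fixture(scope="session")
def monotone_profile():
    return gen_atmosphere(SynthSpec(seed=7, dip=False))


@pytest.fixture(scope="session")
def synthetic_dataset(synth_spec):
    return gen_molecule_set(synth_spec, 100)


@pytest.fixture(scope="session")
def dataset_matches(synthetic_dataset, registry):
    return [match_groups(r, registry) for r in synthetic_dataset.records]


@pytest.fixture(scope="session")
def dataset_results(dataset_matches, rate_library, venus_profile):
    return profile_stability(dataset_matches, rate_library, venus_profile)
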