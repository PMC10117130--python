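import pytest

from ssfkin import SSFKineticsModel, datasets


@pytest.fixture(scope="session")
def cs_tv52j_fixture():
    return datasets.get_fixture("CS-TV52J")


@pytest.fixture(scope="session")
def noisefree_bundle(cs_tv52j_fixture):
    """Noise-free CS-TV52J dataset on the 30-day batch design."""
    return datasets.generate_treatment_dataset(
        cs_tv52j_fixture, noise=None, n_replicates=1, seed=0
    )


@pytest.fixture(scope="session")
def noisefree_fit(noisefree_bundle):
    """Full staged calibration of the noise-free CS-TV52J dataset.

    Session-scoped: several modules check different facets of this one fit.
    """
    return SSFKineticsModel.from_dataset(noisefree_bundle).fit()
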