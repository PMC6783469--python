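import pytest

import spectriage as sp


@pytest.fixture(scope="session")
def small_cohort():
    """10 cancer + 10 control simulated patients, default generator settings."""
    config = sp.SimulationConfig(seed=42)
    manifest, collection = sp.simulate_cohort(config, sp.CohortDesignSpec(10, 10))
    return config, manifest, collection


@pytest.fixture(scope="session")
def small_features(small_cohort):
    _, manifest, collection = small_cohort
    return manifest, sp.preprocess_collection(collection, manifest=manifest)


@pytest.fixture(scope="session")
def retrospective_manifest():
    return sp.builtin_fixture("retrospective_table1")


@pytest.fixture()
def noiseless_config():
    """Simulator with every variance component switched off."""
    return sp.SimulationConfig(
        sigma_patient=0.0,
        sigma_well=0.0,
        sigma_noise=0.0,
        baseline_scale=0.0,
        si_band_amplitude=0.0,
        seed=7,
    )
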