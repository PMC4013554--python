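import pytest

from dmforecast import GeneratorParams, generate_bundle, reference_hazards


@pytest.fixture(scope="session")
def hazards():
    return reference_hazards()


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic bundle with survey jitter, fixed seed."""
    return generate_bundle(GeneratorParams(random_seed=20))


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Bundle whose survey points lie exactly on the configured lines."""
    return generate_bundle(GeneratorParams(noise_sd=0.0, random_seed=0))
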