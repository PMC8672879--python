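import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20211215)


@pytest.fixture(scope="session")
def random_sequences(rng):
    """Random standard-alphabet sequences of length 1-500."""
    alphabet = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
    seqs = []
    for _ in range(1000):
        n = int(rng.integers(1, 501))
        seqs.append(alphabet[rng.integers(0, 20, size=n)].tobytes().decode("ascii"))
    return seqs


@pytest.fixture(scope="session")
def synthetic_study():
    """One seeded five-class study reused by the pipeline tests."""
    from halocharge.profiling import profile_strain
    from halocharge.synthetic import GeneratorConfig, make_study

    config = GeneratorConfig(seed=11, n_strains_per_class=2, proteome_size=40)
    study = make_study(config)
    profiles = [profile_strain(s.records, s.metadata) for s in study.strains]
    return study, profiles
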