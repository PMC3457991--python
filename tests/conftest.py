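import pytest

from mirindel.simulate import GeneratorConfig, generate


@pytest.fixture(scope="session")
def bundle():
    """One full synthetic fixture shared across tests (deterministic)."""
    return generate(GeneratorConfig(rng_seed=7))


@pytest.fixture(scope="session")
def small_bundle():
    """A lighter fixture without panel for quick scans."""
    return generate(GeneratorConfig(
        rng_seed=3, genome_length=200_000, n_mirnas=12, n_utrs=15,
        n_footprints=20, make_panel=False))
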