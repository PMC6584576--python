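import pytest
from hypothesis import settings

from uvlinker.simulate import SimConfig, simulate_reads, simulate_reference

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_config():
    """A fast desk-scale genome: one 50 kb autosome, 20 kb U/V, one
    contaminant, no organelles."""
    return SimConfig(
        n_autosomes=1, autosome_len=50_000, u_len=20_000, v_len=20_000,
        organelle_lens=(), n_contaminants=1, contam_len=20_000,
        contam_read_fraction=0.3, depth=20.0, seed=7)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return simulate_reference(small_config)


@pytest.fixture(scope="session")
def small_reads(small_reference):
    male = simulate_reads(small_reference, "male", depth=20.0, seed=71,
                          contam_read_fraction=0.3)
    female = simulate_reads(small_reference, "female", depth=20.0, seed=72,
                            contam_read_fraction=0.3)
    return male, female
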