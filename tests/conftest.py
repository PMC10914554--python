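import pytest

from meiobar import SimulationConfig, run_synthetic_study


def toy_config(seed: int = 1, **overrides) -> SimulationConfig:
    """A small two-site study used by fast unit/integration tests."""
    base = dict(
        n_sites=2, depths_m=(54, 394), n_species=8, n_background_species=3,
        n_other_species=1, reads_per_slice=120, seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def toy_study():
    """Toy noisy study through the full pipeline."""
    return run_synthetic_study(toy_config(seed=1), n_perm=10, diversity_boot=50)


@pytest.fixture(scope="session")
def default_noiseless_study():
    """The default study design with sequencing noise and background reads
    switched off; the regime in which the pipeline must recover the planted
    truth exactly."""
    return run_synthetic_study(
        SimulationConfig(seed=11).noiseless(),
        n_perm=10, diversity_boot=50, run_bioenv=False,
    )


@pytest.fixture(scope="session")
def default_study():
    """The default study design at its stated conditions (8.9% background
    reads, sequencing errors on)."""
    return run_synthetic_study(SimulationConfig(seed=11), n_perm=20, diversity_boot=50)
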