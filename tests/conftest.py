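import numpy as np
import pytest

from mircoloc import SimulationParams, simulate_field


def small_params(**overrides) -> SimulationParams:
    """A 512x512 field with 4 cells: fast enough for unit tests."""
    base = dict(
        field_size_px=(512, 512),
        n_cells=4,
        cell_radius_um=(5.0, 6.5),
        nucleus_radius_um=(2.0, 3.0),
        seed=7,
    )
    base.update(overrides)
    return SimulationParams(**base)


def noise_free(**overrides) -> SimulationParams:
    """Same field without shot/read noise and without background."""
    return small_params(
        shot_noise=False,
        read_noise_sd=0.0,
        background_level={r: 0.0 for r in
                          ("nucleus", "cytoplasm", "mve",
                           "mirna_guide", "mirna_passenger")},
        **overrides,
    )


@pytest.fixture(scope="session")
def small_field():
    return simulate_field(small_params())


@pytest.fixture(scope="session")
def clean_field():
    return simulate_field(noise_free())


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
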