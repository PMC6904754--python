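import pytest

from placfbv import AcquisitionParams, PhantomConfig, build_phantom


@pytest.fixture
def acq() -> AcquisitionParams:
    """The standard acquisition: TR 20 ms, TE 3.5 ms, 5 flip angles."""
    return AcquisitionParams()


@pytest.fixture
def small_config() -> PhantomConfig:
    """A 48^3 noiseless phantom config small enough for fast unit tests."""
    return PhantomConfig.for_age(
        "E14.5", grid_shape=(48, 48, 48), n_fpu=4, fpu_fractions=(0.47,) * 4
    )


@pytest.fixture
def small_phantom(small_config):
    return build_phantom(small_config)
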