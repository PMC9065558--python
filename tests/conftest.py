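import pytest

from qmrikit import (
    InsertPhantomSpec,
    MagicProtocol,
    MeseProtocol,
    VfaProtocol,
    make_insert_phantom,
)


@pytest.fixture(scope="session")
def vfa_protocol():
    return VfaProtocol()


@pytest.fixture(scope="session")
def mese_protocol():
    return MeseProtocol()


@pytest.fixture(scope="session")
def magic_protocol():
    return MagicProtocol()


@pytest.fixture(scope="session")
def small_spec():
    """Insert phantom at coarse 2.04 mm pixels: same physical layout, 4x fewer voxels."""
    return InsertPhantomSpec(pixel_size_mm=(2.04, 2.04), shape=(64, 64))


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_insert_phantom(small_spec)
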