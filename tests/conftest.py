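import numpy as np
import pytest

from perfrad import imaging, synth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_phantom():
    """One default noisy phantom with its ground truth (session-cached)."""
    spec = synth.PhantomSpec(seed=7)
    vol, mask = synth.generate_phantom(spec)
    return spec, vol, mask


@pytest.fixture()
def random_volume_mask(rng):
    """A random 20x20x20 HU field with an irregular blob mask."""
    vox = rng.normal(30.0, 40.0, size=(20, 20, 20))
    zz, yy, xx = np.meshgrid(*[np.arange(20)] * 3, indexing="ij")
    blob = ((zz - 10.0) ** 2 / 36 + (yy - 9.0) ** 2 / 25 + (xx - 11.0) ** 2 / 16) <= 1.0
    blob |= rng.random((20, 20, 20)) < 0.002
    spacing = (1.25, 1.0, 0.8)
    return (
        imaging.CTVolume(vox, spacing),
        imaging.BinaryMask(blob.astype(np.uint8), spacing),
    )
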