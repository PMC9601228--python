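import numpy as np
import pytest

from mammotensor.enrichment import BreastMask, MultichannelImage, N_CHANNELS
from mammotensor.phantoms import ClassMix, PhantomSpec, generate_cohort
from mammotensor.sampling import Patch


def make_mci(h=128, w=128, mask=None, seed=0):
    """A synthetic multichannel object with arbitrary channel content."""
    rng = np.random.default_rng(seed)
    channels = rng.random((h, w, N_CHANNELS))
    if mask is None:
        mask = np.ones((h, w), dtype=np.uint8)
    return MultichannelImage(channels, tuple(f"ch{i}" for i in range(N_CHANNELS)),
                             BreastMask(mask))


def make_patch(sps=64, labels=None, seed=0, patch_id=0):
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = np.zeros((sps, sps), dtype=np.uint8)
    return Patch(block=rng.random((sps, sps, N_CHANNELS)), labels=labels,
                 origin=(0, 0), source_id=f"p{patch_id}")


@pytest.fixture(scope="session")
def small_cohort():
    """Six small phantoms (2 with masses, 2 healthy, 2 with calcifications)."""
    return generate_cohort(6, PhantomSpec(image_size=(160, 160)),
                           ClassMix(1 / 3, 1 / 3), seed=7)
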