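import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from cmrseg.core import SequenceKind
from cmrseg.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_cine():
    """A small noiseless cine phantom with its truth."""
    spec = PhantomSpec(kind=SequenceKind.CINE, n_frames=8, n_slices=5, noise_sd=0.0, seed=3)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def small_lge():
    spec = PhantomSpec(kind=SequenceKind.LGE, n_slices=5, noise_sd=0.0, seed=4)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def small_t1():
    spec = PhantomSpec(kind=SequenceKind.T1_NATIVE, n_slices=5, noise_sd=0.0, seed=5)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def small_flow():
    spec = PhantomSpec(kind=SequenceKind.FLOW, n_frames=16, noise_sd=0.0, seed=6)
    return make_phantom(spec)


def random_blob(rng, shape, p=0.5, smooth=1.5):
    """A random connected-ish blob by thresholding smoothed noise."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), smooth)
    thr = np.quantile(field, 1 - p * rng.uniform(0.2, 0.8))
    blob = field > thr
    if not blob.any():
        blob[tuple(d // 2 for d in shape)] = True
    return blob
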