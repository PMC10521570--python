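import numpy as np
import pytest

from strokeseg.io import SlicePair
from strokeseg.phantom import PhantomParams, generate_cohort


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """Reduced phantom geometry for cheap I/O and preprocessing tests."""
    return PhantomParams(n_subjects=2, slices_per_volume=16, height=64, width=64,
                         lesion_slice_range=(4, 7), lesion_radius_range=(3.0, 8.0),
                         seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return generate_cohort(small_params)


@pytest.fixture
def asymmetric_slice() -> SlicePair:
    """A square slice with no rotational or mirror symmetry."""
    rng = np.random.default_rng(5)
    img = rng.random((16, 16)).astype(np.float32)
    mask = np.zeros((16, 16), dtype=np.uint8)
    mask[2:5, 9:14] = 1
    return SlicePair(image=img, mask=mask, subject_id="sub-x", modality="DWI",
                     slice_index=0)
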