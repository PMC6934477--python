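import numpy as np
import pytest

from srtrad.cohort import CohortConfig, generate_cohort
from srtrad.masks import make_margin_masks


@pytest.fixture(scope="session")
def small_cohort():
    """12-patient synthetic cohort with the default planted effects."""
    cfg = CohortConfig(n_patients=12, seed=7)
    lesions, survival = generate_cohort(cfg)
    return cfg, lesions, survival


@pytest.fixture(scope="session")
def one_lesion(small_cohort):
    _, lesions, _ = small_cohort
    return lesions[0]


@pytest.fixture(scope="session")
def one_lesion_masks(one_lesion):
    return make_margin_masks(
        one_lesion.tumour_mask,
        one_lesion.edema_mask,
        one_lesion.voxel_size_mm,
        margin_mm=3.0,
    )


@pytest.fixture(scope="session")
def ball_mask():
    """Solid ball of radius 10 voxels in a 28^3 grid."""
    shape = (28, 28, 28)
    c = (np.array(shape) - 1) / 2.0
    coords = np.indices(shape)
    dist = np.sqrt(sum((coords[a] - c[a]) ** 2 for a in range(3)))
    return dist <= 10.0


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
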