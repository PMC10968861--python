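import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from deltarad.io_core import ScanPair
from deltarad.synthetic_cohort import CohortSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten-subject noiseless-ish cohort shared by several module tests."""
    spec = CohortSpec(
        n_subjects=10, grid_shape=(32, 32, 32), spacing=(3.0, 3.0, 3.0),
        radius_range_mm=(12.0, 20.0), pet_noise_sd=0.1, seed=7,
    )
    return simulate_cohort(spec)


def sphere_scan(radius_vox=5, shape=(16, 16, 16), spacing=(2.0, 2.0, 2.0),
                peak=10.0, background=1.0, exponent=1.0, subject="phantom"):
    """Deterministic noise-free spherical phantom ScanPair."""
    center = (np.array(shape) - 1) / 2.0
    idx = np.indices(shape)
    r = np.sqrt(((idx - center[:, None, None, None]) ** 2).sum(axis=0))
    mask = (r <= radius_vox).astype(np.uint8)
    pet = background + np.where(mask, peak * (1 - (r / radius_vox) ** exponent), 0.0)
    ct = 40.0 + 25.0 * mask
    return ScanPair(subject_id=subject, timepoint="baseline", pet=pet, ct=ct,
                    mask=mask, spacing=spacing)
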