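import numpy as np
import pytest

from attr2unet.records import SliceRecord
from attr2unet.synthetic import CohortSpec, PhantomSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small 32x32 phantom cohort (10 patients) for pipeline-level tests."""
    spec = CohortSpec(
        n_patients=10,
        slices_per_patient=(2, 4),
        phantom=PhantomSpec(image_side=32, lesion_area_fraction=(0.01, 0.08), seed=7),
    )
    records, manifest = generate_cohort(spec)
    return records, manifest


@pytest.fixture
def checker_record():
    """A deterministic 12x12 record with a centred square lesion."""
    image = np.linspace(0, 1, 144).reshape(12, 12)
    mask = np.zeros((12, 12), dtype=np.uint8)
    mask[4:8, 5:9] = 1
    return SliceRecord("P000", 0, image, mask)
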