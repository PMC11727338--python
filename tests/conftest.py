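import numpy as np
import pytest

from attnseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    return generate_phantom(
        PhantomSpec(image_size=64, n_lesions=1, lesion_radius_range=(8, 12), seed=3)
    )


def random_mask_pairs(n, size=16, p=0.3, seed=0):
    """Seeded random binary mask pairs for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(
            (
                (rng.random((size, size)) < p).astype(np.uint8),
                (rng.random((size, size)) < p).astype(np.uint8),
            )
        )
    return out
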