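import numpy as np
import pytest

from ovicount import preprocess, random_well_spec, render_well


@pytest.fixture(scope="session")
def clean_well():
    """One noise-free well with 8 planted non-overlapping eggs."""
    spec = random_well_spec(1, n_eggs=8)
    img, truth = render_well(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def clean_preprocessed(clean_well):
    _, img, _ = clean_well
    return preprocess(img)


def random_masks(rng: np.random.Generator, n: int, shape=(48, 48), min_side=5, max_side=16):
    """Random axis-aligned rectangle masks for matching/NMS property tests."""
    masks = []
    h, w = shape
    for _ in range(n):
        sh = int(rng.integers(min_side, max_side))
        sw = int(rng.integers(min_side, max_side))
        r0 = int(rng.integers(0, h - sh))
        c0 = int(rng.integers(0, w - sw))
        m = np.zeros(shape, dtype=bool)
        m[r0:r0 + sh, c0:c0 + sw] = True
        masks.append(m)
    return masks
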