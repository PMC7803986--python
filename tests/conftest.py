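import numpy as np
import pytest

from stlseg.data_prep import PatchMaskPair, crop_roi_patches, resize_pair
from stlseg.synthetic_data import SyntheticConfig, generate_dataset


def make_pair(h=4, w=4, target=3, fg=None, seed=0, source="t:box0",
              transform="identity"):
    """Small asymmetric patch-mask pair for transform tests."""
    rng = np.random.default_rng(seed)
    patch = rng.integers(0, 255, size=(h, w, 3), dtype=np.uint8)
    mask = np.zeros((h, w), dtype=np.int64)
    if fg is None:
        mask[: h // 2, : w // 2] = target
    else:
        mask[fg] = target
    return PatchMaskPair(patch=patch, mask=mask, target_class=target,
                         source_id=source, transform=transform)


@pytest.fixture(scope="session")
def small_synthetic():
    """A 3x3-family synthetic dataset with its designed hierarchy."""
    cfg = SyntheticConfig(family_color_spread=100.0, class_color_spread=10.0,
                          seed=7)
    trays, designed = generate_dataset(cfg, n_trays=12, seed=3)
    return cfg, trays, designed


@pytest.fixture(scope="session")
def small_pairs(small_synthetic):
    """Resized 64x64 single-class pairs from the synthetic dataset."""
    _, trays, _ = small_synthetic
    return [resize_pair(p, (64, 64)) for p in crop_roi_patches(trays)]
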