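import numpy as np
import pytest

from pterymeter.stats import CrossTab


@pytest.fixture(scope="session")
def staging_crosstab() -> CrossTab:
    """Published 3-class staging crosstab (visual inspection vs prediction)."""
    return CrossTab(np.array([[121, 0, 0], [0, 68, 8], [0, 4, 38]]))


@pytest.fixture(scope="session")
def smoke_set():
    """Eight 96x96 pterygium phantoms for CPU-scale training checks.

    Fat wedges (~5% foreground) keep the class imbalance mild enough for a
    small network to overfit quickly.
    """
    from pterymeter.synthetic import generate_phantom, sample_params

    rng = np.random.default_rng(42)
    ranges = {"semi_axis_px": (32.0, 42.0), "center_jitter_px": 4.0,
              "invasion_fraction": (0.5, 0.9), "wedge_half_angle": (0.5, 0.7)}
    images, masks = [], []
    for i in range(8):
        p = sample_params(rng, with_pterygium=True, param_ranges=ranges,
                          image_size=96)
        s = generate_phantom(p, seed=i)
        images.append(s.image.transpose(2, 0, 1).astype(np.float32) / 255.0)
        masks.append(s.pterygium_mask[None].astype(np.float32))
    return np.stack(images), np.stack(masks)
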