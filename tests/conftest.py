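import numpy as np
import pytest
from PIL import Image

from selfieplaque import SmileSpec, generate_smile


@pytest.fixture()
def rng():
    return np.random.default_rng(20220901)


@pytest.fixture(scope="session")
def default_smile():
    """One mid-coverage synthetic smile shared across read-only tests."""
    return generate_smile(SmileSpec(target_fraction_pct=25.0, seed=42))


@pytest.fixture()
def smile_on_disk(tmp_path, default_smile):
    """Synthetic smile written out as PNG image + mask files."""
    img_path = tmp_path / "smile.png"
    mask_path = tmp_path / "mask.png"
    Image.fromarray(default_smile.image).save(img_path)
    Image.fromarray(default_smile.mask.astype(np.uint8) * 255).save(mask_path)
    return img_path, mask_path, default_smile
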