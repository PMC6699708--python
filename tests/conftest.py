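import numpy as np
import pytest

from melonqmon.features import features_to_frame, extract_features
from melonqmon.segmentation import segment
from melonqmon.synthetic import CohortSpec, generate_cohort, generate_scene


@pytest.fixture(scope="session")
def small_cohort():
    """12 fruits x 3 views at 240x240: records + phenotype table."""
    spec = CohortSpec(n_fruits=12, views_per_fruit=3, image_size=(240, 240), seed=7)
    records, phenotypes = generate_cohort(spec)
    return spec, records, phenotypes


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    """Feature table extracted end to end from the small cohort."""
    _, records, phenotypes = small_cohort
    rows = []
    for rec in records:
        image, _ = generate_scene(rec.params)
        mask, t = segment(image)
        fv = extract_features(image, mask, image_id=rec.image_id, mask_threshold=t)
        rows.append((rec.image_id, rec.fruit_id, rec.view, fv))
    return features_to_frame(rows), phenotypes


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
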