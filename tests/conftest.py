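import numpy as np
import pytest

from plantgrow.core_types import InstanceMask, PlantRecord, RGBFrame
from plantgrow.synthetic_plants import SynthConfig, generate_plant_record


@pytest.fixture(scope="session")
def small_record() -> PlantRecord:
    """A 32x32, 8-frame, 3-leaf synthetic rosette used across modules."""
    cfg = SynthConfig(image_size=32, n_frames=8, max_leaves=3, seed=7)
    return generate_plant_record(cfg)


@pytest.fixture(scope="session")
def medium_record() -> PlantRecord:
    """A 64x64, 12-frame, 4-leaf record for augmentation/metrics tests."""
    cfg = SynthConfig(image_size=64, n_frames=12, max_leaves=4, seed=11)
    return generate_plant_record(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_disjoint_leaf_record(size=32, n_frames=5, n_classes=9) -> PlantRecord:
    """Two square leaves that grow but never overlap nor touch the border."""
    frames = []
    for t in range(n_frames):
        rgb = np.full((size, size, 3), 0.3, dtype=np.float32)
        mask = np.zeros((size, size), dtype=np.int64)
        s1 = 3 + t  # leaf 1 grows
        mask[4 : 4 + s1, 4 : 4 + s1] = 1
        rgb[4 : 4 + s1, 4 : 4 + s1] = (0.2, 0.6, 0.2)
        if t >= 1:
            s2 = 2 + t
            mask[20 : 20 + s2, 18 : 18 + s2] = 2
            rgb[20 : 20 + s2, 18 : 18 + s2] = (0.1, 0.5, 0.3)
        frames.append((RGBFrame(rgb), InstanceMask(mask, n_classes=n_classes)))
    return PlantRecord(plant_id="disjoint", viewpoint="vp0", frames=frames)


@pytest.fixture()
def disjoint_record() -> PlantRecord:
    return make_disjoint_leaf_record()
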