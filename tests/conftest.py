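import numpy as np
import pytest

from octdet.data_io import AnnotatedRecord, BoundingBox, BoxArray, ScanImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def single_box_record(rng):
    """A 64x64 scan with one box, for quick geometric tests."""
    img = ScanImage(id="r0", pixels=rng.random((64, 64)))
    boxes = BoxArray.from_boxes([BoundingBox(0.2, 0.3, 0.5, 0.6)], 3)
    return AnnotatedRecord(image=img, boxes=boxes)


def random_box(rng, min_size: float = 0.01) -> BoundingBox:
    """Uniform random valid box with both sides at least min_size."""
    while True:
        x = np.sort(rng.random(2))
        y = np.sort(rng.random(2))
        if x[1] - x[0] >= min_size and y[1] - y[0] >= min_size:
            return BoundingBox(x[0], y[0], x[1], y[1])
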