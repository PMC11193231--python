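import numpy as np
import pytest

from gazewalk import (
    CameraModel,
    ClassTaxonomy,
    CornerBox,
    Detection,
    FrameSize,
    build_default_layout,
)


@pytest.fixture(scope="session")
def taxonomy():
    return ClassTaxonomy.default()


@pytest.fixture(scope="session")
def fs():
    return FrameSize(1920, 1080)


@pytest.fixture(scope="session")
def camera():
    return CameraModel()


@pytest.fixture
def rng():
    return np.random.default_rng(20240622)


@pytest.fixture(scope="session")
def layout():
    return build_default_layout(body_height=1.66, seed=3)


def random_box(rng, lo=0.0, hi=1000.0, integer=False):
    a = rng.uniform(lo, hi, size=2)
    b = rng.uniform(lo, hi, size=2)
    x1, x2 = sorted((a[0], b[0]))
    y1, y2 = sorted((a[1], b[1]))
    if integer:
        x1, y1, x2, y2 = (float(int(v)) for v in (x1, y1, x2, y2))
    return CornerBox(x1, y1, x2, y2)


def random_detection(rng, labels=("hurdle", "tennis_ball", "support"), **kw):
    return Detection(
        box=random_box(rng, **kw),
        class_label=str(rng.choice(labels)),
        confidence=float(rng.uniform(0, 1)),
    )
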