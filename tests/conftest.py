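import numpy as np
import pytest

from solwrite import detection, fixtures


@pytest.fixture(scope="session")
def rendered():
    """name -> (ShapeImage, ground-truth Shape) for every built-in fixture."""
    return {
        name: fixtures.render_shape_image(spec)
        for name, spec in fixtures.BUILTIN_SHAPES.items()
    }


@pytest.fixture(scope="session")
def detected(rendered):
    """name -> Shape produced by the full detection pipeline (seed 0)."""
    return {
        name: detection.build_shape(img, rng_seed=0, name=name)
        for name, (img, _) in rendered.items()
    }


@pytest.fixture(scope="session")
def m_truth():
    return fixtures.ground_truth_shape(fixtures.builtin_stroke_spec("M"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
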