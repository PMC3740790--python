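import numpy as np
import pytest

from regnull import SceneSpec, copy_shift_paste, render_scene


@pytest.fixture
def default_spec():
    """The canonical scene: 206x256 canvas, 156x196 region, shift 50."""
    return SceneSpec(seed=7)


@pytest.fixture
def default_scene(default_spec):
    fixed = render_scene(default_spec)
    moving, truth = copy_shift_paste(fixed, default_spec)
    return fixed, moving, truth


@pytest.fixture
def small_spec():
    """A small scene for fast geometry checks: 20x16 canvas, 12x10 region, shift 4."""
    return SceneSpec(width=20, height=16, region_width=12, region_height=10,
                     shift=4, seed=3)


@pytest.fixture
def small_scene(small_spec):
    fixed = render_scene(small_spec)
    moving, truth = copy_shift_paste(fixed, small_spec)
    return fixed, moving, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
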