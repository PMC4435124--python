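import numpy as np
import pytest

from berrypheno import SceneSpec, fit_one_class_model, render_scene, run_detection_benchmark
from berrypheno.benchmark import training_patches


@pytest.fixture(scope="session")
def default_scene():
    """One deterministic default scene with its ground truth."""
    return render_scene(SceneSpec(seed=3))


@pytest.fixture(scope="session")
def nonoverlap_scene():
    """Scene with strictly disjoint berries (clean color-extraction oracle)."""
    return render_scene(SceneSpec(seed=11, n_berries=10, max_overlap=0.0))


@pytest.fixture(scope="session")
def trained_one_class_model():
    """One-class model fitted on truth patches from 8 training scenes."""
    specs = [SceneSpec(seed=500 + i) for i in range(8)]
    return fit_one_class_model(training_patches(specs))


@pytest.fixture(scope="session")
def standard_benchmark():
    """The 50-scene synthetic detection benchmark, seeds fixed."""
    return run_detection_benchmark(n_scenes=50, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
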