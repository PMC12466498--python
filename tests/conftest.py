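import numpy as np
import pytest

from chickendet.synth import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Ten small synthetic scenes in YOLO layout (session-wide, read-only)."""
    out = tmp_path_factory.mktemp("tinyds")
    manifest = generate_dataset(10, out, seed=42, size=96)
    return manifest


@pytest.fixture(scope="session")
def baseline_model():
    from chickendet.scaffold import build_yolo11n_baseline

    return build_yolo11n_baseline(num_classes=1, seed=0)
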