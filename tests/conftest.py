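import numpy as np
import pytest

from thermasym import generate_face
from thermasym.synthgen import FacePhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom():
    """One noisy healthy phantom with ground truth."""
    return generate_face(seed=7)


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Exactly mirror-symmetric phantom (noise SD 0)."""
    return generate_face(FacePhantomConfig(noise_sd=0.0), seed=0)


@pytest.fixture(scope="session")
def default_cohort():
    """The standard 45 + 45 synthetic cohort, fixed seed."""
    from thermasym import generate_cohort

    return generate_cohort(seed=0)


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    """Feature-symmetry table of the default cohort via the full automatic
    pipeline (segmentation included), plus its metadata."""
    from thermasym import cohort_feature_table
    from thermasym.synthgen import cohort_metadata

    features = cohort_feature_table(default_cohort)
    metadata = cohort_metadata(default_cohort)
    return features, metadata
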