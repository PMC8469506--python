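import numpy as np
import pytest

from endospectra import FeatureExpansionSpec, fit_conversion_matrix
from endospectra.stages import StageLabel
from endospectra.synth import (
    Lesion,
    SceneSpec,
    TissueSpectrumModel,
    capture_color_target,
    make_color_target,
    render_rgb,
    wli_camera,
)


@pytest.fixture(scope="session")
def seed1_target():
    return make_color_target(seed=1)


@pytest.fixture(scope="session")
def wli_cam():
    return wli_camera()


@pytest.fixture(scope="session")
def tissue_model():
    return TissueSpectrumModel(seed=1)


@pytest.fixture(scope="session")
def seed1_matrix(seed1_target, wli_cam):
    rgbs = capture_color_target(seed1_target, wli_cam)
    return fit_conversion_matrix(rgbs, seed1_target, FeatureExpansionSpec(degree=3),
                                 ridge=1e-6, rgb_is_linear=False)


@pytest.fixture(scope="session")
def seed1_scene(tissue_model, wli_cam):
    """A 128x128 two-lesion scene rendered through the WLI camera."""
    spec = SceneSpec(width=128, height=128, lesions=(
        Lesion(center=(48.0, 48.0), axes=(20.0, 14.0), angle=0.4,
               stage=StageLabel.INVASIVE_CANCER),
        Lesion(center=(92.0, 90.0), axes=(16.0, 12.0), angle=1.1,
               stage=StageLabel.LOW_GRADE_DYSPLASIA),
    ), seed=1)
    return render_rgb(spec, tissue_model, wli_cam)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
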