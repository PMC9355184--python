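import numpy as np
import pytest

from photic_sim import SceneConfig, build_scene


@pytest.fixture(scope="session")
def scene6_absorbing():
    return build_scene(SceneConfig(iol_diameter_mm=6, edge_mode="absorbing"))


@pytest.fixture(scope="session")
def scene6_reflective():
    return build_scene(SceneConfig(iol_diameter_mm=6, edge_mode="reflective"))


@pytest.fixture(scope="session")
def scene7_absorbing():
    return build_scene(SceneConfig(iol_diameter_mm=7, edge_mode="absorbing"))


@pytest.fixture(scope="session")
def cornea_only_scene(scene6_absorbing):
    """The eye stripped to the two corneal surfaces and the retina."""
    from photic_sim.eye_model import EyeScene

    base = scene6_absorbing
    surfaces = [base.surface("cornea_front"), base.surface("cornea_back"),
                base.surface("retina")]
    return EyeScene(surfaces=surfaces, media=base.media, edge_mode="absorbing",
                    config=base.config, fovea_center=np.array([0.0, 0.0, 23.95]))
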