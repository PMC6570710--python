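import numpy as np
import pytest

from colodepth import scene_sim as ss


@pytest.fixture(scope="session")
def cylinder_spec():
    """Straight plain cylinder: every geometric quantity has a closed form."""
    return ss.SceneSpec(
        centerline=((0.0, 0.0, 0.0), (0.0, 0.0, 30.0)),
        base_radius=1.5,
        fold_amplitude=0.0,
        fold_frequency=0.0,
    )


@pytest.fixture(scope="session")
def default_scene():
    return ss.default_scene(seed=0)


@pytest.fixture(scope="session")
def axis_pose():
    """Camera on the cylinder axis looking down +z."""
    return ss.CameraPose(
        position=(0.0, 0.0, 5.0),
        orientation=((1, 0, 0), (0, 1, 0), (0, 0, 1)),
    )


@pytest.fixture(scope="session")
def toy_pairs_32():
    """Small shared 32x32 paired dataset (rendered once per session)."""
    from colodepth.experiment import render_toy_dataset

    pairs, sh_train, sh_test = render_toy_dataset(
        20, 4, 3, size=32, seed=0, ray_step=0.1
    )
    return pairs, sh_train, sh_test
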