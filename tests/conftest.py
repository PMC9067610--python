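"""Shared fixtures.

The heavyweight paired-training experiments are session-scoped so that the
trend checks (loss curves, SSIM/ACC ordering, diffuser-swap comparison)
all reuse one set of runs.
"""

import numpy as np
import pytest

from speckleplane.experiments import ExperimentSpec, _camera_frame_renderer, run
from speckleplane.metrics import train_digit_classifier
from speckleplane.objects import generate_digits
from speckleplane.system import desk_config


@pytest.fixture(scope="session")
def desk_cfg():
    return desk_config()


@pytest.fixture(scope="session")
def digits20():
    return generate_digits(20, size=48, seed=1)


@pytest.fixture(scope="session")
def digit_classifier(desk_cfg):
    """The ACC classifier, trained once on clean camera-frame renderings."""
    objs = generate_digits(480, size=48, seed=7001)
    return train_digit_classifier(
        objs, seed=7, side=32, renderer=_camera_frame_renderer(desk_cfg)
    )


@pytest.fixture(scope="session")
def paired_experiment(tmp_path_factory, digit_classifier):
    """Three-seed paired object-plane vs diffuser-plane runs with an object
    between a weak front diffuser and a strong back diffuser."""
    out = tmp_path_factory.mktemp("between")
    spec = ExperimentSpec(
        name="between", condition="between_two_diffusers", seeds=(0, 1, 2)
    )
    return run(spec, out, classifier=digit_classifier)


@pytest.fixture(scope="session")
def swapped_experiment(tmp_path_factory, digit_classifier):
    """Three-seed object-plane runs with the diffusers swapped (weak D2)."""
    out = tmp_path_factory.mktemp("swapped")
    spec = ExperimentSpec(
        name="swapped",
        condition="swapped_diffusers",
        seeds=(0, 1, 2),
        image_plane="object",
    )
    return run(spec, out, classifier=digit_classifier)
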