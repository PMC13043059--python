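import numpy as np
import pytest

import roomlayout as rl


@pytest.fixture(scope="session")
def frame():
    return rl.ImageFrame(650, 520)


@pytest.fixture(scope="session")
def micro_geom(frame):
    """Hand-derived worked scene: V1=(-500,-100), V2=(700,-100) centered."""
    return rl.geometry_from_vps(
        rl.HomoPoint2D.finite(-500.0, -100.0),
        rl.HomoPoint2D.finite(700.0, -100.0),
        frame,
    )


@pytest.fixture(scope="session")
def scene_bank():
    """A reusable batch of noise-free synthetic scenes with varied poses."""
    return [rl.make_scene([2024, i], jitter_px=0.0) for i in range(12)]


@pytest.fixture(scope="session")
def pipeline_bank(scene_bank):
    return [(scene, rl.run_pipeline(scene)) for scene in scene_bank]


def centered(frame, xy):
    return np.asarray(xy, dtype=float) - frame.center
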