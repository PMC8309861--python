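import numpy as np
import pytest

from wscas import (
    BackboneConfig,
    RunConfig,
    SceneSpec,
    TrainConfig,
    generate_scene,
)
from wscas.io import run_pipeline


@pytest.fixture(scope="session")
def scene360():
    """A noiseless default-size scene with a 5-degree edge."""
    return generate_scene(SceneSpec(noise_sigma=0, edge_angle_deg=5.0,
                                    edge_bottom_x=200.0, seed=11))


@pytest.fixture(scope="session")
def small_scene():
    """A small noisy scene that admits 48 px class-pure patches."""
    return generate_scene(
        SceneSpec(width=120, height=120, horizon_row=56, edge_bottom_x=60.0,
                  edge_angle_deg=-2.0, noise_sigma=4.0, seed=5)
    )


def tiny_config(seed: int = 3) -> RunConfig:
    """A minutes-scale pipeline configuration for plumbing tests."""
    return RunConfig(
        seed=seed,
        scene=SceneSpec(width=120, height=120, horizon_row=56,
                        edge_bottom_x=58.0, edge_angle_deg=-2.0, noise_sigma=4.0),
        n_train_frames=12,
        n_test_frames=4,
        train_drift_bottom_x=0.2,
        train_drift_angle_deg=0.3,
        test_scene=SceneSpec(width=120, height=120, horizon_row=56,
                             edge_bottom_x=66.0, edge_angle_deg=-4.0, noise_sigma=4.0),
        test_drift_bottom_x=-0.8,
        test_drift_angle_deg=0.9,
        crop_size=48,
        backbone=BackboneConfig(input_size=48),
        train=TrainConfig(batch_size=16, patience=4, max_epochs=4),
        ipc_patch_size=40,
    )


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """One full (tiny) pipeline run shared across plumbing tests."""
    out = tmp_path_factory.mktemp("tiny-run")
    return run_pipeline(tiny_config(), out)


@pytest.fixture(scope="session")
def oracle_model():
    from wscas.testing import make_color_oracle_model

    return make_color_oracle_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
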