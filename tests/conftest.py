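import numpy as np
import pytest

from woundseg import (
    NetConfig,
    TrainConfig,
    build_group,
    build_network,
    remove_background,
    train,
)
from woundseg.skin_detection import SkinParams
from woundseg.synthetic_data import SceneSpec, generate_scene, generate_suite

# Desk-scale study conditions: 40 synthetic 160x160 sources split 30/10, the
# train side composed of raw + background-removed twins (the best-performing
# train/test composition, group 4), DM=0.25 network with 128x128 crops,
# 2000 steps of the standard schedule.
DESK_SUITE_SEED = 101
DESK_SPLIT_SEED = 7
DESK_TRAIN_SEED = 1
DESK_SCENE_SIZE = (160, 160)
DESK_INPUT_SIZE = 128
DESK_STEPS = 2000


def clutter_free_scene(category: int, seed: int, size=(512, 512)):
    return generate_scene(SceneSpec(category=category, size=size,
                                    background_clutter=0, seed=seed))


@pytest.fixture(scope="session")
def desk_group():
    """Group-4 train/test split over 40 desk-scale scenes.

    Returns (group, scenes) where ``scenes`` is the full source list (the
    test sources are ``scenes[i] for i in group.test_sources``).
    """
    scenes = generate_suite(40, seed=DESK_SUITE_SEED, size=DESK_SCENE_SIZE)
    raw = [(sc.image, sc.wound_mask) for sc in scenes]
    pre = [
        (remove_background(sc.image, SkinParams.pre_profile()), sc.wound_mask)
        for sc in scenes
    ]
    group = build_group(raw, pre, group_id=4, seed=DESK_SPLIT_SEED, test_fraction=0.25)
    return group, scenes


@pytest.fixture(scope="session")
def trained_toy_model(desk_group):
    """DM=0.25 network trained 2000 steps on the desk-scale group.

    Session-scoped: the scaled-down learning check, the correction check and
    the end-to-end pipeline check all reuse these weights and the log.
    """
    group, _ = desk_group
    network = build_network(NetConfig(depth_multiplier=0.25,
                                      input_size=DESK_INPUT_SIZE, seed=0))
    config = TrainConfig(total_steps=DESK_STEPS, eval_interval=200,
                         seed=DESK_TRAIN_SEED)
    network, log = train(network, group, config)
    return network, log


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
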