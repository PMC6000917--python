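import numpy as np
import pytest

from woundseg import _nn
from woundseg.preprocess import DatasetGroup
from woundseg.segnet import (
    MobileFCN,
    NetConfig,
    TrainConfig,
    build_network,
    epochs,
    load_checkpoint,
    lr_at,
    save_checkpoint,
    segment,
    train,
)
from woundseg.synthetic_data import generate_suite


class TestSchedule:
    @pytest.mark.parametrize(
        "step,expected",
        [(0, 0.01), (4999, 0.01), (10000, 0.01), (14999, 0.01),
         (15000, 0.005), (20000, 0.0025), (30000, 0.000625)],
    )
    def test_halving_schedule(self, step, expected):
        assert lr_at(step, TrainConfig()) == pytest.approx(expected)

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            lr_at(-1, TrainConfig())

    def test_non_increasing(self):
        cfg = TrainConfig()
        rates = [lr_at(s, cfg) for s in range(0, 60000, 500)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestEpochs:
    @pytest.mark.parametrize("args,expected", [((50000, 760, 5), 329),
                                               ((0, 760, 5), 0),
                                               ((152, 760, 5), 1)])
    def test_examples(self, args, expected):
        assert epochs(*args) == expected

    def test_zero_train_set_rejected(self):
        with pytest.raises(ValueError):
            epochs(1000, 0, 5)


class TestArchitecture:
    def test_parameter_count_monotone_in_depth_multiplier(self):
        counts = [build_network(NetConfig(depth_multiplier=dm)).parameter_count()
                  for dm in (0.25, 0.5, 1.0)]
        assert counts[0] < counts[1] < counts[2]

    def test_unsupported_depth_multiplier_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(depth_multiplier=0.75)

    @pytest.mark.parametrize("size", [(64, 64), (96, 64), (100, 90)])
    def test_output_resolution_matches_input(self, size, rng):
        net = build_network(NetConfig(depth_multiplier=0.25, input_size=64, seed=2))
        img = rng.integers(0, 256, size=size + (3,), dtype=np.uint8)
        prob = segment(net, img)
        assert prob.shape == size
        assert (prob >= 0).all() and (prob <= 1).all()

    def test_segment_is_deterministic(self, rng):
        net = build_network(NetConfig(depth_multiplier=0.25, input_size=64, seed=2))
        img = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        assert (segment(net, img) == segment(net, img)).all()


class TestBackpropagation:
    def test_gradients_match_finite_differences(self, rng):
        """Analytic directional derivatives agree with float64 central
        differences through the whole network (training-mode batch norm)."""
        net = build_network(NetConfig(depth_multiplier=0.25, input_size=32, seed=4))
        # promote to float64: finite differences at eps=1e-5 drown in
        # float32 rounding otherwise
        for p in net.params:
            p.value = p.value.astype(np.float64)
            p.grad = np.zeros_like(p.value)
        for bn in net._bn_layers():
            bn.running_mean = bn.running_mean.astype(np.float64)
            bn.running_var = bn.running_var.astype(np.float64)
        x = rng.normal(0, 1, (1, 3, 32, 32))
        y = (rng.random((1, 32, 32)) < 0.3).astype(np.int64)

        def loss_value():
            logits = net.forward(x, training=True)
            loss, _ = _nn.softmax_cross_entropy(logits, y)
            return loss

        logits = net.forward(x, training=True)
        _, dlogits = _nn.softmax_cross_entropy(logits, y)
        net.backward(dlogits.astype(np.float64))

        eps = 1e-5
        for i in rng.permutation(len(net.params))[:8]:
            param = net.params[int(i)]
            direction = rng.normal(0, 1, param.value.shape)
            direction /= np.sqrt(direction.size)
            analytic = float((param.grad * direction).sum())
            param.value += eps * direction
            up = loss_value()
            param.value -= 2 * eps * direction
            down = loss_value()
            param.value += eps * direction
            fd = (up - down) / (2 * eps)
            assert analytic == pytest.approx(fd, rel=1e-2, abs=1e-7)


@pytest.fixture(scope="module")
def tiny_group():
    scenes = generate_suite(4, seed=31, size=(64, 64))
    held = generate_suite(2, seed=32, size=(64, 64))
    return DatasetGroup(group_id=0, train=scenes, test=held)


class TestTraining:
    def test_loss_decreases(self, tiny_group):
        net = build_network(NetConfig(depth_multiplier=0.25, input_size=64, seed=0))
        cfg = TrainConfig(total_steps=60, eval_interval=60, seed=3)
        _, log = train(net, tiny_group, cfg, augment_training_data=False)
        assert np.mean(log["loss"][-10:]) < log["loss"][0]

    def test_same_seed_reproduces_loss_trajectory(self, tiny_group):
        losses = []
        for _ in range(2):
            net = build_network(NetConfig(depth_multiplier=0.25, input_size=64, seed=0))
            cfg = TrainConfig(total_steps=25, eval_interval=25, seed=3)
            _, log = train(net, tiny_group, cfg, augment_training_data=False)
            losses.append(log["loss"])
        assert losses[0] == losses[1]

    def test_empty_training_set_rejected(self):
        net = build_network(NetConfig(depth_multiplier=0.25, input_size=64))
        group = DatasetGroup(group_id=0, train=[], test=[])
        with pytest.raises(ValueError):
            train(net, group, TrainConfig(total_steps=5))

    def test_checkpoint_roundtrip(self, tiny_group, tmp_path, rng):
        net = build_network(NetConfig(depth_multiplier=0.25, input_size=64, seed=0))
        cfg = TrainConfig(total_steps=10, eval_interval=10, seed=3)
        net, _ = train(net, tiny_group, cfg, augment_training_data=False)
        path = tmp_path / "model.npz"
        save_checkpoint(net, str(path))
        restored = load_checkpoint(str(path))
        img = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        np.testing.assert_array_equal(segment(net, img), segment(restored, img))
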