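import numpy as np
import pytest

from ecgdenoise import ParameterError, RCEDConfig, TrainConfig, build_rced, predict, train_rced
from ecgdenoise.nn import BatchNorm1d, Conv1d, ReLU

SMALL = RCEDConfig(n_blocks=4, filter_counts=(12, 16, 12, 1), kernel_widths=(9, 7, 9, 65))


class TestArchitecture:
    def test_default_has_sixteen_conv_blocks(self):
        net = build_rced(RCEDConfig(), seed=0)
        convs = [l for l in net.layers if isinstance(l, Conv1d)]
        assert len(convs) == 16
        assert convs[0].in_channels == 8
        assert convs[-1].out_channels == 1

    def test_last_block_is_bare_convolution(self):
        net = build_rced(RCEDConfig(), seed=0)
        assert isinstance(net.layers[-1], Conv1d)  # no activation after the final conv
        # every non-final conv is followed by batch norm then ReLU
        convs = [i for i, l in enumerate(net.layers) if isinstance(l, Conv1d)]
        for i in convs[:-1]:
            assert isinstance(net.layers[i + 1], BatchNorm1d)
            assert isinstance(net.layers[i + 2], ReLU)

    def test_forward_shape_and_finiteness(self, rng):
        net = build_rced(RCEDConfig(), seed=1)
        out = net.forward(rng.standard_normal((3, 8, 129)))
        assert out.shape == (3, 1, 129)
        assert np.all(np.isfinite(out))

    def test_parameter_count_closed_form(self):
        cfg = RCEDConfig()
        assert build_rced(cfg, seed=0).n_params == cfg.parameter_count() == 60_125

    def test_bad_schedule_rejected(self):
        with pytest.raises(ParameterError):
            RCEDConfig(filter_counts=(12,) * 15 + (1,), kernel_widths=(9,) * 17)
        with pytest.raises(ParameterError):
            RCEDConfig(filter_counts=(12,) * 16, kernel_widths=(9,) * 16)  # last != 1


class TestTrainingRecipe:
    def test_learning_rate_schedule(self):
        tc = TrainConfig(lr0=0.01)
        assert tc.lr_at_epoch(1) == 0.01
        assert tc.lr_at_epoch(12) == pytest.approx(0.01 * 0.95**11)

    def test_zero_epochs_rejected(self):
        with pytest.raises(ParameterError):
            TrainConfig(epochs=0)

    def test_empty_or_mismatched_data_rejected(self, rng):
        net = build_rced(SMALL, seed=0)
        with pytest.raises(ParameterError):
            train_rced(net, np.zeros((0, 8, 129)), np.zeros((0, 129)), TrainConfig())
        with pytest.raises(ParameterError):
            train_rced(
                net, rng.standard_normal((4, 8, 129)), rng.standard_normal((3, 129)), TrainConfig()
            )

    def test_training_is_deterministic_per_seed(self, rng):
        x = rng.standard_normal((64, 8, 129))
        y = x[:, -1, :]
        runs = [
            train_rced(build_rced(SMALL, seed=3), x, y, TrainConfig(seed=3, epochs=2), SMALL)
            for _ in range(2)
        ]
        assert runs[0].history == runs[1].history
        assert np.array_equal(
            predict(runs[0], x[:5]), predict(runs[1], x[:5])
        )

    def test_identity_task_learnable_within_twelve_epochs(self, rng):
        """Predicting the stack's own target frame drives the loss below 5%
        of its starting value under the standard recipe."""
        x = rng.standard_normal((2048, 8, 129))
        y = x[:, -1, :]
        tm = train_rced(build_rced(SMALL, seed=1), x, y, TrainConfig(seed=1), SMALL)
        assert len(tm.history) == 12
        assert tm.history[-1] < 0.05 * tm.history[0]


class TestPredict:
    def test_same_input_same_output(self, rng):
        x = rng.standard_normal((16, 8, 129))
        tm = train_rced(
            build_rced(SMALL, seed=0), x, x[:, -1, :], TrainConfig(seed=0, epochs=1), SMALL
        )
        assert np.array_equal(predict(tm, x[0]), predict(tm, x[0]))

    def test_output_length_and_batch_order(self, rng):
        x = rng.standard_normal((5, 8, 129))
        tm = train_rced(
            build_rced(SMALL, seed=0), x, x[:, -1, :], TrainConfig(seed=0, epochs=1), SMALL
        )
        batch = predict(tm, x)
        assert batch.shape == (5, 129)
        for i in range(5):
            # batched BLAS paths may differ from single-stack ones in the
            # last ulp; order preservation is the contract
            assert predict(tm, x[i]) == pytest.approx(batch[i], rel=1e-10, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        tm = train_rced(
            build_rced(SMALL, seed=0),
            rng.standard_normal((8, 8, 129)),
            rng.standard_normal((8, 129)),
            TrainConfig(seed=0, epochs=1),
            SMALL,
        )
        with pytest.raises(ParameterError):
            predict(tm, rng.standard_normal((4, 129)))


class TestGradients:
    def test_conv_backward_matches_numerical_gradient(self, rng):
        """Finite-difference check of the convolution backward pass."""
        conv = Conv1d(2, 3, 5, rng)
        x = rng.standard_normal((2, 2, 11))
        out = conv.forward(x, training=True)
        upstream = rng.standard_normal(out.shape)
        dx = conv.backward(upstream)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 1, 5), (0, 1, 10)]:
            xp = x.copy()
            xp[idx] += eps
            xm = x.copy()
            xm[idx] -= eps
            num = (
                np.sum(conv.forward(xp, True) * upstream)
                - np.sum(conv.forward(xm, True) * upstream)
            ) / (2 * eps)
            assert num == pytest.approx(dx[idx], rel=1e-5, abs=1e-8)

    def test_batchnorm_backward_matches_numerical_gradient(self, rng):
        bn = BatchNorm1d(3)
        x = rng.standard_normal((4, 3, 7))
        upstream = rng.standard_normal(x.shape)
        bn.forward(x, training=True)
        dx = bn.backward(upstream)
        eps = 1e-6
        for idx in [(0, 0, 0), (3, 2, 6), (1, 1, 3)]:
            xp = x.copy()
            xp[idx] += eps
            xm = x.copy()
            xm[idx] -= eps
            num = (
                np.sum(bn.forward(xp, True) * upstream) - np.sum(bn.forward(xm, True) * upstream)
            ) / (2 * eps)
            bn.backward(upstream)  # clear cache state
            assert num == pytest.approx(dx[idx], rel=1e-4, abs=1e-7)
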