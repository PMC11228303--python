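"""Network contracts: block shapes, residual identity, gradient flow,
parameter economy, training smoke behavior and checkpointing."""

import numpy as np
import pytest
from scipy import stats as sps

from fusionrad import nn
from fusionrad.network import FusionNetClassifier
from fusionrad.nn import autograd as ag
from fusionrad.nn.layers import Conv2d, ConvTranspose2d, Linear


def _zero_convs(module):
    for m in module.modules():
        if isinstance(m, (Conv2d, ConvTranspose2d)):
            m.weight.data[:] = 0.0
            if m.bias is not None:
                m.bias.data[:] = 0.0


class TestSeqResBlock:
    @pytest.mark.parametrize("channels,spatial", [(16, 16), (7, 8), (64, 32)])
    def test_shape_preserved(self, rng, channels, spatial):
        blk = nn.SeqResBlock(channels)
        x = rng.normal(size=(2, channels, spatial, spatial))
        assert blk(ag.Tensor(x)).shape == x.shape

    def test_zero_weights_reduce_to_identity(self, rng):
        blk = nn.SeqResBlock(12)
        _zero_convs(blk)
        x = rng.normal(size=(2, 12, 8, 8))
        np.testing.assert_array_equal(blk(ag.Tensor(x)).data, x)

    def test_every_parameter_receives_gradient(self, rng):
        blk = nn.SeqResBlock(8)
        nn.init_normal(blk, np.random.default_rng(0))
        y = blk(ag.Tensor(rng.normal(size=(2, 8, 8, 8))))
        y.backward(np.ones_like(y.data))
        for name, p in blk.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0), name

    def test_parameter_economy_vs_plain_residual(self):
        for width in (32, 64, 96):
            seq = nn.count_parameters(nn.SeqResBlock(width))
            plain = nn.count_parameters(nn.PlainResidualBlock(width))
            assert seq < plain

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            nn.SeqResBlock(0)
        with pytest.raises(ValueError):
            nn.SeqResBlock(8, reduced_channels=14, n_subspaces=5)


class TestUpDownModules:
    def test_upsample_doubles(self, rng):
        up = nn.UpsampleModule(16)
        nn.init_normal(up, np.random.default_rng(1))
        y = up(ag.Tensor(rng.normal(size=(2, 16, 8, 8))))
        assert y.shape == (2, 16, 16, 16)

    def test_downsample_halves(self, rng):
        down = nn.DownsampleModule(16)
        nn.init_normal(down, np.random.default_rng(1))
        y = down(ag.Tensor(rng.normal(size=(2, 16, 16, 16))))
        assert y.shape == (2, 16, 8, 8)

    def test_zero_input_zero_output_no_bias_leak(self):
        up = nn.UpsampleModule(4, bias=False)
        nn.init_normal(up, np.random.default_rng(2))
        y = up(ag.Tensor(np.zeros((1, 4, 6, 6))))
        np.testing.assert_array_equal(y.data, 0.0)

    def test_down_up_round_trip_shape(self, rng):
        up, down = nn.UpsampleModule(8), nn.DownsampleModule(8)
        nn.init_normal(up, np.random.default_rng(0))
        nn.init_normal(down, np.random.default_rng(1))
        x = ag.Tensor(rng.normal(size=(1, 8, 10, 6)))
        assert down(up(x)).shape == x.data.shape

    def test_odd_dims_rejected(self, rng):
        down = nn.DownsampleModule(4)
        with pytest.raises(ValueError):
            down(ag.Tensor(rng.normal(size=(1, 4, 7, 8))))

    def test_gradient_flows_to_all_parameters(self, rng):
        down = nn.DownsampleModule(6)
        nn.init_normal(down, np.random.default_rng(3))
        y = down(ag.Tensor(rng.normal(size=(2, 6, 8, 8))))
        y.backward(np.ones_like(y.data))
        for name, p in down.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0), name


class TestFusionNet:
    def test_default_has_37_blocks(self):
        assert nn.FusionNet(nn.FusionNetConfig()).n_seqres_blocks == 37

    def test_depth_scale_shrinks(self):
        net = nn.FusionNet(nn.FusionNetConfig(depth_scale=0.25))
        assert net.n_seqres_blocks == sum(
            max(1, round(b * 0.25)) for b in (6, 8, 12, 8, 3))

    def test_forward_shapes(self, rng):
        cfg = nn.FusionNetConfig(in_channels=5, depth_scale=0.25, fc_dim=32,
                                 stage_channels=(8, 12, 16, 16, 12))
        net = nn.FusionNet(cfg)
        nn.init_normal(net, np.random.default_rng(0))
        logits, feats = net(rng.normal(size=(2, 5, 32, 32)))
        assert logits.shape == (2, 2) and feats.shape == (2, 32)

    def test_inconsistent_plan_rejected(self):
        with pytest.raises(ValueError):
            nn.FusionNetConfig(stage_blocks=(2, 2), stage_channels=(8,))


class TestTraining:
    def test_init_distribution(self):
        net = nn.FusionNet(nn.FusionNetConfig(in_channels=1, depth_scale=0.25,
                                              fc_dim=16,
                                              stage_channels=(8, 8, 8, 8, 8)))
        nn.init_normal(net, np.random.default_rng(0))
        weights = np.concatenate([
            m.weight.data.ravel() for m in net.modules()
            if isinstance(m, (Conv2d, ConvTranspose2d, Linear))])
        assert abs(weights.std() - 0.1) < 0.005  # variance 0.01
        assert abs(weights.mean()) < 0.005
        assert sps.kstest(weights / 0.1, "norm").pvalue > 0.01
        for m in net.modules():
            if isinstance(m, (Conv2d, ConvTranspose2d, Linear)) and m.bias is not None:
                assert np.all(m.bias.data == 0)

    def test_single_class_rejected(self, rng):
        net = nn.FusionNet(nn.FusionNetConfig(in_channels=1, depth_scale=0.25,
                                              stage_channels=(4, 4, 4, 4, 4),
                                              fc_dim=8))
        with pytest.raises(ValueError):
            nn.train(net, rng.normal(size=(4, 1, 16, 16)), np.zeros(4, int))

    def test_smoke_training_and_determinism(self, rng):
        X = rng.normal(size=(24, 1, 16, 16))
        X[::2] += 2.0  # separable by mean intensity
        y = np.array([1, 0] * 12)
        histories = []
        for _ in range(2):
            net = nn.FusionNet(nn.FusionNetConfig(
                in_channels=1, depth_scale=0.25, fc_dim=16,
                stage_channels=(8, 8, 8, 8, 8)))
            h = nn.train(net, X, y, nn.TrainConfig(lr=1e-3, max_epochs=3,
                                                   batch_size=8, seed=4))
            histories.append(h["loss"])
        assert histories[0] == histories[1]  # bit-identical loss curves
        assert histories[0][-1] < histories[0][0]

    def test_feature_extraction_contracts(self, rng):
        net = nn.FusionNet(nn.FusionNetConfig(in_channels=1, depth_scale=0.25,
                                              fc_dim=16,
                                              stage_channels=(8, 8, 8, 8, 8)))
        nn.init_normal(net, np.random.default_rng(0))
        X = rng.normal(size=(4, 1, 16, 16))
        with pytest.warns(UserWarning, match="untrained"):
            f1 = nn.extract_deep_features(net, X)
        f2 = nn.extract_deep_features(net, X, warn_untrained=False)
        np.testing.assert_array_equal(f1, f2)  # eval mode is deterministic
        assert f1.shape == (4, 16)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        net = nn.FusionNet(nn.FusionNetConfig(in_channels=1, depth_scale=0.25,
                                              fc_dim=16,
                                              stage_channels=(8, 8, 8, 8, 8)))
        nn.init_normal(net, np.random.default_rng(0))
        net.eval()
        X = rng.normal(size=(2, 1, 16, 16))
        logits, _ = net(X)
        path = str(tmp_path / "model.ckpt")
        nn.save_checkpoint(net, path)
        restored = nn.load_checkpoint(path)
        logits2, _ = restored(X)
        np.testing.assert_array_equal(logits.data, logits2.data)


class TestClassifierEstimator:
    def test_sklearn_protocol(self):
        clf = FusionNetClassifier(fc_dim=8)
        params = clf.get_params()
        assert params["fc_dim"] == 8
        clf.set_params(max_epochs=2)
        assert clf.max_epochs == 2
        with pytest.raises(ValueError):
            clf.set_params(bogus=1)

    def test_fit_predict_transform(self, phantoms_2d):
        X = [s.image for s in phantoms_2d]
        y = [s.label for s in phantoms_2d]
        clf = FusionNetClassifier(depth_scale=0.25, max_epochs=2, batch_size=6,
                                  fc_dim=8, stage_channels=(4, 4, 4, 4, 4), seed=1)
        clf.fit(X, y)
        assert set(clf.predict(X)) <= {0, 1}
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert clf.transform(X).shape == (len(X), 8)
        assert len(clf.history_["loss"]) >= 1
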