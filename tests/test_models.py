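"""Architecture geometry, fusion semantics, forward-pass oracles and the
training/prediction contracts of the deep spectral regressors."""

import numpy as np
import pandas as pd
import pytest

from pearhsi import ContractError, SpectrumTable
from pearhsi.errors import GeometryError
from pearhsi.nn import (
    MSCNNConfig,
    BranchSpec,
    TrainConfig,
    build_mscnn,
    build_mscnn_lstm,
    build_resnet18_1d,
    conv1d_output_length,
    load_model,
    predict,
    save_model,
    train_regressor,
)
from pearhsi.nn.models import MSCNN, _BasicBlock, branch_output_shape

TINY = MSCNNConfig(input_length=32, seed=3)  # fast geometry for toy training


class TestMSCNNGeometry:
    def test_default_branch_maps_are_128x53(self):
        cfg = MSCNNConfig()
        for spec in cfg.branches:
            assert branch_output_shape(cfg, spec) == (128, 53)

    def test_flattened_fused_dimension_6784(self):
        graph = build_mscnn()
        assert graph.model.flat_dim == 6784
        assert graph.model.fc.in_features == 6784
        assert graph.model.fc.out_features == 128

    def test_short_input_still_fuses(self):
        # 10 -> 5 -> 3 -> pool -> 1 under the floor-based length formula
        cfg = MSCNNConfig(input_length=10)
        graph = build_mscnn(cfg)
        assert graph.model.map_shape == (128, 1)

    def test_mismatched_branches_raise(self):
        cfg = MSCNNConfig(branches=(
            BranchSpec(kernel=3, mid_channels=16, out_channels=128, padding=1),
            BranchSpec(kernel=5, mid_channels=64, out_channels=128, padding=0),
            BranchSpec(kernel=7, mid_channels=128, out_channels=128, padding=3)))
        with pytest.raises(GeometryError):
            build_mscnn(cfg)


class TestResNetGeometry:
    def test_downsampling_chain_and_feature_dim(self):
        graph = build_resnet18_1d(421)
        L = conv1d_output_length(421, 7, 2, 3)
        assert L == 211
        L = conv1d_output_length(L, 3, 2, 1)
        assert L == 106
        lengths = [L]
        for _ in range(3):
            L = conv1d_output_length(L, 3, 2, 1)
            lengths.append(L)
        assert lengths == [106, 53, 27, 14]
        assert graph.model.final_length == 14
        assert graph.model.head.in_features == 512

    def test_too_short_input_raises(self):
        with pytest.raises(GeometryError):
            build_resnet18_1d(16)

    def test_zero_residual_block_is_relu_of_skip(self, rng):
        block = _BasicBlock(8, 8, 1, np.random.default_rng(0))
        for conv in (block.conv1, block.conv2):
            conv.weight.value[...] = 0
            conv.bias.value[...] = 0
        block.set_training(False)  # unit running stats: BN(0) == 0
        x = rng.normal(size=(2, 8, 12)).astype(np.float32)
        np.testing.assert_allclose(block.forward(x), np.maximum(x, 0), atol=1e-6)


class TestFusion:
    def _forward_single_branch(self, model: MSCNN, branch_idx: int, x):
        fmap = model.branches[branch_idx](x[:, None, :])
        flat = fmap.reshape(fmap.shape[0], -1)
        h = np.maximum(flat @ model.fc.weight.value.T + model.fc.bias.value, 0)
        return (h @ model.head.weight.value.T + model.head.bias.value)[:, 0]

    @pytest.mark.parametrize("branch_idx", [0, 1, 2])
    def test_one_hot_weights_reduce_to_single_branch(self, rng, branch_idx):
        model = build_mscnn(MSCNNConfig(input_length=24, seed=1)).model
        model.set_training(False)
        for i, w in enumerate(model.fusion_weights):
            w.value[...] = 1.0 if i == branch_idx else 0.0
        x = rng.normal(size=(3, 24)).astype(np.float32)
        np.testing.assert_allclose(model.forward(x),
                                   self._forward_single_branch(model, branch_idx, x),
                                   rtol=1e-5, atol=1e-6)

    def test_zero_weights_make_output_input_independent(self, rng):
        model = build_mscnn(MSCNNConfig(input_length=24, seed=1)).model
        model.set_training(False)
        for w in model.fusion_weights:
            w.value[...] = 0.0
        a = model.forward(rng.normal(size=(2, 24)).astype(np.float32))
        b = model.forward(rng.normal(size=(2, 24)).astype(np.float32))
        np.testing.assert_allclose(a, b, atol=1e-7)
        # the constant is head(ReLU(fc bias))
        h = np.maximum(model.fc.bias.value, 0)
        const = float(h @ model.head.weight.value[0] + model.head.bias.value[0])
        assert a[0] == pytest.approx(const, rel=1e-5)

    def test_forward_matches_layer_by_layer_oracle(self, rng):
        """Recompute the full multiscale forward pass from the parameter store
        with plain loops/matmuls in float64 and compare."""
        cfg = MSCNNConfig(input_length=16, seed=9)
        model = build_mscnn(cfg).model
        model.set_training(False)
        x = rng.normal(size=(2, 16)).astype(np.float32)

        def naive_conv(xa, conv):
            n, c, L = xa.shape
            k, s, p = conv.kernel, conv.stride, conv.padding
            xp = np.pad(xa, ((0, 0), (0, 0), (p, p)))
            L_out = (L + 2 * p - k) // s + 1
            out = np.zeros((n, conv.out_channels, L_out))
            for nn_ in range(n):
                for o in range(conv.out_channels):
                    for t in range(L_out):
                        out[nn_, o, t] = (np.sum(
                            xp[nn_, :, s * t:s * t + k] * conv.weight.value[o])
                            + conv.bias.value[o])
            return out

        def naive_bn(xa, bn):
            shp = (1, -1, 1)
            return (bn.gamma.value.reshape(shp)
                    * (xa - bn.running_mean.reshape(shp))
                    / np.sqrt(bn.running_var.reshape(shp) + bn.eps)
                    + bn.beta.value.reshape(shp))

        def naive_pool(xa, k, s):
            n, c, L = xa.shape
            L_out = (L - k) // s + 1
            out = np.zeros((n, c, L_out))
            for t in range(L_out):
                out[:, :, t] = xa[:, :, s * t:s * t + k].max(axis=2)
            return out

        maps = []
        for branch in model.branches:
            conv1, bn1, _, conv2, bn2, _, pool = branch.layers
            h = np.maximum(naive_bn(naive_conv(x.astype(float)[:, None, :], conv1), bn1), 0)
            h = np.maximum(naive_bn(naive_conv(h, conv2), bn2), 0)
            maps.append(naive_pool(h, pool.kernel, pool.stride))
        fused = sum(w.value.astype(float)[None, :, None] * m
                    for w, m in zip(model.fusion_weights, maps))
        flat = fused.reshape(2, -1)
        h = np.maximum(flat @ model.fc.weight.value.T.astype(float)
                       + model.fc.bias.value, 0)
        expected = (h @ model.head.weight.value.T.astype(float)
                    + model.head.bias.value)[:, 0]
        np.testing.assert_allclose(model.forward(x), expected, rtol=1e-4, atol=1e-5)


class TestMSCNNLSTM:
    def test_parameter_count_closed_form(self):
        trunk = build_mscnn().model.n_parameters()
        # swap the MSCNN head (128->1) for LSTM(128->128) + head (128->1)
        lstm_params = 4 * (128 * 128 + 128 * 128 + 2 * 128)
        graph = build_mscnn_lstm()
        assert graph.model.n_parameters() == trunk + lstm_params

    def test_saturated_output_gate_yields_head_bias(self, rng):
        graph = build_mscnn_lstm(MSCNNConfig(input_length=24, seed=2))
        model = graph.model
        model.set_training(False)
        for p in (model.lstm.w_ih, model.lstm.w_hh, model.lstm.b_ih, model.lstm.b_hh):
            p.value[...] = 0.0
        model.lstm.b_ih.value[3 * 128:] = -30.0  # output gate shut
        out = model.forward(rng.normal(size=(2, 24)).astype(np.float32))
        np.testing.assert_allclose(out, model.head.bias.value[0], atol=1e-6)

    def test_forward_matches_lstm_cell_oracle(self, rng):
        graph = build_mscnn_lstm(MSCNNConfig(input_length=16, seed=4))
        model = graph.model
        model.set_training(False)
        x = rng.normal(size=(2, 16)).astype(np.float32)
        h_fusion = model._trunk_forward(x)

        def sigmoid(v):
            return 1.0 / (1.0 + np.exp(-v))

        gates = (h_fusion.astype(float) @ model.lstm.w_ih.value.T.astype(float)
                 + model.lstm.b_ih.value + model.lstm.b_hh.value)
        H = 128
        c = sigmoid(gates[:, :H]) * np.tanh(gates[:, 2 * H:3 * H])
        h = sigmoid(gates[:, 3 * H:]) * np.tanh(c)
        expected = (h @ model.head.weight.value.T.astype(float)
                    + model.head.bias.value)[:, 0]
        np.testing.assert_allclose(model.forward(x), expected, rtol=1e-4, atol=1e-5)


def _linear_toy(n=64, bands=32, seed=0):
    """Target is an exact linear function of 3 bands."""
    local = np.random.default_rng(seed)
    X = local.uniform(0.2, 0.9, (n, bands))
    y = 4.0 * X[:, 3] - 2.5 * X[:, 10] + 1.5 * X[:, 20] + 5.0
    wl = np.linspace(950, 1650, bands)
    return SpectrumTable(X, wl, targets=pd.DataFrame(
        {"FI": y, "SSC": y, "FSR": np.ones(n)}))


class TestTraining:
    def test_loss_collapses_on_separable_toy(self):
        table = _linear_toy()
        graph = build_mscnn(MSCNNConfig(input_length=32, seed=3))
        cfg = TrainConfig(max_iterations=300, learning_rate=1e-3, seed=0)
        train_regressor(graph, table, "FI", cfg)
        hist = graph.history["train_loss"]
        assert hist[-1] < hist[0] / 100

    def test_toy_recovery_rmse_below_tenth_of_sd(self):
        table = _linear_toy()
        graph = build_mscnn(MSCNNConfig(input_length=32, seed=3))
        train_regressor(graph, table, "FI",
                        TrainConfig(max_iterations=300, learning_rate=1e-3, seed=0))
        yhat = predict(graph, table)
        y = table.target_values("FI")
        assert np.sqrt(np.mean((yhat - y) ** 2)) < 0.1 * y.std()

    def test_zero_learning_rate_freezes_parameters(self):
        table = _linear_toy(n=32)
        graph = build_mscnn(MSCNNConfig(input_length=32, seed=3))
        before = [p.value.copy() for p in graph.model.parameters()]
        train_regressor(graph, table, "FI",
                        TrainConfig(max_iterations=3, learning_rate=0.0, seed=0))
        for b, p in zip(before, graph.model.parameters()):
            np.testing.assert_array_equal(b, p.value)
        # loss is constant up to batch-norm batch-composition jitter
        # (batch statistics depend on the per-epoch shuffle even with lr=0)
        losses = graph.history["train_loss"]
        assert max(losses) - min(losses) < 1e-6 * max(losses)

    def test_same_seed_bitwise_identical_history(self):
        table = _linear_toy(n=48)
        runs = []
        for _ in range(2):
            graph = build_mscnn(MSCNNConfig(input_length=32, seed=3))
            train_regressor(graph, table, "FI",
                            TrainConfig(max_iterations=5, seed=11))
            runs.append(graph.history["train_loss"])
        assert runs[0] == runs[1]

    def test_early_stopping_restores_best_and_records_validation(self):
        table = _linear_toy(n=60)
        from pearhsi.nn import EarlyStoppingConfig

        graph = build_mscnn(MSCNNConfig(input_length=32, seed=3))
        cfg = TrainConfig(max_iterations=100, learning_rate=1e-3, seed=0,
                          early_stopping=EarlyStoppingConfig(
                              enabled=True, patience=5, validation_fraction=0.2))
        train_regressor(graph, table, "FI", cfg)
        assert len(graph.history["val_loss"]) == graph.history["epochs_run"]


class TestPredict:
    @pytest.fixture(scope="class")
    def fitted(self):
        table = _linear_toy()
        graph = build_mscnn_lstm(MSCNNConfig(input_length=32, seed=3))
        train_regressor(graph, table, "FI",
                        TrainConfig(max_iterations=100, learning_rate=1e-3, seed=0))
        return graph, table

    def test_batch_size_independent(self, fitted):
        graph, table = fitted
        a = predict(graph, table, batch_size=1)
        b = predict(graph, table, batch_size=32)
        np.testing.assert_allclose(a, b, rtol=1e-5, atol=1e-6)

    def test_duplicated_rows_give_duplicated_outputs(self, fitted, rng):
        graph, table = fitted
        X = table.spectra[:4]
        doubled = np.vstack([X, X])
        out = predict(graph, doubled)
        np.testing.assert_allclose(out[:4], out[4:], atol=1e-7)

    def test_permutation_equivariance(self, fitted, rng):
        graph, table = fitted
        X = table.spectra[:8]
        perm = rng.permutation(8)
        np.testing.assert_allclose(predict(graph, X[perm]),
                                   predict(graph, X)[perm], atol=1e-7)

    def test_unfitted_and_mismatched_inputs_raise(self, fitted, rng):
        graph, table = fitted
        with pytest.raises(ContractError):
            predict(build_mscnn(MSCNNConfig(input_length=32)), table)
        with pytest.raises(ContractError):
            predict(graph, rng.uniform(0, 1, (3, 31)))

    def test_artifact_round_trip(self, fitted, tmp_path):
        graph, table = fitted
        save_model(graph, tmp_path / "model")
        back = load_model(tmp_path / "model")
        np.testing.assert_allclose(predict(back, table), predict(graph, table),
                                   atol=1e-7)
        assert back.architecture == "mscnn_lstm"
        assert back.target == "FI"
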