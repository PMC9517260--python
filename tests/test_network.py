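"""Architecture fidelity: shapes, parameter counts, forward contract."""

import numpy as np
import pytest

from hear.nn import (
    HierarchicalNetwork,
    NetworkSpec,
    build_model,
    count_parameters,
)

#: published construction-table values for the default architecture:
#: layer -> (feature maps, map size, parameter count); one instance each
LAYER1_TABLE = {
    "LSTM": (32, 28, 4352),
    "1D-CNN": (8, 28, 1288),
    "BN-1": (8, 28, 32),
    "Max-pooling1D": (8, 14, 0),
    "Concatenate-channels": (72, 14, 0),
    "Reshape": (1, (14, 72), 0),
}
LAYER2_TABLE = {
    "2D-CNN-sensor": (8, (14, 72), 80),
    "BN-2": (8, (14, 72), 32),
    "Max-pooling2D-sensor": (8, (7, 36), 0),
    "Concatenate-sensors": (16, (7, 36), 0),
    "2D-CNN-fused": (32, (7, 36), 4640),
    "BN-3": (32, (7, 36), 128),
    "Max-pooling2D-fused": (32, (4, 18), 0),
}
HEAD_TABLE = {
    "Flatten": (1, 2304, 0),
    "Dense-1": (1, 64, 147520),
    "Dense-2": (1, 32, 2080),
    "Dense-3": (1, 16, 528),
    "Dense-4": (1, 8, 136),
    "Dense-5": (1, 7, 63),
}
PARAM_NAMES = {
    "LSTM": "lstm", "1D-CNN": "conv1d", "BN-1": "bn1",
    "2D-CNN-sensor": "conv2d_sensor", "BN-2": "bn2",
    "2D-CNN-fused": "conv2d_fused", "BN-3": "bn3",
    "Dense-1": "dense1", "Dense-2": "dense2", "Dense-3": "dense3",
    "Dense-4": "dense4", "Dense-5": "dense5",
}


class TestShapeChain:
    def test_every_stage_matches_published_tables(self):
        chain = dict((k, v) for k, v in NetworkSpec().shape_chain())
        for table in (LAYER1_TABLE, LAYER2_TABLE, HEAD_TABLE):
            for stage, (maps, size, _) in table.items():
                assert chain[stage] == (maps, size), stage

    def test_pool_divisibility_error_names_stage(self):
        with pytest.raises(ValueError, match="Max-pooling1D"):
            NetworkSpec(t_in=27)
        with pytest.raises(ValueError, match="Max-pooling2D"):
            NetworkSpec(t_in=28, conv1d_filters=5, n_channels=3)

    def test_invalid_class_count_error(self):
        with pytest.raises(ValueError):
            NetworkSpec(n_classes=1)

    def test_spec_json_roundtrip(self):
        spec = NetworkSpec(n_classes=4, head=(10, 5))
        assert NetworkSpec.from_json(spec.to_json()) == spec


class TestParameterCounts:
    def test_analytic_counts_match_published_tables(self):
        spec = NetworkSpec()
        for table in (LAYER1_TABLE, LAYER2_TABLE, HEAD_TABLE):
            for stage, (_, _, n_params) in table.items():
                if stage in PARAM_NAMES:
                    assert count_parameters(spec, PARAM_NAMES[stage]) == n_params

    def test_enumeration_of_built_model_agrees_with_formulas(self):
        """The model's own array enumeration is the oracle for the
        analytic counting rules, layer by layer and in total."""
        for spec in (NetworkSpec(),
                     NetworkSpec(t_in=12, n_sensors=2, n_channels=2,
                                 lstm_units=3, conv1d_filters=2,
                                 conv1d_kernel=3, conv2d_sensor_filters=2,
                                 conv2d_fused_filters=3, head=(5, 4),
                                 n_classes=3)):
            model = build_model(spec, seed=0)
            for layer in ("lstm", "conv1d", "bn1", "conv2d_sensor", "bn2",
                          "conv2d_fused", "bn3", "dense1"):
                assert model.param_count(layer) == count_parameters(spec, layer)
            assert model.param_count("all") == count_parameters(spec, "all")

    def test_unknown_layer_error(self):
        with pytest.raises(ValueError, match="unknown layer"):
            count_parameters(NetworkSpec(), "attention")


class TestForward:
    def test_rows_are_probability_vectors(self, tiny_spec):
        model = build_model(tiny_spec, seed=0)
        X = np.random.default_rng(0).normal(size=(9, 12, 2, 2))
        p = model.forward(X)
        assert p.shape == (9, 3)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0) and np.all(p <= 1)

    def test_inference_is_deterministic_per_sample(self, tiny_spec):
        model = build_model(tiny_spec, seed=0)
        x = np.random.default_rng(1).normal(size=(1, 12, 2, 2))
        batch = np.repeat(x, 5, axis=0)
        p = model.forward(batch, training=False)
        for row in p[1:]:
            np.testing.assert_array_equal(row, p[0])

    def test_seeded_initialization_reproducible(self, tiny_spec):
        X = np.random.default_rng(2).normal(size=(3, 12, 2, 2))
        p1 = build_model(tiny_spec, seed=7).forward(X)
        p2 = build_model(tiny_spec, seed=7).forward(X)
        np.testing.assert_array_equal(p1, p2)
        p3 = build_model(tiny_spec, seed=8).forward(X)
        assert not np.array_equal(p1, p3)

    def test_two_class_head(self):
        spec = NetworkSpec(t_in=12, n_sensors=2, n_channels=2, lstm_units=3,
                           conv1d_filters=2, conv1d_kernel=3,
                           conv2d_sensor_filters=2, conv2d_fused_filters=3,
                           head=(5,), n_classes=2)
        model = build_model(spec, seed=0)
        p = model.forward(np.zeros((4, 12, 2, 2)))
        assert p.shape == (4, 2)

    def test_shape_mismatch_error_reports_expected(self, tiny_spec):
        model = build_model(tiny_spec, seed=0)
        with pytest.raises(ValueError, match=r"\(12, 2, 2\)"):
            model.forward(np.zeros((2, 10, 2, 2)))

    def test_default_shapes_propagate(self):
        model = build_model(NetworkSpec(), seed=0)
        p = model.forward(np.zeros((2, 28, 2, 9), dtype=np.float32))
        assert p.shape == (2, 7)


class TestWiring:
    def test_sensor_permutation_consistency(self, tiny_spec):
        """Swapping the two sensors in the input and the corresponding
        per-sensor branches (grouped Layer-1 weights, Layer-2 sensor
        branches, fused-conv input blocks) leaves the output unchanged."""
        spec = tiny_spec
        C, F1 = spec.n_channels, spec.conv1d_filters
        F2a = spec.conv2d_sensor_filters
        a = build_model(spec, seed=3)
        b = build_model(spec, seed=3)

        def swap_groups(layer):
            for store in (layer.params, layer.buffers):
                for key in store:
                    arr = store[key]
                    arr[...] = np.concatenate([arr[C:2 * C], arr[:C]], axis=0)

        swap_groups(b.lstm)
        swap_groups(b.conv1)
        swap_groups(b.bn1)
        b.conv2a = b.conv2a[::-1]
        b.relu2a = b.relu2a[::-1]
        b.bn2a = b.bn2a[::-1]
        b.pool2a = b.pool2a[::-1]
        W = b.conv2b.params["W"]
        W[...] = np.concatenate([W[:, :, F2a:], W[:, :, :F2a]], axis=2)

        X = np.random.default_rng(4).normal(size=(5, spec.t_in, 2, C))
        X_swapped = X[:, :, ::-1, :]
        np.testing.assert_allclose(
            a.forward(X), b.forward(X_swapped), rtol=2e-4, atol=1e-6)


class TestPersistence:
    def test_checkpoint_roundtrip(self, tiny_spec, tmp_path):
        model = build_model(tiny_spec, seed=0)
        X = np.random.default_rng(5).normal(size=(4, 12, 2, 2))
        before = model.forward(X)
        path = tmp_path / "model.npz"
        model.save(path)
        back = HierarchicalNetwork.load(path)
        assert back.spec == tiny_spec
        np.testing.assert_allclose(back.forward(X), before, atol=1e-6)
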