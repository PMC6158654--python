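"""Deep feature learning: architecture, constraints, loss accounting, training.

The loss oracles recompute the weighted objectives directly from the
model's own outputs with plain per-sample arithmetic; the gradient check
compares backpropagation against central finite differences on a small
network.
"""

import logging

import numpy as np
import pytest

from idaod import (
    AutoencoderConfig,
    FeatureLearner,
    FineTuneConfig,
    LabeledDataset,
    extract_representation,
    fine_tune,
    pretrain_autoencoder,
)
from idaod.errors import ConfigError, DegenerateTrainingError, ValidationError
from idaod.network import (
    Dense,
    build_fc_stack,
    weighted_cross_entropy,
    weighted_reconstruction_loss,
)


def _param_count(layers):
    return sum(l.W.size + l.b.size for l in layers)


class TestArchitecture:
    def test_autoencoder_parameter_count_exact(self, small_dataset):
        cfg = AutoencoderConfig(epochs=1, seed=0)
        layers, _ = pretrain_autoencoder(small_dataset, cfg, return_full=True)
        widths = cfg.layer_widths
        expected = sum(
            widths[i] * widths[i + 1] + widths[i + 1]
            for i in range(len(widths) - 1)
        )
        assert _param_count(layers) == expected
        assert layers[-1].W.shape == (650, 800)  # reconstruction width

    def test_full_model_parameter_count_exact(self, tiny_trained_model):
        m = tiny_trained_model
        enc_widths = [800, 650, 500, 300]
        fc_widths = [300, 50, 25, 1]
        expected = sum(
            a * b + b for a, b in zip(enc_widths[:-1], enc_widths[1:])
        ) + sum(a * b + b for a, b in zip(fc_widths[:-1], fc_widths[1:]))
        assert _param_count(m.layers) == expected

    def test_invalid_widths_rejected(self):
        with pytest.raises(ConfigError):
            AutoencoderConfig(layer_widths=(800, 650, 300, 500, 650, 800))
        with pytest.raises(ConfigError):
            AutoencoderConfig(layer_widths=(800, 650, 500, 300, 500, 650, 700))


class TestInitialization:
    def test_fc_init_range_and_zero_bias(self):
        cfg = FineTuneConfig(seed=3)
        fc = build_fc_stack(300, cfg, np.random.default_rng(3))
        for layer in fc:
            assert np.all(np.abs(layer.W) <= cfg.weight_init_range)
            assert np.all(layer.b == 0)
        assert [l.W.shape for l in fc] == [(300, 50), (50, 25), (25, 1)]
        # max-norm trivially satisfied at init
        for layer in fc:
            assert np.linalg.norm(layer.W, axis=0).max() <= cfg.max_weight_norm


class TestPretraining:
    def test_reconstruction_width_is_input_width(self, small_dataset):
        layers, _ = pretrain_autoencoder(
            small_dataset, AutoencoderConfig(epochs=1, seed=1), return_full=True
        )
        out = layers[0].forward(small_dataset.features[:4], cache=False)
        for l in layers[1:]:
            out = l.forward(out, cache=False)
        assert out.shape == (4, 800)

    def test_loss_decreases_on_seeded_run(self, small_dataset):
        _, losses = pretrain_autoencoder(
            small_dataset, AutoencoderConfig(epochs=30, seed=2)
        )
        assert losses[-1] < losses[0]

    def test_loss_trace_matches_output_oracle(self, small_dataset):
        layers, losses = pretrain_autoencoder(
            small_dataset, AutoencoderConfig(epochs=3, seed=5), return_full=True
        )
        X = small_dataset.features
        w = small_dataset.sample_weights
        out = X
        for l in layers:
            out = l.forward(out, cache=False)
        # independent per-sample accumulation in float64
        num = 0.0
        for i in range(X.shape[0]):
            num += w[i] * float(
                np.sum((X[i] - out[i].astype(np.float64)) ** 2)
            )
        oracle = num / w.sum()
        assert abs(losses[-1] - oracle) < 1e-6

    def test_batch_clipped_with_warning(self, small_dataset, caplog):
        tiny = LabeledDataset(
            features=small_dataset.features[:5],
            labels=np.array([1, 0, 0, 1, 0]),
        )
        with caplog.at_level(logging.WARNING, logger="idaod.network"):
            _, losses = pretrain_autoencoder(
                tiny, AutoencoderConfig(epochs=1, batch_size=12, seed=1)
            )
        assert len(losses) == 1
        assert any("clipped" in m for m in caplog.messages)

    def test_greedy_layerwise_mode_runs(self, small_dataset):
        enc, losses = pretrain_autoencoder(
            small_dataset,
            AutoencoderConfig(epochs=2, greedy_layerwise=True, seed=1),
        )
        assert [l.W.shape for l in enc] == [(800, 650), (650, 500), (500, 300)]
        assert np.isfinite(losses).all()


class TestFineTuning:
    def test_predictions_strictly_inside_unit_interval(
        self, tiny_trained_model, small_dataset
    ):
        y = tiny_trained_model.predict_proba(small_dataset.features)
        assert np.all((y > 0) & (y < 1))

    def test_cross_entropy_decreases_on_separable_data(
        self, small_dataset, tiny_trained_model
    ):
        losses = tiny_trained_model.finetune_losses
        assert losses[-1] < losses[0]

    def test_loss_trace_matches_output_oracle(
        self, tiny_trained_model, small_dataset
    ):
        m = tiny_trained_model
        y = m.predict_proba(small_dataset.features)
        t = small_dataset.labels.astype(float)
        w = small_dataset.sample_weights
        yc = np.clip(y, 1e-7, 1 - 1e-7)
        num = sum(
            w[i] * -(t[i] * np.log(yc[i]) + (1 - t[i]) * np.log(1 - yc[i]))
            for i in range(len(t))
        )
        assert abs(m.finetune_losses[-1] - num / w.sum()) < 1e-6

    @pytest.mark.parametrize("epochs", [1, 2, 5])
    def test_max_norm_holds_after_every_epoch(self, small_dataset, epochs):
        """Same seed replays the same batches, so checking the endpoint of
        runs of increasing length audits the constraint after each epoch."""
        enc, _ = pretrain_autoencoder(
            small_dataset, AutoencoderConfig(epochs=1, seed=8)
        )
        m = fine_tune(enc, small_dataset, FineTuneConfig(epochs=epochs, seed=8))
        for layer in m.fc_layers:
            norms = np.linalg.norm(
                layer.W.astype(np.float64), axis=0
            )
            assert norms.max() <= 3.0 + 1e-9

    def test_tight_max_norm_actively_enforced(self, small_dataset):
        enc, _ = pretrain_autoencoder(
            small_dataset, AutoencoderConfig(epochs=1, seed=8)
        )
        m = fine_tune(
            enc, small_dataset,
            FineTuneConfig(epochs=3, max_weight_norm=0.01, seed=8),
        )
        for layer in m.fc_layers:
            assert np.linalg.norm(layer.W, axis=0).max() <= 0.01 + 1e-9

    def test_single_class_labels_rejected(self, small_dataset):
        enc, _ = pretrain_autoencoder(
            small_dataset, AutoencoderConfig(epochs=1, seed=1)
        )
        bad = LabeledDataset(
            features=small_dataset.features,
            labels=np.zeros(small_dataset.n, dtype=int),
        )
        with pytest.raises(DegenerateTrainingError):
            fine_tune(enc, bad, FineTuneConfig(epochs=1, seed=1))


class TestRepresentation:
    def test_shape_and_determinism(self, tiny_trained_model, small_dataset):
        X = small_dataset.features
        r1 = extract_representation(tiny_trained_model, X)
        r2 = extract_representation(tiny_trained_model, X)
        assert r1.shape == (small_dataset.n, 50)
        np.testing.assert_array_equal(r1, r2)  # bit-identical, dropout off

    def test_identical_rows_map_identically(self, tiny_trained_model):
        x = np.random.default_rng(0).random((1, 800))
        X = np.vstack([x, x])
        r = extract_representation(tiny_trained_model, X)
        np.testing.assert_array_equal(r[0], r[1])

    def test_wrong_width_rejected(self, tiny_trained_model):
        with pytest.raises(ValidationError):
            extract_representation(
                tiny_trained_model, np.zeros((3, 400))
            )

    def test_serialization_roundtrip_bit_stable(
        self, tiny_trained_model, small_dataset, tmp_path
    ):
        path = tmp_path / "model.npz"
        tiny_trained_model.save(path)
        back = FeatureLearner.load(path)
        X = small_dataset.features
        np.testing.assert_array_equal(
            tiny_trained_model.transform(X), back.transform(X)
        )
        np.testing.assert_array_equal(
            tiny_trained_model.predict_proba(X), back.predict_proba(X)
        )


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of the weighted BCE through a small
        tanh/sigmoid stack agree with central differences."""
        rng = np.random.default_rng(42)
        layers = [
            Dense(rng.normal(0, 0.5, (6, 4)), rng.normal(0, 0.1, 4), "tanh"),
            Dense(rng.normal(0, 0.5, (4, 3)), rng.normal(0, 0.1, 3), "relu"),
            Dense(rng.normal(0, 0.5, (3, 1)), rng.normal(0, 0.1, 1), "sigmoid"),
        ]
        X = rng.normal(0, 1, (8, 6)).astype(np.float32)
        t = rng.integers(0, 2, 8).astype(np.float64)
        w = np.where(t == 1, 6.0, 1.0)

        def loss():
            a = X
            for l in layers:
                a = l.forward(a, cache=False)
            return weighted_cross_entropy(t, a.ravel(), w)

        # analytic
        a = X
        for l in layers:
            a = l.forward(a)
        y = a.ravel().astype(np.float64)
        grad = (((y - t) * w / w.sum())[:, None]).astype(np.float32)
        for li in range(2, -1, -1):
            grad = layers[li].backward(grad, wrt_preactivation=(li == 2))

        h = 1e-2
        checked = 0
        for l in layers:
            W = l.W
            flat = [(0, 0), (W.shape[0] - 1, W.shape[1] - 1), (1, 0)]
            for (i, j) in flat:
                orig = W[i, j]
                W[i, j] = orig + h
                lp = loss()
                W[i, j] = orig - h
                lm = loss()
                W[i, j] = orig
                numeric = (lp - lm) / (2 * h)
                analytic = float(l.dW[i, j])
                assert analytic == pytest.approx(numeric, rel=2e-2, abs=2e-4)
                checked += 1
        assert checked == 9


class TestLinearProbeProperty:
    def test_representation_beats_label_permuted_control(
        self, strong_representation
    ):
        """Permutation test of linear separability: a held-out linear probe
        on the learned 50-dim representation beats the same probe fitted on
        label-permuted controls across 10 permutation seeds."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import balanced_accuracy_score
        from sklearn.model_selection import train_test_split

        rep, y = strong_representation

        def probe_acc(labels, split_seed):
            r_tr, r_te, y_tr, y_te = train_test_split(
                rep, labels, test_size=0.33, random_state=split_seed,
                stratify=labels,
            )
            clf = LogisticRegression(
                max_iter=500, class_weight="balanced"
            ).fit(r_tr, y_tr)
            return balanced_accuracy_score(y_te, clf.predict(r_te))

        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            true_acc = probe_acc(y, seed)
            perm_acc = probe_acc(rng.permutation(y), seed)
            if true_acc > perm_acc:
                wins += 1
        assert wins >= 9
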