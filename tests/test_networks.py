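"""Backbone construction, the multi-task loss, and inference behavior."""

import numpy as np
import pytest

from m6a2stage import nn
from m6a2stage.dataset_builder import DatasetSplit
from m6a2stage.encoding import MultiTaskBatch, encode_split
from m6a2stage.networks import (
    BackboneConfig,
    build_model,
    loss_terms,
    multitask_loss,
    predict,
)
from m6a2stage.evaluation import roc_pr_curves
from conftest import make_window, random_rna

TINY = dict(window_length=21, conv_kernel_size=5, pool_size=2, dropout_rate=0.0)


def _batch(n, length, seed=0, probs=None, preds=None):
    rng = np.random.default_rng(seed)
    x = np.zeros((n, 4, length))
    x[np.arange(n)[:, None], rng.integers(0, 4, (n, length)), np.arange(length)] = 1
    y = np.zeros((n, 2))
    y[np.arange(n), rng.integers(0, 2, n)] = 1
    b = MultiTaskBatch(inputs=x, class_labels=y, regression_targets=rng.random(n))
    b.class_probs = probs
    b.regression_preds = preds
    return b


class TestBuildModel:
    def test_two_outputs_with_expected_shapes(self):
        cfg = BackboneConfig(variant="cnn_bilstm", **TINY)
        state = build_model(cfg, "multitask")
        logits, reg = state.model.forward(np.zeros((3, 4, 21)))
        assert logits.shape == (3, 2)
        assert reg.shape == (3,)

    def test_single_task_modes_drop_a_head(self):
        cfg = BackboneConfig(**TINY)
        logits, reg = build_model(cfg, "classify_only").model.forward(np.zeros((2, 4, 21)))
        assert logits is not None and reg is None
        logits, reg = build_model(cfg, "regress_only").model.forward(np.zeros((2, 4, 21)))
        assert logits is None and reg is not None

    def test_seeded_build_is_deterministic(self):
        cfg = BackboneConfig(variant="cnn_transformer", **TINY, seed=5)
        a, b = build_model(cfg), build_model(cfg)
        for k, v in a.weights.items():
            assert np.array_equal(v, b.weights[k]), k

    def test_parameter_count_ordering(self):
        """Analytic layer formulas: the BiLSTM adds 2*4H(C+H+1) parameters on
        top of the CNN; the transformer adds position embedding + attention +
        feed-forward + layer norms, which is larger at the defaults."""
        counts = {}
        for variant in ("cnn", "cnn_bilstm", "cnn_transformer"):
            cfg = BackboneConfig(variant=variant, **TINY)
            counts[variant] = build_model(cfg).n_params()
        C, H = 16, 8
        assert counts["cnn_bilstm"] - counts["cnn"] == 2 * 4 * H * (C + H + 1)
        L = 21 - 5 + 1
        transformer_extra = (
            C * L                      # position embedding
            + 4 * (C * C + C)          # q, k, v, o projections
            + C * 64 + 64 + 64 * C + C  # feed-forward
            + 4 * C                    # two layer norms
        )
        assert counts["cnn_transformer"] - counts["cnn"] == transformer_extra
        assert counts["cnn"] < counts["cnn_bilstm"] < counts["cnn_transformer"]

    def test_groupnorm_divisibility_enforced(self):
        with pytest.raises(ValueError):
            BackboneConfig(conv_filters=15, groupnorm_groups=4, **TINY)

    def test_invalid_variant(self):
        with pytest.raises(ValueError):
            BackboneConfig(variant="mlp", **TINY)

    def test_save_load_bit_exact(self, tmp_path):
        cfg = BackboneConfig(variant="cnn_bilstm", **TINY, seed=2)
        state = build_model(cfg)
        state.save(tmp_path / "m")
        from m6a2stage.networks import ModelState

        back = ModelState.load(tmp_path / "m")
        for k, v in state.weights.items():
            assert np.array_equal(v, back.weights[k])


class TestGradients:
    """Backprop vs central finite differences on every parameter tensor."""

    @pytest.mark.parametrize("variant", ["cnn", "cnn_bilstm", "cnn_transformer"])
    def test_numeric_gradient_agreement(self, variant):
        rng = np.random.default_rng(17)
        cfg = BackboneConfig(variant=variant, **TINY, seed=3)
        state = build_model(cfg)
        x = rng.random((3, 4, 21))
        y = np.zeros((3, 2))
        y[[0, 1, 2], [0, 1, 1]] = 1
        t = rng.random(3)

        def loss():
            logits, reg = state.model.forward(x)
            p = nn.softmax(logits, axis=1)
            ce = -np.mean(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p), axis=1))
            return ce + np.mean(np.log(np.cosh(reg - t)))

        logits, reg = state.model.forward(x)
        p = nn.softmax(logits, axis=1)
        state.model.backward(2 * (p - y) / 3, np.tanh(reg - t) / 3)
        grads = state.model.named_grads()
        for name, arr in state.model.named_params().items():
            g = grads[name]
            for _ in range(2):
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                eps, old = 1e-6, arr[idx]
                arr[idx] = old + eps
                lp = loss()
                arr[idx] = old - eps
                lm = loss()
                arr[idx] = old
                num = (lp - lm) / (2 * eps)
                # key-projection bias gradients are exactly zero (softmax is
                # invariant to a constant shift of every score in a row)
                scale = max(1e-4, abs(num) + abs(g[idx]))
                assert abs(num - g[idx]) / scale < 1e-4, f"{name}{idx}"


class TestMultitaskLoss:
    def test_vanishes_at_clipped_perfect_prediction(self):
        b = _batch(4, 21, probs=None)
        b.class_probs = b.class_labels.astype(float)
        b.regression_preds = b.regression_targets.copy()
        assert multitask_loss(b) < 1e-5

    def test_printed_both_class_form_at_half(self):
        """p=0.5 for both classes gives CE = -2 log 0.5 = 1.3863."""
        b = _batch(1, 21)
        b.class_probs = np.array([[0.5, 0.5]])
        b.regression_preds = b.regression_targets.copy()
        assert multitask_loss(b) == pytest.approx(2 * np.log(2), abs=1e-6)
        assert multitask_loss(b) == pytest.approx(1.3863, abs=1e-4)

    def test_logcosh_at_unit_residual(self):
        """log(cosh 1) = log((e + 1/e)/2) = 0.43378."""
        b = _batch(1, 21)
        b.class_probs = b.class_labels.astype(float)
        b.regression_preds = b.regression_targets + 1.0
        expected = np.log((np.e + 1 / np.e) / 2)
        assert multitask_loss(b) == pytest.approx(expected, abs=1e-6)
        assert multitask_loss(b) == pytest.approx(0.43378, abs=1e-5)

    def test_ablation_weight_equalities(self):
        b = _batch(8, 21, seed=4)
        rng = np.random.default_rng(5)
        p1 = rng.random(8)
        b.class_probs = np.stack([1 - p1, p1], axis=1)
        b.regression_preds = rng.random(8)
        ce, lc = loss_terms(b)
        assert multitask_loss(b, w_class=1, w_reg=0) == pytest.approx(ce)
        assert multitask_loss(b, w_class=0, w_reg=1) == pytest.approx(lc)
        assert multitask_loss(b, 0.06, 1.85) == pytest.approx(0.06 * ce + 1.85 * lc)

    def test_printed_form_is_twice_categorical(self):
        b = _batch(16, 21, seed=6)
        rng = np.random.default_rng(7)
        p1 = rng.uniform(0.05, 0.95, 16)
        b.class_probs = np.stack([1 - p1, p1], axis=1)
        b.regression_preds = b.regression_targets.copy()
        assert loss_terms(b, "printed")[0] == pytest.approx(
            2 * loss_terms(b, "categorical")[0]
        )

    def test_logcosh_symmetric_nonnegative(self):
        rng = np.random.default_rng(8)
        r = rng.normal(size=200)
        b = _batch(200, 21, seed=9)
        b.class_probs = b.class_labels.astype(float)
        b.regression_preds = b.regression_targets + r
        _, lc_pos = loss_terms(b)
        b.regression_preds = b.regression_targets - r
        _, lc_neg = loss_terms(b)
        assert lc_pos == pytest.approx(lc_neg, abs=1e-12)
        assert lc_pos >= 0
        direct = np.mean(np.log(np.cosh(r)))
        assert lc_pos == pytest.approx(direct, abs=1e-12)

    def test_nan_inputs_rejected(self):
        b = _batch(2, 21)
        b.class_probs = np.array([[np.nan, 0.5], [0.5, 0.5]])
        b.regression_preds = b.regression_targets.copy()
        with pytest.raises(ValueError):
            multitask_loss(b)


class TestPredict:
    def _random_split(self, n, length=21, seed=0):
        rng = np.random.default_rng(seed)
        wins = []
        for i in range(n):
            w = make_window(random_rna(rng, length, "GAC"), label=int(i % 2))
            w.support_target = float(rng.random())
            wins.append(w)
        return DatasetSplit(name="r", windows=wins)

    def test_probabilities_sum_to_one(self):
        state = build_model(BackboneConfig(**TINY))
        batch = encode_split(self._random_split(32))
        predict(state, batch)
        assert np.allclose(batch.class_probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(np.isfinite(batch.regression_preds))

    def test_inference_deterministic_despite_dropout_config(self):
        cfg = BackboneConfig(window_length=21, conv_kernel_size=5, pool_size=2,
                             dropout_rate=0.5)
        state = build_model(cfg)
        batch = encode_split(self._random_split(16))
        a = predict(state, batch).class_probs.copy()
        b = predict(state, batch).class_probs.copy()
        assert np.array_equal(a, b)

    def test_untrained_model_is_chance_level(self):
        """Fresh weights carry no label information: AUROC ~ 0.5."""
        state = build_model(BackboneConfig(**TINY, seed=123))
        batch = encode_split(self._random_split(600, seed=11))
        predict(state, batch)
        _, auroc, _, _ = roc_pr_curves(batch.class_labels[:, 1], batch.class_probs[:, 1])
        assert abs(auroc - 0.5) < 0.1

    def test_shape_mismatch_rejected(self):
        state = build_model(BackboneConfig(**TINY))
        batch = encode_split(self._random_split(4, length=31))
        with pytest.raises(ValueError):
            predict(state, batch)
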