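"""Backbone architectures, task heads, and the composite multi-task loss.

Three shared backbones operate on a one-hot 4 x L window:

* ``cnn``            — Conv1D(16 filters) -> GroupNorm(4) -> ELU
* ``cnn_bilstm``     — CNN stack + bidirectional LSTM (8 hidden units per
  direction, full output sequence, 16 output channels)
* ``cnn_transformer``— CNN stack + learned position embedding + one
  transformer encoder block (2 heads, position-wise feed-forward)

followed by 1-D max pooling, flatten, a dense layer of 64 units (optionally
one per task), dropout, and two heads: a 2-unit softmax classifier
(m6A vs background) and a 1-unit ELU regressor predicting the normalized
experimental SupportNum.

The multi-task loss is ``w_class * CE + w_reg * LC`` where CE is the two-class
cross-entropy written in the per-sample both-class form
``-(y log p + (1-y) log(1-p))`` summed over both softmax outputs (equal to
twice the standard categorical cross-entropy of a 2-class softmax) and LC is
the log-cosh regression loss; both terms are averaged over the batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .encoding import MultiTaskBatch

__all__ = [
    "BackboneConfig",
    "ModelState",
    "build_model",
    "multitask_loss",
    "loss_terms",
    "predict",
    "UNCERTAINTY_WEIGHT_PRESET",
]

#: loss-weight ratio (classification : regression) obtained elsewhere by
#: uncertainty weighting; exposed as a configuration preset only.
UNCERTAINTY_WEIGHT_PRESET = (0.06, 1.85)

VARIANTS = ("cnn", "cnn_bilstm", "cnn_transformer")
MODES = ("multitask", "classify_only", "regress_only")
EPS = 1e-7


@dataclass
class BackboneConfig:
    """Architecture variant plus every tunable hyperparameter and the seed."""

    variant: str = "cnn_bilstm"
    window_length: int = 601
    conv_filters: int = 16
    conv_kernel_size: int = 9
    groupnorm_groups: int = 4
    bilstm_hidden: int = 8
    transformer_heads: int = 2
    transformer_ff_dim: int = 64
    pool_size: int = 8
    dense_units: int = 64
    dropout_rate: float = 0.3
    activation: str = "elu"
    task_specific_dense: bool = False
    ce_form: str = "printed"  # "printed" (both-class sum) or "categorical"
    loss_weight_class: float = 1.0
    loss_weight_reg: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.conv_filters % self.groupnorm_groups != 0:
            raise ValueError("groupnorm_groups must divide conv_filters")
        for name in ("conv_filters", "conv_kernel_size", "groupnorm_groups",
                     "bilstm_hidden", "transformer_heads", "pool_size", "dense_units"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.ce_form not in ("printed", "categorical"):
            raise ValueError("ce_form must be 'printed' or 'categorical'")

    @property
    def conv_out_length(self) -> int:
        return self.window_length - self.conv_kernel_size + 1

    @property
    def backbone_channels(self) -> int:
        if self.variant == "cnn_bilstm":
            return 2 * self.bilstm_hidden
        return self.conv_filters

    @property
    def flat_features(self) -> int:
        return self.backbone_channels * (self.conv_out_length // self.pool_size)


class _Model:
    """Internal forward/backward machine shared by all variants."""

    def __init__(self, config: BackboneConfig, mode: str):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.config = config
        self.mode = mode
        rng = np.random.default_rng(config.seed)
        C = config.conv_filters
        layers: list[nn.Layer] = [
            nn.Conv1D("conv", 4, C, config.conv_kernel_size, rng),
            nn.GroupNorm("gn", C, config.groupnorm_groups),
            nn.ELU("act0"),
        ]
        if config.variant == "cnn_bilstm":
            layers.append(nn.BiLSTM("bilstm", C, config.bilstm_hidden, rng))
        elif config.variant == "cnn_transformer":
            layers.append(nn.PositionEmbedding("posemb", C, config.conv_out_length, rng))
            layers.append(
                nn.TransformerBlock(
                    "encoder", C, config.transformer_heads, config.transformer_ff_dim, rng
                )
            )
        layers.append(nn.MaxPool1D("pool", config.pool_size))
        layers.append(nn.Flatten("flatten"))
        self.shared = nn.Sequential(layers)

        D = config.dense_units
        F = config.flat_features
        drop_seed = int(np.random.default_rng((config.seed, 1)).integers(2**31))

        def trunk(tag: str, offset: int) -> nn.Sequential:
            return nn.Sequential(
                [
                    nn.Dense(f"dense_{tag}", F, D, rng),
                    nn.ELU(f"dense_{tag}_act"),
                    nn.Dropout(f"dropout_{tag}", config.dropout_rate, drop_seed + offset),
                ]
            )

        self.task_specific = config.task_specific_dense
        if self.task_specific:
            self.trunk_cls = trunk("cls", 0)
            self.trunk_reg = trunk("reg", 1)
        else:
            self.trunk_cls = self.trunk_reg = trunk("shared", 0)

        self.head_cls = nn.Dense("head_cls", D, 2, rng) if mode != "regress_only" else None
        if mode != "classify_only":
            self.head_reg = nn.Dense("head_reg", D, 1, rng)
            self.head_reg_act = nn.ELU("head_reg_act")
        else:
            self.head_reg = None
            self.head_reg_act = None

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray | None, np.ndarray | None]:
        """Returns (class logits (N,2) or None, regression output (N,) or None)."""
        feats = self.shared.forward(x, train=train)
        logits = reg = None
        if self.task_specific:
            if self.head_cls is not None:
                logits = self.head_cls.forward(self.trunk_cls.forward(feats, train=train))
            if self.head_reg is not None:
                reg = self.head_reg_act.forward(
                    self.head_reg.forward(self.trunk_reg.forward(feats, train=train))
                )[:, 0]
        else:
            t = self.trunk_cls.forward(feats, train=train)
            if self.head_cls is not None:
                logits = self.head_cls.forward(t)
            if self.head_reg is not None:
                reg = self.head_reg_act.forward(self.head_reg.forward(t))[:, 0]
        return logits, reg

    def backward(self, dlogits: np.ndarray | None, dreg: np.ndarray | None) -> None:
        if self.task_specific:
            dfeats = 0.0
            if dlogits is not None:
                dfeats = dfeats + self.trunk_cls.backward(self.head_cls.backward(dlogits))
            if dreg is not None:
                d = self.head_reg_act.backward(dreg[:, None])
                dfeats = dfeats + self.trunk_reg.backward(self.head_reg.backward(d))
        else:
            dtrunk = 0.0
            if dlogits is not None:
                dtrunk = dtrunk + self.head_cls.backward(dlogits)
            if dreg is not None:
                d = self.head_reg_act.backward(dreg[:, None])
                dtrunk = dtrunk + self.head_reg.backward(d)
            dfeats = self.trunk_cls.backward(dtrunk)
        self.shared.backward(dfeats)

    # -- parameter plumbing -------------------------------------------------
    def _layer_groups(self) -> list[nn.Sequential | nn.Layer]:
        groups: list = [self.shared, self.trunk_cls]
        if self.task_specific:
            groups.append(self.trunk_reg)
        if self.head_cls is not None:
            groups.append(self.head_cls)
        if self.head_reg is not None:
            groups.append(self.head_reg)
        return groups

    def named_params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for g in self._layer_groups():
            if isinstance(g, nn.Sequential):
                out.update(g.named_params())
            else:
                for k, v in g.params.items():
                    out[f"{g.name}.{k}"] = v
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for g in self._layer_groups():
            if isinstance(g, nn.Sequential):
                out.update(g.named_grads())
            else:
                for k, v in g.grads.items():
                    out[f"{g.name}.{k}"] = v
        return out

    def set_params(self, values: dict[str, np.ndarray]) -> None:
        current = self.named_params()
        for name, arr in values.items():
            if name not in current:
                raise KeyError(f"unknown parameter {name!r}")
            if current[name].shape != arr.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {current[name].shape} vs {arr.shape}"
                )
            current[name][...] = arr

    def n_params(self) -> int:
        return sum(v.size for v in self.named_params().values())


@dataclass
class ModelState:
    """A built (possibly trained) model plus its configuration and stage tag."""

    config: BackboneConfig
    mode: str
    model: _Model
    stage_tag: str = "stage1"
    support_normalizer: object | None = None

    @property
    def weights(self) -> dict[str, np.ndarray]:
        return self.model.named_params()

    def n_params(self) -> int:
        return self.model.n_params()

    def feature_param_names(self) -> list[str]:
        """Parameters of all layers except the two output heads."""
        return [k for k in self.weights if not k.startswith("head_")]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.weights)
        meta = {"config": asdict(self.config), "mode": self.mode, "stage_tag": self.stage_tag}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        state = build_model(BackboneConfig(**meta["config"]), meta["mode"])
        state.stage_tag = meta["stage_tag"]
        with np.load(path.with_suffix(".npz")) as data:
            state.model.set_params({k: data[k] for k in data.files})
        return state


def build_model(config: BackboneConfig, mode: str = "multitask") -> ModelState:
    """Construct a seeded, ready-to-train model for the given variant/mode."""
    return ModelState(config=config, mode=mode, model=_Model(config, mode))


def _check_finite(*arrays: np.ndarray | None) -> None:
    for a in arrays:
        if a is not None and not np.all(np.isfinite(a)):
            raise ValueError("non-finite values in loss inputs")


def loss_terms(batch: MultiTaskBatch, ce_form: str = "printed") -> tuple[float, float]:
    """(cross-entropy term, log-cosh term), each averaged over the batch.

    Requires ``batch.class_probs`` / ``batch.regression_preds`` to be filled;
    an absent prediction yields 0.0 for that term (single-task modes).
    """
    ce = lc = 0.0
    if batch.class_probs is not None:
        p = np.clip(batch.class_probs, EPS, 1.0 - EPS)
        _check_finite(batch.class_probs, batch.class_labels)
        y = batch.class_labels
        if ce_form == "printed":
            ce = float(-np.mean(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p), axis=1)))
        else:
            ce = float(-np.mean(np.sum(y * np.log(p), axis=1)))
    if batch.regression_preds is not None:
        _check_finite(batch.regression_preds, batch.regression_targets)
        resid = np.abs(batch.regression_preds - batch.regression_targets)
        # stable log cosh: |x| + log1p(exp(-2|x|)) - log 2
        lc = float(np.mean(resid + np.log1p(np.exp(-2.0 * resid)) - np.log(2.0)))
    return ce, lc


def multitask_loss(batch: MultiTaskBatch, w_class: float = 1.0, w_reg: float = 1.0,
                   ce_form: str = "printed") -> float:
    """Composite loss ``w_class * CE + w_reg * LC``.

    With ``w_reg=0`` this equals the classification-only loss, with
    ``w_class=0`` the regression-only loss (single-task ablations).
    """
    ce, lc = loss_terms(batch, ce_form=ce_form)
    return w_class * ce + w_reg * lc


def predict(state: ModelState, batch: MultiTaskBatch) -> MultiTaskBatch:
    """Run inference (dropout disabled); fills class_probs and
    regression_preds in place and returns the batch."""
    if batch.inputs.shape[2] != state.config.window_length:
        raise ValueError(
            f"input length {batch.inputs.shape[2]} != configured "
            f"{state.config.window_length}"
        )
    logits, reg = state.model.forward(batch.inputs, train=False)
    if logits is not None:
        batch.class_probs = nn.softmax(logits, axis=1)
    if reg is not None:
        batch.regression_preds = reg
    return batch
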