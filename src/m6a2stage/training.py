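"""Training loops: stage-1 multi-task SGD, 5-fold grid-search CV, and stage-2
transfer learning with a from-scratch control.

Stage 1 learns to separate low-resolution m6A windows from motif-matched
background while regressing the normalized SupportNum.  Stage 2 re-uses every
layer except the output heads of a stage-1 model as initialization (no
freezing by default) and re-optimizes only the ``epochs`` hyperparameter by
cross-validation, comparing against the same architecture trained from random
initialization over two epoch grids.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .dataset_builder import DatasetSplit
from .encoding import encode_split, make_batches
from .evaluation import EvalReport, evaluate_model
from .networks import BackboneConfig, ModelState, build_model, loss_terms
from . import nn

__all__ = [
    "TrainLog",
    "CVResult",
    "TransferPlan",
    "train_model",
    "train_stage1",
    "grid_search_cv",
    "transfer_stage2",
    "stratified_fold_indices",
]

#: BackboneConfig fields that a hyperparameter grid may set
_CONFIG_KEYS = {
    "conv_kernel_size", "pool_size", "dropout_rate", "conv_filters",
    "bilstm_hidden", "transformer_heads", "transformer_ff_dim", "dense_units",
    "variant", "task_specific_dense", "loss_weight_class", "loss_weight_reg",
}
_TRAIN_KEYS = {"epochs", "lr", "momentum", "batch_size"}


@dataclass
class TrainLog:
    """Per-epoch loss components (and optional validation AUROC)."""

    epochs: list[dict] = field(default_factory=list)

    def append(self, **row) -> None:
        self.epochs.append(row)

    @property
    def final_loss(self) -> float:
        return self.epochs[-1]["total"] if self.epochs else float("nan")

    @property
    def initial_loss(self) -> float:
        return self.epochs[0]["total"] if self.epochs else float("nan")


@dataclass
class CVResult:
    """Cross-validation outcome: per-combination table and the chosen one."""

    table: list[dict]  # one row per hyperparameter combination
    best: dict  # chosen combination (hyperparameters only)
    best_mean_auroc: float
    fold_reports: list[EvalReport]  # folds of the chosen combination
    folds: int
    seed: int

    def metric_mean_std(self, metric: str) -> tuple[float, float]:
        vals = [getattr(r, metric) for r in self.fold_reports]
        return float(np.mean(vals)), float(np.std(vals))


@dataclass
class TransferPlan:
    """How stage-2 initializes from a stage-1 model."""

    source: ModelState
    freeze: bool = False
    epochs_grid: tuple[int, ...] = (16, 32, 64, 128, 256)
    scratch_epochs_grids: tuple[tuple[int, ...], ...] = (
        (16, 32, 64, 128, 256),
        (76, 92, 124, 188, 316),
    )


def _training_step(
    state: ModelState,
    batch,
    optimizer: nn.SGD,
    w_class: float,
    w_reg: float,
    ce_form: str,
    frozen: set[str] | None = None,
) -> tuple[float, float]:
    logits, reg = state.model.forward(batch.inputs, train=True)
    for out in (logits, reg):
        if out is not None and not np.all(np.isfinite(out)):
            raise RuntimeError(
                "training diverged: non-finite model outputs; "
                "reduce the learning rate"
            )
    N = batch.n
    dlogits = dreg = None
    if logits is not None:
        probs = nn.softmax(logits, axis=1)
        batch.class_probs = probs
        gf = 2.0 if ce_form == "printed" else 1.0
        dlogits = w_class * gf * (probs - batch.class_labels) / N
    if reg is not None:
        batch.regression_preds = reg
        dreg = w_reg * np.tanh(reg - batch.regression_targets) / N
    ce, lc = loss_terms(batch, ce_form=ce_form)
    total = w_class * ce + w_reg * lc
    if not np.isfinite(total):
        raise RuntimeError(
            f"training diverged: loss={total} (ce={ce}, lc={lc}); "
            "reduce the learning rate"
        )
    state.model.backward(dlogits, dreg)
    grads = state.model.named_grads()
    if frozen:
        grads = {k: v for k, v in grads.items() if k not in frozen}
    optimizer.step(grads)
    return ce, lc


def train_model(
    state: ModelState,
    train: DatasetSplit,
    epochs: int,
    lr: float = 0.01,
    momentum: float = 0.9,
    batch_size: int = 128,
    seed: int = 0,
    val: DatasetSplit | None = None,
    frozen: set[str] | None = None,
) -> TrainLog:
    """SGD-train a built model in place; returns the per-epoch loss log.

    Zero epochs is a no-op (weights keep their initialization).  A NaN loss
    aborts with a diagnostic.
    """
    cfg = state.config
    w_class = cfg.loss_weight_class if state.mode != "regress_only" else 0.0
    w_reg = cfg.loss_weight_reg if state.mode != "classify_only" else 0.0
    optimizer = nn.SGD(state.model.named_params(), lr=lr, momentum=momentum)
    log = TrainLog()
    for epoch in range(epochs):
        ce_sum = lc_sum = 0.0
        n_batches = 0
        for batch in make_batches(train, batch_size, seed, epoch=epoch):
            ce, lc = _training_step(state, batch, optimizer, w_class, w_reg, cfg.ce_form, frozen)
            ce_sum += ce
            lc_sum += lc
            n_batches += 1
        row = {
            "epoch": epoch,
            "ce": ce_sum / n_batches,
            "lc": lc_sum / n_batches,
            "total": (w_class * ce_sum + w_reg * lc_sum) / n_batches,
        }
        if val is not None:
            row["val_auroc"] = evaluate_model(state, val).AUROC
        log.append(**row)
    return log


def train_stage1(
    train: DatasetSplit,
    config: BackboneConfig,
    epochs: int = 60,
    lr: float = 0.01,
    momentum: float = 0.9,
    batch_size: int = 128,
    seed: int = 0,
    mode: str = "multitask",
    val: DatasetSplit | None = None,
) -> tuple[ModelState, TrainLog]:
    """Build and train the stage-1 model (multitask by default)."""
    state = build_model(config, mode=mode)
    state.stage_tag = "stage1"
    state.support_normalizer = train.normalizer
    log = train_model(state, train, epochs=epochs, lr=lr, momentum=momentum,
                      batch_size=batch_size, seed=seed, val=val)
    return state, log


def stratified_fold_indices(labels: np.ndarray, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Label-stratified K-fold partition of sample indices."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(labels)), labels)]


def _subset(split: DatasetSplit, idx: np.ndarray, name: str) -> DatasetSplit:
    return DatasetSplit(name=name, windows=[split.windows[i] for i in idx],
                        normalizer=split.normalizer)


def _cv_eval(
    split: DatasetSplit,
    folds: int,
    seed: int,
    build_fn,
    epochs: int,
    lr: float,
    momentum: float,
    batch_size: int,
) -> list[EvalReport]:
    """Train a fresh model per fold (via build_fn) and evaluate on the held
    fold."""
    labels = np.array([w.label for w in split.windows])
    reports = []
    for f, (tr, va) in enumerate(stratified_fold_indices(labels, folds, seed)):
        state = build_fn(f)
        train_model(state, _subset(split, tr, f"{split.name}_cvtrain{f}"),
                    epochs=epochs, lr=lr, momentum=momentum,
                    batch_size=batch_size, seed=seed + f)
        reports.append(evaluate_model(state, _subset(split, va, f"{split.name}_cvval{f}")))
    return reports


def grid_search_cv(
    train: DatasetSplit,
    grid: dict[str, list],
    folds: int = 5,
    seed: int = 0,
    base_config: BackboneConfig | None = None,
    mode: str = "multitask",
    epochs: int = 60,
    lr: float = 0.01,
    momentum: float = 0.9,
    batch_size: int = 128,
) -> CVResult:
    """Exhaustive hyperparameter grid search with stratified K-fold CV.

    Grid keys may be BackboneConfig fields or training parameters (epochs,
    lr, momentum, batch_size).  Selection metric is mean CV AUROC; ties break
    by smaller parameter count, then grid order.  A combination that fails to
    build is recorded as failed, not fatal.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not grid:
        raise ValueError("grid must be non-empty")
    unknown = set(grid) - _CONFIG_KEYS - _TRAIN_KEYS
    if unknown:
        raise ValueError(f"unknown grid keys: {sorted(unknown)}")
    base_config = base_config or BackboneConfig()
    keys = list(grid)
    table: list[dict] = []
    results: list[tuple[float, int, int, dict, list[EvalReport]]] = []
    for order, combo_vals in enumerate(itertools.product(*(grid[k] for k in keys))):
        combo = dict(zip(keys, combo_vals))
        cfg_kwargs = {k: v for k, v in combo.items() if k in _CONFIG_KEYS}
        tr_kwargs = {k: v for k, v in combo.items() if k in _TRAIN_KEYS}
        row = dict(combo)
        try:
            cfg = BackboneConfig(**{**_cfg_dict(base_config), **cfg_kwargs})
            reports = _cv_eval(
                train, folds, seed,
                build_fn=lambda f: build_model(cfg, mode=mode),
                epochs=tr_kwargs.get("epochs", epochs),
                lr=tr_kwargs.get("lr", lr),
                momentum=tr_kwargs.get("momentum", momentum),
                batch_size=tr_kwargs.get("batch_size", batch_size),
            )
        except (ValueError, RuntimeError) as exc:
            row.update(status="failed", error=str(exc))
            table.append(row)
            continue
        mean_auroc = float(np.mean([r.AUROC for r in reports]))
        n_params = build_model(cfg, mode=mode).n_params()
        row.update(
            status="ok",
            mean_auroc=mean_auroc,
            std_auroc=float(np.std([r.AUROC for r in reports])),
            n_params=n_params,
        )
        if mode == "multitask":
            rs = [r.pearson_r for r in reports if r.pearson_r is not None]
            if rs:
                row["mean_pearson_r"] = float(np.mean(rs))
        table.append(row)
        results.append((mean_auroc, n_params, order, combo, reports))
    if not results:
        raise RuntimeError("every grid combination failed")
    results.sort(key=lambda t: (-t[0], t[1], t[2]))
    best_auroc, _, _, best_combo, best_reports = results[0]
    return CVResult(table=table, best=best_combo, best_mean_auroc=best_auroc,
                    fold_reports=best_reports, folds=folds, seed=seed)


def _cfg_dict(config: BackboneConfig) -> dict:
    from dataclasses import asdict

    return asdict(config)


def _transfer_init(plan: TransferPlan, config: BackboneConfig, mode: str, seed: int) -> ModelState:
    """Fresh model with feature layers copied bit-exact from the source."""
    cfg = BackboneConfig(**{**_cfg_dict(config), "seed": seed})
    state = build_model(cfg, mode=mode)
    state.stage_tag = "stage2"
    src = plan.source.weights
    dst = state.weights
    feature_names = [k for k in dst if not k.startswith("head_")]
    missing = [k for k in feature_names if k not in src]
    if missing:
        raise ValueError(f"source model lacks layers: {missing}")
    for k in feature_names:
        if src[k].shape != dst[k].shape:
            raise ValueError(
                f"shape mismatch for transferred layer {k}: "
                f"{src[k].shape} vs {dst[k].shape}"
            )
    state.model.set_params({k: src[k].copy() for k in feature_names})
    for k in feature_names:  # copy semantics must be bit-exact
        assert np.array_equal(state.weights[k], src[k])
    return state


def transfer_stage2(
    plan: TransferPlan,
    stage2_train: DatasetSplit,
    config: BackboneConfig,
    seed: int = 0,
    mode: str = "classify_only",
    folds: int = 5,
    lr: float = 0.01,
    momentum: float = 0.9,
    batch_size: int = 128,
    train_scratch_control: bool = True,
) -> tuple[ModelState, dict]:
    """Stage-2 model by transfer learning, with a from-scratch control.

    Every layer except the output head(s) is initialized from the stage-1
    source (verified bit-equal before training); heads are re-initialized from
    ``seed``; nothing is frozen unless ``plan.freeze``.  The ``epochs``
    hyperparameter is chosen by CV over ``plan.epochs_grid``; the scratch
    control (same architecture, random init) is CV-scored over
    ``plan.scratch_epochs_grids``.  Returns the final transfer model (trained
    on all of ``stage2_train`` at the best epochs) and a result dict with the
    transfer and scratch CV tables.
    """
    frozen = set()
    if plan.freeze:
        probe = _transfer_init(plan, config, mode, seed)
        frozen = set(probe.feature_param_names())

    def cv_over_epochs(build_fn, grid: tuple[int, ...]) -> list[dict]:
        rows = []
        for epochs in grid:
            reports = _cv_eval(stage2_train, folds, seed, build_fn,
                               epochs=epochs, lr=lr, momentum=momentum,
                               batch_size=batch_size)
            rows.append({
                "epochs": epochs,
                "mean_auroc": float(np.mean([r.AUROC for r in reports])),
                "std_auroc": float(np.std([r.AUROC for r in reports])),
            })
        return rows

    transfer_table = cv_over_epochs(
        lambda f: _transfer_init(plan, config, mode, seed + f), plan.epochs_grid
    )
    best_row = max(transfer_table, key=lambda r: r["mean_auroc"])
    result = {
        "transfer_table": transfer_table,
        "best_epochs": best_row["epochs"],
        "transfer_cv_auroc": best_row["mean_auroc"],
    }

    if train_scratch_control:
        scratch_tables = []
        for gi, grid in enumerate(plan.scratch_epochs_grids):
            scratch_tables.append(cv_over_epochs(
                lambda f: _scratch_model(config, mode, seed + 1000 + f), grid
            ))
        result["scratch_tables"] = scratch_tables
        best_scratch = max(
            (row for tab in scratch_tables for row in tab),
            key=lambda r: r["mean_auroc"],
        )
        result["scratch_cv_auroc"] = best_scratch["mean_auroc"]
        result["scratch_best_epochs"] = best_scratch["epochs"]

    final = _transfer_init(plan, config, mode, seed)
    train_model(final, stage2_train, epochs=best_row["epochs"], lr=lr,
                momentum=momentum, batch_size=batch_size, seed=seed,
                frozen=frozen or None)
    return final, result


def _scratch_model(config: BackboneConfig, mode: str, seed: int) -> ModelState:
    cfg = BackboneConfig(**{**_cfg_dict(config), "seed": seed})
    state = build_model(cfg, mode=mode)
    state.stage_tag = "stage2"
    return state
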