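"""Desk-scale benchmark experiments on synthetic genomes.

These drivers wire the full pipeline together — simulate a genome with
planted m6A-like signal, build balanced splits, train, evaluate — at sizes a
single CPU handles in minutes.  They are used by the acceptance tests and the
reproduction script, and serve as end-to-end usage examples of the library.

Default problem sizes: stage 1 uses 1,000 sites per class with 301-nt windows
(half-width 150) and 60 training epochs; the transfer comparison uses 600
positives (half base-resolution) with 101-nt windows.  These are the
package's desk-scale stand-ins for the original database-scale datasets.
"""

from __future__ import annotations

import numpy as np

from .dataset_builder import (
    DatasetSplit,
    apply_support_normalizer,
    balance_by_undersampling,
    fit_support_normalizer,
    split_train_test,
)
from .evaluation import evaluate_model
from .genome_io import extract_window
from .networks import BackboneConfig
from .synthetic_data import SyntheticSpec, simulate
from .training import TransferPlan, train_stage1, transfer_stage2

__all__ = ["make_stage1_splits", "run_stage1_experiment", "run_transfer_comparison"]


def make_stage1_splits(
    spec: SyntheticSpec,
) -> tuple[DatasetSplit, DatasetSplit, "SyntheticTruth"]:
    """Simulate and assemble normalized, balanced stage-1 train/test splits."""
    genome, pos, neg, truth = simulate(spec)
    k = spec.half_width
    pos_w = [extract_window(genome, s, k=k, label=1) for s in pos]
    neg_w = [extract_window(genome, s, k=k, label=0) for s in neg]
    balanced = balance_by_undersampling(pos_w, neg_w, seed=spec.seed, name="stage1")
    train, test = split_train_test(balanced, ratio=0.8, seed=spec.seed)
    normalizer = fit_support_normalizer(train)
    apply_support_normalizer(train, normalizer)
    apply_support_normalizer(test, normalizer)
    return train, test, truth


def run_stage1_experiment(
    seed: int,
    signal_strength: float = 1.5,
    n_per_class: int = 1000,
    half_width: int = 150,
    epochs: int = 60,
    lr: float = 0.01,
    batch_size: int = 128,
    variant: str = "cnn_bilstm",
) -> dict:
    """Train the stage-1 multitask model on a fresh synthetic fixture and
    evaluate on the held-out test split.

    Returns the held-out AUROC/Acc/MCC, the regression-head Pearson r against
    the normalized SupportNum targets, and the baseline Pearson r obtained
    from the classification probability against the same targets.
    """
    spec = SyntheticSpec(
        n_pos=n_per_class, n_neg=n_per_class, half_width=half_width,
        signal_strength=signal_strength, seed=seed,
    )
    train, test, _ = make_stage1_splits(spec)
    config = BackboneConfig(
        variant=variant, window_length=2 * half_width + 1, seed=seed
    )
    state, log = train_stage1(
        train, config, epochs=epochs, lr=lr, batch_size=batch_size, seed=seed
    )
    report = evaluate_model(state, test)
    return {
        "auroc": report.AUROC,
        "acc": report.Acc,
        "mcc": report.MCC,
        "auprc": report.AUPRC,
        "pearson_r": report.pearson_r,
        "prob_vs_target_r": report.prob_vs_target_r,
        "final_train_loss": log.final_loss,
        "initial_train_loss": log.initial_loss,
        "n_train": len(train),
        "n_test": len(test),
        "seed": seed,
        "signal_strength": signal_strength,
    }


def run_transfer_comparison(
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    n_pos: int = 600,
    half_width: int = 50,
    stage1_epochs: int = 30,
    stage2_epochs_grid: tuple[int, ...] = (24,),
    folds: int = 3,
    stage2_shift: float = 0.3,
    base_seed: int = 11,
    lr: float = 0.01,
    batch_size: int = 128,
) -> dict:
    """Paired-seed comparison of transfer learning vs training from scratch.

    One synthetic fixture provides the stage-1 task (positives vs background)
    and the stage-2 task (base-resolution positives vs low-resolution-only
    positives, i.e. shifted- vs original-flank signal).  A stage-1 source
    model is trained once; then, for each seed, the stage-2 model is scored
    by stratified CV both from transfer initialization and from random
    initialization.  Returns per-seed and mean CV AUROCs.
    """
    k = half_width
    spec = SyntheticSpec(
        n_pos=n_pos, n_neg=n_pos, half_width=k, stage2_fraction=0.5,
        stage2_shift=stage2_shift, seed=base_seed,
    )
    genome, pos, neg, truth = simulate(spec)
    pos_w = [extract_window(genome, s, k=k, label=1) for s in pos]
    neg_w = [extract_window(genome, s, k=k, label=0) for s in neg]
    balanced = balance_by_undersampling(pos_w, neg_w, seed=base_seed, name="s1")
    tr1, te1 = split_train_test(balanced, 0.8, seed=base_seed)
    normalizer = fit_support_normalizer(tr1)
    apply_support_normalizer(tr1, normalizer)
    apply_support_normalizer(te1, normalizer)
    config = BackboneConfig(variant="cnn_bilstm", window_length=2 * k + 1,
                            seed=base_seed)
    source, _ = train_stage1(tr1, config, epochs=stage1_epochs, lr=lr,
                             batch_size=batch_size, seed=base_seed)

    s2_pos = [extract_window(genome, s, k=k, label=1)
              for s in truth.stage2_positive_sites()]
    s2_neg = [extract_window(genome, s, k=k, label=0)
              for s in truth.stage2_negative_sites()]
    stage2 = balance_by_undersampling(s2_pos, s2_neg, seed=base_seed, name="stage2")

    transfer_aurocs, scratch_aurocs = [], []
    for seed in seeds:
        plan = TransferPlan(source=source, epochs_grid=stage2_epochs_grid,
                            scratch_epochs_grids=(stage2_epochs_grid,))
        _, result = transfer_stage2(plan, stage2, config, seed=seed,
                                    folds=folds, lr=lr, batch_size=batch_size)
        transfer_aurocs.append(result["transfer_cv_auroc"])
        scratch_aurocs.append(result["scratch_cv_auroc"])
    return {
        "transfer_cv_aurocs": transfer_aurocs,
        "scratch_cv_aurocs": scratch_aurocs,
        "mean_transfer_auroc": float(np.mean(transfer_aurocs)),
        "mean_scratch_auroc": float(np.mean(scratch_aurocs)),
        "stage1_source_auroc": evaluate_model(source, te1).AUROC,
        "n_stage2": len(stage2),
        "seeds": list(seeds),
    }
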