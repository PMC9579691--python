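"""Benchmark-dataset construction: redundancy reduction, balancing, splitting,
SupportNum normalization.

The pipeline order is: redundancy reduction within each class (greedy
clustering at sequence identity 0.7), under-sampling of the larger class to
balance, then a stratified 4:1 train/test split.  SupportNum (the number of
experiments supporting a site) is min-max normalized to [0,1] on the training
positives and applied with clipping elsewhere; negative windows get target 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import Genome, GenomicSite, SequenceWindow, extract_window

__all__ = [
    "DatasetSplit",
    "SupportNormalizer",
    "ClusterAssignment",
    "reduce_redundancy",
    "pairwise_identity",
    "balance_by_undersampling",
    "split_train_test",
    "fit_support_normalizer",
    "apply_support_normalizer",
    "build_stage2_dataset",
]


@dataclass
class SupportNormalizer:
    """Min-max transform of SupportNum fitted on training positives.

    transform maps min -> 0 and max -> 1 and clips outside the fitted range;
    inverse_transform is exact for in-range values.
    """

    min_value: float
    max_value: float

    def __post_init__(self) -> None:
        if not self.max_value > self.min_value:
            raise ValueError("constant support values: max must exceed min")

    def transform(self, value: float) -> float:
        t = (value - self.min_value) / (self.max_value - self.min_value)
        return min(1.0, max(0.0, t))

    def inverse_transform(self, target: float) -> float:
        return self.min_value + target * (self.max_value - self.min_value)


@dataclass
class DatasetSplit:
    """A named list of labeled windows with bookkeeping counts."""

    name: str
    windows: list[SequenceWindow]
    normalizer: SupportNormalizer | None = None

    @property
    def positives(self) -> int:
        return sum(1 for w in self.windows if w.label == 1)

    @property
    def negatives(self) -> int:
        return sum(1 for w in self.windows if w.label == 0)

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class ClusterAssignment:
    """Greedy-clustering result: cluster index per input sequence."""

    representatives: list[int]  # input indices that founded clusters
    membership: list[int]  # input index -> cluster index
    identity_threshold: float


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of positions with identical characters (equal-length,
    ungapped)."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def reduce_redundancy(
    windows: list[SequenceWindow], threshold: float = 0.7, seed: int = 0
) -> tuple[list[SequenceWindow], ClusterAssignment]:
    """Greedy incremental clustering at the given identity threshold.

    Sequences are visited in input order; each joins the first existing
    representative with identity >= threshold, else founds a new cluster.
    Only representatives are returned.  Identity is the exact-match fraction
    over the equal-length ungapped windows.  ``seed`` is accepted for API
    symmetry but has no effect: input order plus first-match assignment leaves
    no ties to break.  Positives and negatives should be clustered separately
    by the caller.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if not windows:
        return [], ClusterAssignment([], [], threshold)
    length = len(windows[0].sequence)
    if any(len(w.sequence) != length for w in windows):
        raise ValueError("all windows must have equal length")

    # byte matrix for vectorized candidate-vs-representative comparison
    mat = np.frombuffer(
        "".join(w.sequence for w in windows).encode("ascii"), dtype=np.uint8
    ).reshape(len(windows), length)

    rep_indices: list[int] = []
    membership: list[int] = []
    rep_mat = np.empty((0, length), dtype=np.uint8)
    for i in range(len(windows)):
        if rep_indices:
            ident = (rep_mat == mat[i]).mean(axis=1)
            hits = np.nonzero(ident >= threshold)[0]
            if hits.size:
                membership.append(int(hits[0]))
                continue
        membership.append(len(rep_indices))
        rep_indices.append(i)
        rep_mat = np.vstack([rep_mat, mat[i : i + 1]])
    reps = [windows[i] for i in rep_indices]
    return reps, ClusterAssignment(rep_indices, membership, threshold)


def balance_by_undersampling(
    pos: list[SequenceWindow], neg: list[SequenceWindow], seed: int, name: str = "balanced"
) -> DatasetSplit:
    """Uniformly subsample the larger class to the smaller class's size and
    shuffle deterministically."""
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)
    if len(neg) > len(pos):
        idx = rng.choice(len(neg), size=len(pos), replace=False)
        neg = [neg[i] for i in sorted(idx)]
    elif len(pos) > len(neg):
        idx = rng.choice(len(pos), size=len(neg), replace=False)
        pos = [pos[i] for i in sorted(idx)]
    windows = pos + neg
    order = rng.permutation(len(windows))
    return DatasetSplit(name=name, windows=[windows[i] for i in order])


def split_train_test(
    dataset: DatasetSplit, ratio: float = 0.8, seed: int = 0
) -> tuple[DatasetSplit, DatasetSplit]:
    """Stratified train/test split; train gets floor(ratio * n) per class.

    With the 4:1 convention (ratio 0.8) a class of 10,937 yields 8,749 train
    and 2,188 test, matching floor arithmetic.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    pos = [w for w in dataset.windows if w.label == 1]
    neg = [w for w in dataset.windows if w.label == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs >= 2 windows to stratify")
    rng = np.random.default_rng(seed)
    train: list[SequenceWindow] = []
    test: list[SequenceWindow] = []
    for group in (pos, neg):
        n_train = int(np.floor(ratio * len(group)))
        perm = rng.permutation(len(group))
        train.extend(group[i] for i in perm[:n_train])
        test.extend(group[i] for i in perm[n_train:])
    train = [train[i] for i in rng.permutation(len(train))]
    test = [test[i] for i in rng.permutation(len(test))]
    return (
        DatasetSplit(name=f"{dataset.name}_train", windows=train, normalizer=dataset.normalizer),
        DatasetSplit(name=f"{dataset.name}_test", windows=test, normalizer=dataset.normalizer),
    )


def fit_support_normalizer(train: DatasetSplit) -> SupportNormalizer:
    """Fit min-max bounds on the SupportNum of training positives."""
    supports = [w.site.support_num for w in train.windows if w.label == 1]
    if len(set(supports)) < 2:
        raise ValueError("need at least two distinct support values among positives")
    return SupportNormalizer(min_value=min(supports), max_value=max(supports))


def apply_support_normalizer(
    split: DatasetSplit, normalizer: SupportNormalizer, negative_target: float = 0.0
) -> DatasetSplit:
    """Attach regression targets: normalized SupportNum for positives,
    ``negative_target`` (default 0: no experimental support) for negatives."""
    for w in split.windows:
        w.support_target = (
            normalizer.transform(w.site.support_num) if w.label == 1 else negative_target
        )
    split.normalizer = normalizer
    return split


def build_stage2_dataset(
    atlas_sites: list[GenomicSite],
    rmbase_sites: list[GenomicSite],
    genome: Genome,
    k: int = 300,
    threshold: float = 0.7,
    seed: int = 0,
    ratio: float = 0.8,
    name: str = "stage2",
) -> tuple[DatasetSplit, DatasetSplit]:
    """Base-resolution vs low-resolution dataset.

    Positives are the base-resolution (atlas) sites; negatives are the
    low-resolution (rmbase) sites absent from the atlas.  Both classes are
    redundancy-reduced at ``threshold``, negatives under-sampled to the
    positive count, and the result split 4:1 stratified.
    """
    atlas_keys = {s.key for s in atlas_sites}
    neg_sites = [s for s in rmbase_sites if s.key not in atlas_keys]
    if not neg_sites:
        raise ValueError("no negatives remain after removing atlas overlap")
    pos_windows = [extract_window(genome, s, k=k, label=1) for s in atlas_sites]
    neg_windows = [extract_window(genome, s, k=k, label=0) for s in neg_sites]
    pos_reps, _ = reduce_redundancy(pos_windows, threshold, seed)
    neg_reps, _ = reduce_redundancy(neg_windows, threshold, seed)
    balanced = balance_by_undersampling(pos_reps, neg_reps, seed=seed, name=name)
    return split_train_test(balanced, ratio=ratio, seed=seed)
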