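"""One-hot encoding of RNA windows and mini-batch assembly.

Alphabet order is fixed: A, U, C, G map to the unit columns
(1,0,0,0), (0,1,0,0), (0,0,1,0), (0,0,0,1); the padding pseudo-nucleotide N
maps to the all-zero column.  An encoded window is a 4 x L matrix whose
column j encodes position j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_builder import DatasetSplit
from .genome_io import SequenceWindow

__all__ = ["ALPHABET", "one_hot_encode", "decode", "MultiTaskBatch", "make_batches", "encode_split"]

ALPHABET = "AUCG"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}


def one_hot_encode(window: SequenceWindow | str) -> np.ndarray:
    """Encode a window (or raw sequence over {A,U,C,G,N}) as a 4 x L float
    matrix; 'N' columns are all-zero."""
    seq = window.sequence if isinstance(window, SequenceWindow) else window
    mat = np.zeros((4, len(seq)), dtype=np.float64)
    for j, c in enumerate(seq):
        if c == "N":
            continue
        i = _INDEX.get(c)
        if i is None:
            raise ValueError(f"unexpected character {c!r} at position {j}")
        mat[i, j] = 1.0
    return mat


def decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero columns decode to 'N'."""
    if matrix.ndim != 2 or matrix.shape[0] != 4:
        raise ValueError("expected a 4 x L matrix")
    chars = []
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        s = col.sum()
        if s == 0:
            chars.append("N")
        elif s == 1 and set(np.unique(col)) <= {0.0, 1.0}:
            chars.append(ALPHABET[int(np.argmax(col))])
        else:
            raise ValueError(f"column {j} is not one-hot")
    return "".join(chars)


@dataclass
class MultiTaskBatch:
    """A batch of encoded windows with both task targets.

    ``class_labels`` are two-class one-hot rows (column 0 = negative,
    column 1 = positive); ``class_probs`` / ``regression_preds`` are filled at
    predict time.
    """

    inputs: np.ndarray  # (N, 4, L)
    class_labels: np.ndarray  # (N, 2) one-hot
    regression_targets: np.ndarray  # (N,) in [0,1]
    windows: list[SequenceWindow] = field(default_factory=list)
    class_probs: np.ndarray | None = None
    regression_preds: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.inputs.shape[0]

    def __post_init__(self) -> None:
        if not (self.inputs.shape[0] == self.class_labels.shape[0] == self.regression_targets.shape[0]):
            raise ValueError("batch arrays must share the leading dimension")


def _encode_windows(windows: list[SequenceWindow]) -> MultiTaskBatch:
    inputs = np.stack([one_hot_encode(w) for w in windows])
    labels = np.zeros((len(windows), 2), dtype=np.float64)
    for i, w in enumerate(windows):
        labels[i, int(w.label)] = 1.0
    targets = np.array(
        [w.support_target if w.support_target is not None else 0.0 for w in windows],
        dtype=np.float64,
    )
    return MultiTaskBatch(inputs=inputs, class_labels=labels, regression_targets=targets, windows=windows)


def encode_split(split: DatasetSplit) -> MultiTaskBatch:
    """Encode a whole split as one batch (for evaluation)."""
    if not split.windows:
        raise ValueError(f"split {split.name!r} is empty")
    return _encode_windows(split.windows)


def make_batches(split: DatasetSplit, batch_size: int, seed: int, epoch: int = 0):
    """Yield deterministically shuffled mini-batches; the short final batch is
    kept.  The shuffle order depends on (seed, epoch) so successive epochs
    reshuffle reproducibly."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if not split.windows:
        raise ValueError(f"split {split.name!r} is empty")
    rng = np.random.default_rng((seed, epoch))
    order = rng.permutation(len(split.windows))
    for start in range(0, len(order), batch_size):
        chunk = [split.windows[i] for i in order[start : start + batch_size]]
        yield _encode_windows(chunk)
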