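"""Shared fixtures: tiny genomes, window factories, and a small trained-model
cache so expensive trainings are shared across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from m6a2stage.genome_io import Genome, GenomicSite, MotifClass, SequenceWindow


@pytest.fixture
def tiny_genome() -> Genome:
    # chrA has one GAC at positions 3-5 (center 4); chrB is A/T only
    return Genome(sequences={"chrA": "GGGACGGTTTAACTT", "chrB": "ATATATATAT"})


def make_window(
    sequence: str,
    label: int = 1,
    support: int = 0,
    chrom: str = "chrT",
    position: int | None = None,
    strand: str = "+",
) -> SequenceWindow:
    """Build a SequenceWindow directly from a sequence string (for tests that
    do not need a genome)."""
    k = len(sequence) // 2
    c = k
    triplet = sequence[c - 1 : c + 2]
    motif = MotifClass(triplet) if triplet in ("GAC", "AAC") else MotifClass.OTHER
    return SequenceWindow(
        sequence=sequence,
        half_width=k,
        motif_class=motif,
        label=label,
        site=GenomicSite(
            chrom=chrom,
            position=position if position is not None else k + 1,
            strand=strand,
            support_num=support,
        ),
    )


@pytest.fixture
def window_factory():
    return make_window


def random_rna(rng: np.random.Generator, length: int, center_motif: str | None = None) -> str:
    seq = "".join(rng.choice(list("AUCG"), size=length))
    if center_motif:
        c = length // 2
        seq = seq[: c - 1] + center_motif + seq[c + 2 :]
    return seq


@pytest.fixture
def rna_factory():
    return random_rna
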