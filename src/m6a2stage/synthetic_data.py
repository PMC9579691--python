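"""Synthetic genomes with planted m6A-like signal, for desk-scale experiments.

The generator emulates the two-stage study design end to end:

* an i.i.d. background genome at a chosen GC content (default 0.38,
  budding-yeast-like), emitted as DNA FASTA;
* positive sites implanted at non-overlapping loci on random strands: the
  central triplet is the requested motif (GAC or AAC) and the flanking
  positions are drawn from a position weight matrix (PWM) sharpened or
  diluted by a single continuous ``signal_strength`` dial (strength 0 makes
  flanks pure background, so positives are indistinguishable from
  motif-matched negatives);
* each positive's "SupportNum" (number of supporting experiments) is drawn
  as 1 + negative-binomial with mean ``lambda * exp(beta * z)`` where z is the
  standardized planted flank log-odds score — so sequence signal and
  experimental support are correlated when beta > 0 and independent at
  beta = 0, and the marginal distribution is strongly right-skewed;
* a fraction of positives is marked base-resolution ("stage 2"): their
  flanks are drawn from a PWM shifted away from the stage-1 PWM by
  ``stage2_shift`` (shift 0 makes the stage-2 task chance level).

The stage-2 task, as in the real pipeline, is to separate base-resolution
positives from the remaining (low-resolution-only) positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import Genome, GenomicSite, reverse_complement, write_site_table

__all__ = ["SyntheticSpec", "SyntheticTruth", "default_pwm", "simulate",
           "support_histogram", "write_fixture"]

_BASES = "ACGT"  # genome alphabet (DNA; pipeline converts to U at emission)
_RNA_BASES = "ACGU"


def default_pwm(motif: str = "GAC", flank: int = 6, enrichment: float = 0.6,
                plateau: int = 4) -> np.ndarray:
    """An RRACH-compatible default PWM of width 2*flank + 3.

    The central triplet columns are fixed to the motif.  Flank columns within
    ``plateau`` of the center favor one base at probability ``enrichment``
    (position -2 favors A/G and +2 favors A/C/U, echoing the RRACH consensus);
    remaining columns are uniform.  Rows follow A, C, G, U.
    """
    width = 2 * flank + 3
    pwm = np.full((4, width), 0.25)
    center = width // 2
    for off, base in zip((-1, 0, 1), motif):
        col = np.zeros(4)
        col[_RNA_BASES.index(base if base != "T" else "U")] = 1.0
        pwm[:, center + off] = col
    favored_cycle = [0, 2, 1, 3]  # A, G, C, U
    j = 0
    for off in range(-flank, flank + 1):
        if off in (-1, 0, 1):
            continue
        if abs(off) <= plateau + 1:
            if off == -2:
                fav = [0, 2]  # R = A/G
            elif off == 2:
                fav = [0, 1, 3]  # H = A/C/U
            else:
                fav = [favored_cycle[j % 4]]
                j += 1
            col = np.full(4, (1.0 - enrichment) / (4 - len(fav)))
            col[fav] = enrichment / len(fav)
        else:
            col = np.full(4, 0.25)
        pwm[:, center + off] = col
    return pwm


@dataclass
class SyntheticSpec:
    """All knobs of the simulator; every random draw derives from ``seed``."""

    n_pos: int = 1000
    n_neg: int = 1000
    half_width: int = 150
    motif: str = "GAC"
    genome_length: int | None = None  # computed from site count if None
    gc_content: float = 0.38
    pwm: np.ndarray = field(default_factory=default_pwm)
    signal_strength: float = 1.5
    support_lambda: float = 3.0
    support_beta: float = 0.8
    support_dispersion: float = 4.0  # negative-binomial shape; larger = less noise
    stage2_fraction: float = 0.5
    stage2_shift: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if not 0.0 < self.stage2_fraction <= 1.0:
            raise ValueError("stage2_fraction must be in (0, 1]")
        pwm = np.asarray(self.pwm, dtype=float)
        if pwm.shape[0] != 4 or pwm.shape[1] % 2 == 0:
            raise ValueError("pwm must be 4 x odd-width")
        if not np.allclose(pwm.sum(axis=0), 1.0):
            raise ValueError("pwm columns must be probability vectors")
        if pwm.shape[1] > 2 * self.half_width + 1:
            raise ValueError("pwm wider than the window")


@dataclass
class SyntheticTruth:
    """Ground truth for every planted site."""

    sites: list[GenomicSite]
    labels: np.ndarray  # 1 positive, 0 negative
    signal_scores: np.ndarray  # standardized planted flank log-odds (0 for negatives)
    support_nums: np.ndarray  # >= 1 positives, 0 negatives
    stage2_members: np.ndarray  # bool; False for negatives

    def positives(self) -> list[GenomicSite]:
        return [s for s, l in zip(self.sites, self.labels) if l == 1]

    def negatives(self) -> list[GenomicSite]:
        return [s for s, l in zip(self.sites, self.labels) if l == 0]

    def stage2_positive_sites(self) -> list[GenomicSite]:
        """Base-resolution sites (the stage-2 positive class)."""
        return [s for s, l, m in zip(self.sites, self.labels, self.stage2_members)
                if l == 1 and m]

    def stage2_negative_sites(self) -> list[GenomicSite]:
        """Low-resolution-only sites (the stage-2 negative class)."""
        return [s for s, l, m in zip(self.sites, self.labels, self.stage2_members)
                if l == 1 and not m]


def _background_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T


def _mix_pwm(pwm: np.ndarray, bg: np.ndarray, strength: float) -> np.ndarray:
    """Geometric interpolation p ∝ bg * (pwm/bg)^s, column-wise.

    s=0 gives background, s=1 the PWM itself, s>1 a sharpened PWM.  PWM
    entries are floored at 1e-3 so deterministic columns stay usable."""
    p = np.clip(pwm, 1e-3, None)
    p = p / p.sum(axis=0, keepdims=True)
    mixed = bg[:, None] * (p / bg[:, None]) ** strength
    return mixed / mixed.sum(axis=0, keepdims=True)


def _shift_pwm(pwm: np.ndarray, shift: float) -> np.ndarray:
    """Stage-2 PWM: flank columns blended toward a distinct alternative.

    The alternative swaps each flank column's preference by rolling its
    probabilities one base; shift=0 returns the original, shift=1 the fully
    swapped PWM.  Central triplet columns are untouched."""
    shift = float(np.clip(shift, 0.0, 1.0))
    out = pwm.copy()
    center = pwm.shape[1] // 2
    for j in range(pwm.shape[1]):
        if abs(j - center) <= 1:
            continue
        alt = np.roll(pwm[:, j], 1)
        out[:, j] = (1 - shift) * pwm[:, j] + shift * alt
    return out


def simulate(spec: SyntheticSpec) -> tuple[Genome, list[GenomicSite], list[GenomicSite], SyntheticTruth]:
    """Generate (genome, positive sites, negative sites, truth).

    Sites are placed at non-overlapping loci (window half-width apart) on
    random strands; identical seeds give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.half_width
    n_sites = spec.n_pos + spec.n_neg
    spacing = 2 * k + 12
    needed = n_sites * spacing + 2 * k + 2
    length = spec.genome_length or needed
    if length < needed:
        raise ValueError(
            f"genome_length {length} too small for {n_sites} non-overlapping "
            f"windows of half-width {k}; need >= {needed}"
        )
    bg = _background_probs(spec.gc_content)
    genome_arr = rng.choice(4, size=length, p=bg).astype(np.int8)

    # slot centers with jitter, guaranteed non-overlapping
    slack = (length - 2 * k - 2) - (n_sites - 1) * spacing
    start = k + 1 + int(rng.integers(0, max(1, min(slack, 10))))
    centers = start + np.arange(n_sites) * spacing + rng.integers(0, 11, size=n_sites)
    labels = np.zeros(n_sites, dtype=int)
    labels[rng.permutation(n_sites)[: spec.n_pos]] = 1
    strands = np.where(rng.random(n_sites) < 0.5, "+", "-")

    pwm_rna = np.asarray(spec.pwm, dtype=float)
    width = pwm_rna.shape[1]
    half_w = width // 2
    # background probs in RNA row order A,C,G,U equal the DNA ones (T<->U)
    stage1_cols = _mix_pwm(pwm_rna, bg, spec.signal_strength)
    stage2_cols = _mix_pwm(_shift_pwm(pwm_rna, spec.stage2_shift), bg, spec.signal_strength)
    motif_idx = [_RNA_BASES.index(b) for b in spec.motif]

    is_pos = labels == 1
    stage2 = np.zeros(n_sites, dtype=bool)
    pos_idx = np.nonzero(is_pos)[0]
    n_s2 = int(round(spec.stage2_fraction * spec.n_pos))
    stage2[rng.choice(pos_idx, size=n_s2, replace=False)] = True

    raw_scores = np.zeros(n_sites)
    for i in range(n_sites):
        center = centers[i]
        if is_pos[i]:
            cols = stage2_cols if stage2[i] else stage1_cols
            window = np.empty(width, dtype=np.int8)
            score = 0.0
            for j in range(width):
                off = j - half_w
                if -1 <= off <= 1:
                    window[j] = motif_idx[off + 1]
                else:
                    b = rng.choice(4, p=cols[:, j])
                    window[j] = b
                    score += np.log(cols[b, j] / bg[b])
            raw_scores[i] = score
        else:
            window = genome_arr[center - 1 - half_w : center + half_w].copy()
            for off, b in zip((-1, 0, 1), motif_idx):
                window[half_w + off] = b
        # windows are in transcript orientation (RNA indices == DNA indices,
        # with U stored as T); reverse-complement before planting on '-'
        if strands[i] == "-":
            window = (3 - window)[::-1]  # A<->T, C<->G in index space
        genome_arr[center - 1 - half_w : center + half_w] = window

    # standardize positive scores
    z = np.zeros(n_sites)
    if spec.n_pos > 1 and raw_scores[is_pos].std() > 0:
        z[is_pos] = (raw_scores[is_pos] - raw_scores[is_pos].mean()) / raw_scores[is_pos].std()

    support = np.zeros(n_sites, dtype=int)
    mean = spec.support_lambda * np.exp(spec.support_beta * z[is_pos])
    shape = spec.support_dispersion
    lam = rng.gamma(shape, mean / shape)
    support[is_pos] = 1 + rng.poisson(lam)

    chrom = "chrSim"
    seq = "".join(_BASES[b] for b in genome_arr)
    genome = Genome(sequences={chrom: seq})
    sites = [
        GenomicSite(chrom=chrom, position=int(centers[i]), strand=str(strands[i]),
                    support_num=int(support[i]),
                    source="planted-positive" if is_pos[i] else "planted-negative")
        for i in range(n_sites)
    ]
    truth = SyntheticTruth(
        sites=sites, labels=labels, signal_scores=z,
        support_nums=support, stage2_members=stage2,
    )
    positives = [s for s, p in zip(sites, is_pos) if p]
    negatives = [s for s, p in zip(sites, is_pos) if not p]
    return genome, positives, negatives, truth


def support_histogram(truth: SyntheticTruth, bins) -> np.ndarray:
    """Histogram counts of positive-site SupportNum; counts sum to n_pos."""
    bins = np.asarray(bins)
    if bins.size < 2:
        raise ValueError("need at least two bin edges")
    supports = truth.support_nums[truth.labels == 1]
    if supports.size == 0:
        raise ValueError("truth contains no positives")
    counts, _ = np.histogram(supports, bins=bins)
    return counts


def write_fixture(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Emit a complete fixture directory: genome FASTA, positive/negative site
    tables, and a truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, positives, negatives, truth = simulate(spec)
    paths = {
        "genome": outdir / "genome.fasta",
        "positives": outdir / "positive_sites.tsv",
        "negatives": outdir / "negative_sites.tsv",
        "truth": outdir / "truth.tsv",
    }
    with open(paths["genome"], "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for j in range(0, len(seq), 80):
                fh.write(seq[j : j + 80] + "\n")
    write_site_table(positives, paths["positives"])
    write_site_table(negatives, paths["negatives"])
    with open(paths["truth"], "w") as fh:
        fh.write("chrom\tposition\tstrand\tlabel\tsignal_score\tsupport_num\tstage2_member\n")
        for s, l, z, su, m in zip(truth.sites, truth.labels, truth.signal_scores,
                                  truth.support_nums, truth.stage2_members):
            fh.write(f"{s.chrom}\t{s.position}\t{s.strand}\t{l}\t{z:.6f}\t{su}\t{int(m)}\n")
    return paths
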