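"""Genome and site-table I/O, motif-centered window extraction.

m6A deposition happens on adenosines in an RRACH sequence context; the two
central triplets of that context are GAC and AAC.  This module turns a genome
(FASTA) plus a table of candidate adenosines into fixed-length RNA windows
centered on the modified base, ready for encoding:

* windows are ``2k + 1`` nt long (default k = 300, i.e. 601 nt);
* positions running off a chromosome end are padded with ``N``;
* minus-strand sites are reverse-complemented so every emitted window reads
  5'->3' on the transcript strand, and motifs are classified on that strand;
* ``T`` is converted to ``U`` at window emission (the genome keeps DNA).

It also samples motif-matched negative sites: adenosines whose central triplet
equals the requested motif but that are not in the known-positive set.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Genome",
    "GenomicSite",
    "SequenceWindow",
    "MotifClass",
    "WindowRejection",
    "load_genome",
    "load_site_table",
    "write_site_table",
    "extract_window",
    "classify_motif",
    "sample_negative_sites",
    "write_windows_fasta",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")
_RNA = str.maketrans("T", "U")
_VALID = set("ACGTUN")


class MotifClass(str, Enum):
    GAC = "GAC"
    AAC = "AAC"
    OTHER = "OTHER"


class WindowRejection(ValueError):
    """Raised when a site cannot yield a valid window (e.g. center not A)."""


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,U,N}; U complements to A."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicSite:
    """One candidate adenosine: 1-based coordinate on a named chromosome."""

    chrom: str
    position: int  # 1-based, fully closed
    strand: str
    support_num: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.support_num < 0:
            raise ValueError("support_num must be non-negative")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.position, self.strand)


@dataclass
class Genome:
    """In-memory genome: chromosome id -> uppercase nucleotide string."""

    sequences: Mapping[str, str]
    alphabet_mode: str = "DNA"

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            bad = set(seq) - _VALID
            if bad:
                # non-ACGTUN characters are tolerated on load and mapped to N
                # lazily at window emission
                pass

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


@dataclass
class SequenceWindow:
    """A (2k+1)-nt RNA segment centered on a candidate adenosine."""

    sequence: str  # over {A,U,C,G,N}, transcript strand 5'->3'
    half_width: int
    motif_class: MotifClass
    label: int  # 1 positive, 0 negative
    site: GenomicSite
    support_target: float | None = None  # min-max normalized SupportNum

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * self.half_width + 1:
            raise ValueError(
                f"window length {len(self.sequence)} != 2*{self.half_width}+1"
            )


def load_genome(path: str | Path) -> Genome:
    """Read a (possibly multi-record, wrapped) FASTA file into a Genome.

    Lowercase is uppercased; T is kept (conversion to U happens at window
    emission).  Duplicate record ids and empty files are errors.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    with open(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in sequences:
                raise ValueError(f"duplicate FASTA record id {record.id!r} in {path}")
            seq = str(record.seq).upper()
            if not seq:
                raise ValueError(f"empty sequence for record {record.id!r} in {path}")
            sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(sequences=sequences, alphabet_mode="DNA")


def load_site_table(path: str | Path, source: str = "") -> list[GenomicSite]:
    """Read a TSV of sites: columns chrom, position (1-based), strand,
    optional support_num (default 0).  Lines starting with '#' are comments."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "position", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table {path} missing columns: {sorted(missing)}")
    if "support_num" not in df.columns:
        df["support_num"] = 0
    return [
        GenomicSite(
            chrom=str(r.chrom),
            position=int(r.position),
            strand=str(r.strand),
            support_num=int(r.support_num),
            source=source,
        )
        for r in df.itertuples(index=False)
    ]


def write_site_table(sites: Iterable[GenomicSite], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "position": s.position,
                "strand": s.strand,
                "support_num": s.support_num,
            }
            for s in sites
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def _plus_strand_slice(genome: Genome, chrom: str, center: int, k: int) -> str:
    """0-padded ('N') plus-strand slice of length 2k+1 centered at the 1-based
    position ``center``."""
    seq = genome.sequences[chrom]
    lo = center - 1 - k  # 0-based inclusive
    hi = center + k  # 0-based exclusive
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    core = seq[max(lo, 0) : min(hi, len(seq))]
    return "N" * left_pad + core + "N" * right_pad


def _sanitize(seq: str) -> str:
    """Map any character outside {A,C,G,U,N} to N (after T->U)."""
    seq = seq.translate(_RNA)
    if set(seq) <= {"A", "C", "G", "U", "N"}:
        return seq
    return "".join(c if c in "ACGUN" else "N" for c in seq)


def classify_motif(sequence: str) -> MotifClass:
    """Central-triplet motif class of an odd-length window (length >= 3)."""
    if len(sequence) < 3 or len(sequence) % 2 == 0:
        raise ValueError("window must have odd length >= 3")
    c = len(sequence) // 2
    triplet = sequence[c - 1 : c + 2]
    if triplet == "GAC":
        return MotifClass.GAC
    if triplet == "AAC":
        return MotifClass.AAC
    return MotifClass.OTHER


def extract_window(
    genome: Genome,
    site: GenomicSite,
    k: int = 300,
    label: int = 1,
    require_center_a: bool = True,
) -> SequenceWindow:
    """Extract the 2k+1 window centered on ``site``.

    Minus-strand sites are reverse-complemented so the emitted sequence is the
    transcript strand; the center must then read 'A'.  Positions beyond the
    chromosome ends become 'N'.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if site.chrom not in genome:
        raise KeyError(f"unknown chromosome {site.chrom!r}")
    raw = _plus_strand_slice(genome, site.chrom, site.position, k)
    if site.strand == "-":
        raw = reverse_complement(raw)
    seq = _sanitize(raw)
    if require_center_a and seq[k] != "A":
        raise WindowRejection(
            f"site {site.chrom}:{site.position}({site.strand}) center base is "
            f"{seq[k]!r}, expected 'A'"
        )
    return SequenceWindow(
        sequence=seq,
        half_width=k,
        motif_class=classify_motif(seq),
        label=label,
        site=site,
    )


def _motif_positions(genome: Genome, motif: str) -> list[tuple[str, int, str]]:
    """All (chrom, 1-based position, strand) whose emitted central triplet is
    ``motif``.  On '+' that is a literal genome match (with T read as U as the
    motif has no T/U anyway); on '-' the plus-strand slice reverse-complements
    to the motif."""
    rc = reverse_complement(motif)  # plus-strand pattern for a minus-strand hit
    out: list[tuple[str, int, str]] = []
    for chrom, seq in genome.sequences.items():
        start = 0
        while True:
            i = seq.find(motif, start)
            if i < 0:
                break
            out.append((chrom, i + 2, "+"))  # center of triplet, 1-based
            start = i + 1
        start = 0
        while True:
            i = seq.find(rc, start)
            if i < 0:
                break
            out.append((chrom, i + 2, "-"))
            start = i + 1
    return out


def sample_negative_sites(
    genome: Genome,
    exclusion: Iterable[GenomicSite] | set[tuple[str, int, str]],
    motif: str,
    n: int,
    seed: int,
) -> list[GenomicSite]:
    """Sample ``n`` distinct motif-matched adenosine sites uniformly at random
    from the genome, excluding known sites.

    Eligible positions are every (chrom, position, strand) whose emitted
    central triplet equals ``motif`` (both strands) and whose key is not in the
    exclusion set.  Raises if fewer than ``n`` positions are eligible.
    """
    if motif not in ("GAC", "AAC"):
        raise ValueError(f"motif must be GAC or AAC, got {motif!r}")
    if n < 0:
        raise ValueError("n must be >= 0")
    excl: set[tuple[str, int, str]] = set()
    for e in exclusion:
        excl.add(e.key if isinstance(e, GenomicSite) else tuple(e))
    eligible = [p for p in _motif_positions(genome, motif) if p not in excl]
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} eligible {motif} positions, need {n} "
            f"(shortfall {n - len(eligible)})"
        )
    eligible.sort()  # deterministic base order regardless of dict ordering
    rng = random.Random(seed)
    chosen = rng.sample(eligible, n)
    return [
        GenomicSite(chrom=c, position=p, strand=s, support_num=0, source="sampled-negative")
        for c, p, s in chosen
    ]


def read_windows_fasta(path: str | Path) -> list[SequenceWindow]:
    """Read windows written by :func:`write_windows_fasta`."""
    windows: list[SequenceWindow] = []
    with open(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            fields = dict(
                kv.split("=", 1) for kv in record.description.split()[1:] if "=" in kv
            )
            chrom, pos, strand = record.id.split("|")[0].split(":")
            seq = str(record.seq).upper()
            target = fields.get("target", "None")
            windows.append(
                SequenceWindow(
                    sequence=seq,
                    half_width=len(seq) // 2,
                    motif_class=MotifClass(fields.get("motif", "OTHER")),
                    label=int(fields.get("label", 0)),
                    site=GenomicSite(
                        chrom=chrom,
                        position=int(pos),
                        strand=strand,
                        support_num=int(fields.get("support", 0)),
                    ),
                    support_target=None if target == "None" else float(target),
                )
            )
    if not windows:
        raise ValueError(f"no windows found in {path}")
    return windows


def write_windows_fasta(windows: Iterable[SequenceWindow], path: str | Path) -> None:
    """Windows as FASTA with structured description fields."""
    with open(path, "w") as fh:
        for i, w in enumerate(windows):
            s = w.site
            desc = (
                f"label={w.label} motif={w.motif_class.value} "
                f"support={s.support_num} target={w.support_target}"
            )
            fh.write(f">{s.chrom}:{s.position}:{s.strand}|{i} {desc}\n")
            for j in range(0, len(w.sequence), 80):
                fh.write(w.sequence[j : j + 80] + "\n")
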