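"""k-mer statistics at desk scale.

Exact in-memory k-mer counting, histogram peak detection, k-mer genome-size
estimation, sequencing-depth arithmetic, and meryl/Merqury-style assembly
completeness and consensus quality (QV).

The genome-size estimator implements

    G = B * (L - k + 1) / (L * d)

where B is total sequenced bases, L the mean read length, k the k-mer size
and d the depth of the homozygous k-mer peak: each read of length L yields
L - k + 1 k-mers, so B(L-k+1)/L is the total k-mer count, and dividing by
the per-locus k-mer depth d gives the number of distinct genomic loci.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .util import revcomp, round_half_up

__all__ = [
    "KmerHistogram",
    "KmerTable",
    "count_kmers",
    "find_homozygous_peak",
    "estimate_genome_size",
    "estimate_depth",
    "kmer_completeness",
    "estimate_qv",
]


@dataclass
class KmerHistogram:
    """Multiplicity -> number-of-distinct-k-mers table with read statistics."""

    k: int
    counts: dict[int, int]
    total_bases: float | None = None
    mean_read_len: float | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if any(m < 1 for m in self.counts):
            raise ValueError("multiplicities must be >= 1")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("multiplicity\tcount\n")
            for m in sorted(self.counts):
                fh.write(f"{m}\t{self.counts[m]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, k: int, total_bases=None, mean_read_len=None):
        counts: dict[int, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.lstrip().startswith("multiplicity"):
                fh.seek(0)
            for line in fh:
                if line.strip():
                    m, c = line.split()[:2]
                    counts[int(m)] = int(c)
        return cls(k=k, counts=counts, total_bases=total_bases, mean_read_len=mean_read_len)


@dataclass
class KmerTable:
    """Exact canonical (or stranded) k-mer -> multiplicity map, toy scale."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        """Total k-mer mass (sum of multiplicities)."""
        return sum(self.counts.values())

    def kmer_set(self, min_multiplicity: int = 1) -> set[str]:
        if min_multiplicity <= 1:
            return set(self.counts)
        return {kmer for kmer, c in self.counts.items() if c >= min_multiplicity}

    def histogram(self, total_bases=None, mean_read_len=None) -> KmerHistogram:
        hist: dict[int, int] = {}
        for c in self.counts.values():
            hist[c] = hist.get(c, 0) + 1
        return KmerHistogram(self.k, hist, total_bases, mean_read_len)


_VALID = frozenset("ACGT")


def count_kmers(
    sequences: Iterable[str] | str, k: int, canonical: bool = True
) -> KmerTable:
    """Exact k-mer counting; k-mers containing non-ACGT characters are skipped.

    With ``canonical=True`` each k-mer is folded with its reverse complement
    (lexicographic minimum wins), matching standard k-mer evaluators.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(sequences, str):
        sequences = [sequences]
    table = KmerTable(k=k)
    counts = table.counts
    any_long_enough = False
    for seq in sequences:
        seq = seq.upper()
        if len(seq) >= k:
            any_long_enough = True
        # positions of invalid characters gate which k-mers are clean
        bad = [i for i, ch in enumerate(seq) if ch not in _VALID]
        bad_ptr = 0
        next_bad = bad[0] if bad else len(seq)
        for i in range(len(seq) - k + 1):
            while next_bad < i:
                bad_ptr += 1
                next_bad = bad[bad_ptr] if bad_ptr < len(bad) else len(seq)
            if next_bad < i + k:
                continue
            kmer = seq[i : i + k]
            if canonical:
                rc = revcomp(kmer)
                if rc < kmer:
                    kmer = rc
            counts[kmer] = counts.get(kmer, 0) + 1
    if not any_long_enough:
        warnings.warn(f"k={k} exceeds every sequence length; empty k-mer table")
    return table


def find_homozygous_peak(hist: KmerHistogram, min_multiplicity: int = 5) -> int:
    """Locate the homozygous (rightmost major) mode of a k-mer histogram.

    Counts are smoothed with a 3-bin moving average; local maxima at
    multiplicity > ``min_multiplicity`` are candidate modes, and the
    homozygous peak is the rightmost one whose smoothed height reaches 20%
    of the tallest mode. Ties break toward higher multiplicity.
    """
    if not hist.counts:
        raise ValueError("empty histogram")
    max_m = max(hist.counts)
    dense = np.zeros(max_m + 3, dtype=float)
    for m, c in hist.counts.items():
        dense[m] = c
    smooth = np.convolve(dense, np.ones(3) / 3.0, mode="same")
    # plateau-aware local maxima of the smoothed curve
    maxima: list[tuple[int, float]] = []  # (location, smoothed height)
    i = 1
    while i < len(smooth):
        j = i
        while j + 1 < len(smooth) and smooth[j + 1] == smooth[i]:
            j += 1
        left = smooth[i - 1]
        right = smooth[j + 1] if j + 1 < len(smooth) else 0.0
        if smooth[i] > 0 and smooth[i] > left and smooth[i] > right:
            # locate the mode on the raw counts within the plateau,
            # ties broken toward higher multiplicity
            span = [m for m in range(i, j + 1) if m > min_multiplicity]
            if span:
                best = max(span, key=lambda m: (dense[m], m))
                maxima.append((best, smooth[i]))
        i = j + 1
    if not maxima:
        raise ValueError("histogram has no local maximum above min_multiplicity")
    tallest = max(h for _, h in maxima)
    eligible = [m for m, h in maxima if h >= 0.2 * tallest]
    return int(max(eligible))


def estimate_genome_size(
    total_bases: float, mean_read_len: float, k: int, peak_depth: float
) -> float:
    """Genome size in bp from the k-mer formula G = B(L-k+1)/(L*d)."""
    if mean_read_len <= k:
        raise ValueError("mean read length must exceed k")
    if peak_depth <= 0:
        raise ValueError("peak depth must be positive")
    return total_bases * (mean_read_len - k + 1) / (mean_read_len * peak_depth)


def format_genome_size_gb(genome_size_bp: float) -> float:
    """Display convention: Gb rounded half-up to 2 decimals (1.64)."""
    return round_half_up(genome_size_bp / 1e9, 2)


def estimate_depth(total_bases: float, reference_length: float) -> float:
    """Fold-depth = total bases / reference length, reported at 2 decimals."""
    if reference_length <= 0:
        raise ValueError("reference length must be positive")
    return round_half_up(total_bases / reference_length, 2)


def kmer_completeness(
    read_table: KmerTable,
    assembly_tables: KmerTable | Iterable[KmerTable],
    noise_cutoff: int = 1,
) -> float:
    """Percent of reliable read k-mers present in the union of assemblies.

    Reliable read k-mers have multiplicity > ``noise_cutoff`` (the error
    tail of the read histogram is excluded, as Merqury does).
    """
    if isinstance(assembly_tables, KmerTable):
        assembly_tables = [assembly_tables]
    assembly_tables = list(assembly_tables)
    if any(t.k != read_table.k for t in assembly_tables):
        raise ValueError("k mismatch between read and assembly k-mer sets")
    reliable = {kmer for kmer, c in read_table.counts.items() if c > noise_cutoff}
    if not reliable:
        return 100.0
    union: set[str] = set()
    for t in assembly_tables:
        union |= t.kmer_set()
    found = len(reliable & union)
    return 100.0 * found / len(reliable)


def estimate_qv(
    assembly_table: KmerTable,
    read_table: KmerTable,
    k: int | None = None,
    assembly_kmer_total: int | None = None,
) -> float:
    """Consensus quality in dB from read-unsupported assembly k-mers.

    E = 1 - (1 - K_err/K_total)^(1/k);  QV = -10 log10(E), where K_err is
    the k-mer mass of the assembly absent from the read set and K_total the
    assembly's total k-mer mass. K_err = 0 reports inf (capped in display).
    """
    k = k if k is not None else assembly_table.k
    if k != read_table.k:
        raise ValueError("k mismatch between assembly and read k-mer sets")
    total = assembly_kmer_total if assembly_kmer_total is not None else assembly_table.total
    if total <= 0:
        raise ValueError("assembly k-mer total must be positive")
    read_set = read_table.kmer_set()
    k_err = sum(c for kmer, c in assembly_table.counts.items() if kmer not in read_set)
    if k_err == 0:
        return math.inf
    err_rate = 1.0 - (1.0 - k_err / total) ** (1.0 / k)
    if err_rate >= 1.0:
        return 0.0
    return -10.0 * math.log10(err_rate)
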